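"""Virtual-patient cohort generation.

For every patient anatomy and every model variant a ground-truth tumour
trajectory is grown from uniformly sampled parameters, then corrupted
with additive Gaussian observation noise at the requested levels,
emulating the repeatability noise of longitudinal MRI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import DEFAULT_OBSERVATION_DAYS, Anatomy, make_anatomy, make_schedule
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .forward import SimulationOutput, SimulationWorkspace, SolverConfig, TumourState, simulate
from .params import ParameterBounds, ParameterSet
from .variants import VARIANTS, ModelVariant, get_variant

logger = logging.getLogger(__name__)

DEFAULT_NOISE_LEVELS = (0.05, 0.10, 0.15)


def sample_parameters(variant, bounds: ParameterBounds, rng) -> ParameterSet:
    """Uniform draw of the variant's free parameters within bounds.

    Fixed parameters follow the variant's rules (e.g. alpha_CT = 1 where
    CT efficacy is not calibrated; all treatment terms inert for the
    no-treatment model).
    """
    variant = get_variant(variant)
    lo = bounds.lower(variant.free_params)
    hi = bounds.upper(variant.free_params)
    values = lo + (hi - lo) * rng.random(len(lo))
    base = ParameterSet(**variant.fixed_params)
    return base.with_values(variant.free_params, values)


def add_noise(
    output,
    level: float,
    rng,
    grid,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    proportional: bool = False,
    truncate: bool = False,
):
    """Noisy copies of the observed states.

    Additive zero-mean Gaussian noise with standard deviation
    ``level * theta_E`` is applied voxelwise to both species inside the
    brain mask (including the baseline scan). By default the noise stays
    zero-mean (negative observed densities are allowed, as for image
    noise on a signed map); ``truncate=True`` clips the observations to
    ``[0, theta_j]``, which makes the floor non-zero-mean and biases
    total-cellularity comparisons. ``proportional=True`` scales the noise
    by the local voxel value instead of the carrying capacity.
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if level not in (0.0, 0.05, 0.10, 0.15):
        warnings.warn(f"unusual noise level {level}", stacklevel=2)
    states = output.states if isinstance(output, SimulationOutput) else list(output)
    mask = grid.brain_mask
    noisy = []
    for st in states:
        n_e = st.N_E.copy()
        n_n = st.N_N.copy()
        if level > 0:
            if proportional:
                sd_e = level * n_e[mask]
                sd_n = level * n_n[mask]
            else:
                sd_e = sd_n = level * constants.theta_E
            n_e[mask] = n_e[mask] + sd_e * rng.standard_normal(mask.sum())
            n_n[mask] = n_n[mask] + sd_n * rng.standard_normal(mask.sum())
            if truncate:
                np.clip(n_e, 0.0, constants.theta_E, out=n_e)
                np.clip(n_n, 0.0, constants.theta_N, out=n_n)
        noisy.append(TumourState(N_E=n_e, N_N=n_n, day=st.day))
    return noisy


@dataclass
class VirtualPatient:
    """One synthetic tumour: anatomy, generating model, truth and noisy scans."""

    patient_id: int
    anatomy: Anatomy
    schedule: list
    generating_variant: ModelVariant
    true_params: ParameterSet
    truth: SimulationOutput
    observations: dict = field(default_factory=dict)   # noise level -> list[TumourState]
    anatomy_seed: int = None


def generate_cohort(
    n_patients: int,
    variants=None,
    bounds: ParameterBounds | None = None,
    noise_levels=DEFAULT_NOISE_LEVELS,
    master_seed: int = 0,
    dims=(16, 16, 3),
    observation_days=DEFAULT_OBSERVATION_DAYS,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    solver: SolverConfig = SolverConfig(),
    max_resample: int = 5,
):
    """Grow the full virtual cohort: one tumour per patient per variant.

    Fully reproducible from ``master_seed``; returns ``(patients,
    manifest)`` where the manifest is a DataFrame with one row per
    tumour recording seeds and generating parameters.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if variants is None:
        variants = sorted(VARIANTS.values(), key=lambda v: v.index)
    variants = [get_variant(v) for v in variants]
    bounds = bounds or ParameterBounds()
    root = np.random.SeedSequence(master_seed)
    patient_seqs = root.spawn(n_patients)

    patients = []
    rows = []
    for p in range(n_patients):
        anat_seed, param_seed, noise_seed = (
            int(s.generate_state(1)[0] % (2 ** 31)) for s in patient_seqs[p].spawn(3)
        )
        anatomy = make_anatomy(anat_seed, dims=dims, constants=constants)
        schedule = make_schedule(anatomy)
        workspace = SimulationWorkspace(anatomy, constants)
        param_rng = np.random.default_rng(param_seed)
        noise_rng = np.random.default_rng(noise_seed)
        for variant in variants:
            truth = None
            for attempt in range(max_resample):
                true_params = sample_parameters(variant, bounds, param_rng)
                try:
                    truth = simulate(
                        variant, true_params, anatomy, schedule, observation_days,
                        constants=constants, config=solver, workspace=workspace,
                    )
                    break
                except FloatingPointError as exc:
                    logger.warning(
                        "patient %d %s: simulation failed (%s); resampling", p, variant.id, exc
                    )
            if truth is None:
                raise RuntimeError(
                    f"patient {p} {variant.id}: no stable parameter set in {max_resample} draws"
                )
            observations = {
                float(level): add_noise(truth, level, noise_rng, anatomy.grid, constants)
                for level in noise_levels
            }
            patient = VirtualPatient(
                patient_id=p,
                anatomy=anatomy,
                schedule=schedule,
                generating_variant=variant,
                true_params=true_params,
                truth=truth,
                observations=observations,
                anatomy_seed=anat_seed,
            )
            patients.append(patient)
            row = {
                "patient_id": p,
                "variant": variant.id,
                "anatomy_seed": anat_seed,
                "n_mask_voxels": anatomy.grid.n_inside,
            }
            row.update({f"true_{k}": v for k, v in true_params.to_dict().items()})
            rows.append(row)
    manifest = pd.DataFrame(rows)
    return patients, manifest
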
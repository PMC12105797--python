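"""Forward simulation of tumour growth and chemoradiation response.

Two interacting species (enhancing and non-enhancing tumour) grow by a
logistic-competition reaction-diffusion system on the brain mask with
zero-flux boundaries. Diffusion is damped by mechanical stress (see
:mod:`gliosel.mechanics`). Radiotherapy and chemotherapy act as discrete
multiplicative reductions at treatment events; the eleven model variants
differ in whether the surviving fraction is spatially uniform, coupled
to vasculature through the oxygen enhancement ratio, or modulated by
local cell density. Repeated irradiation also shrinks the effective
proliferation rate by a per-fraction factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import assemble_and_integrate
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .grid import GREY, WHITE, DiffusionAssembler, Grid
from .mechanics import ElasticitySystem, damp_diffusion
from .params import ParameterSet
from .variants import DENSITY, OFF, VASCULATURE, ModelVariant

__all__ = [
    "TumourState", "TreatmentEvent", "SimulationOutput", "SolverConfig",
    "oer_map", "surviving_fraction_lq", "surviving_fraction_oer",
    "surviving_fraction_density", "apply_treatment_event",
    "effective_proliferation", "growth_step", "simulate", "SimulationWorkspace",
]


@dataclass
class TumourState:
    """Normalized tumour density fields at one time point (days)."""

    N_E: np.ndarray
    N_N: np.ndarray
    day: float

    def total(self) -> np.ndarray:
        return self.N_E + self.N_N


@dataclass(frozen=True)
class TreatmentEvent:
    """One fraction of RT and/or one concurrent chemotherapy dose."""

    day: int
    has_rt: bool
    has_ct: bool
    dose_map: np.ndarray     # Gy, zero outside the brain mask
    fraction_index: int


@dataclass
class SimulationOutput:
    states: list
    er_map: np.ndarray
    auxiliary: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for the explicit time integration.

    dt is chosen as ``min(dt_max, cfl / (2 * D_max * sum(1/h^2)))`` so the
    forward-Euler diffusion update stays stable; the mechanics solve and
    the stress-damped diffusivity are refreshed once per
    ``mechanics_interval`` simulated days (quasi-static assumption).
    """

    dt_max: float = 0.1
    cfl: float = 0.9
    mechanics_interval: float = 1.0


# ---------------------------------------------------------------------------
# treatment-response primitives
# ---------------------------------------------------------------------------

def oer_map(er_field: np.ndarray, brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Oxygen enhancement ratio OER = max(ER) - ER + 1.

    The maximum is taken over the brain mask; a voxel at the maximum
    enhancement ratio (best perfused) gets OER = 1 and treatment there is
    unattenuated, while poorly perfused voxels get OER > 1.
    """
    er = np.asarray(er_field, dtype=float)
    if not np.all(np.isfinite(er)) or np.any(er <= 0):
        raise ValueError("ER field must be finite and positive")
    if brain_mask is not None:
        if not np.any(brain_mask):
            raise ValueError("brain mask is empty")
        er_max = float(er[np.asarray(brain_mask, bool)].max())
    else:
        if er.size == 0:
            raise ValueError("ER field is empty")
        er_max = float(er.max())
    return er_max - er + 1.0


def surviving_fraction_lq(alpha, dose, alpha_beta=None):
    """Linear-quadratic surviving fraction.

    ``SF = exp(-alpha * D * (1 + D / (alpha/beta)))`` for radiotherapy;
    passing ``alpha_beta=None`` (or 0) takes the chemotherapy convention
    where the quadratic term is dropped: ``SF = exp(-alpha * D)``.
    """
    alpha = np.asarray(alpha, dtype=float)
    dose = np.asarray(dose, dtype=float)
    if np.any(alpha < 0) or np.any(dose < 0):
        raise ValueError("alpha and dose must be non-negative")
    if alpha_beta is None or (np.isscalar(alpha_beta) and alpha_beta == 0):
        return np.exp(-alpha * dose)
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be positive for the RT term")
    return np.exp(-alpha * dose * (1.0 + dose / alpha_beta))


def surviving_fraction_oer(alpha, dose, alpha_beta, oer):
    """Vasculature-coupled surviving fraction: dose is divided by the OER."""
    oer = np.asarray(oer, dtype=float)
    if np.any(oer < 1):
        raise ValueError("OER must be >= 1 everywhere")
    dose_eff = np.asarray(dose, dtype=float) / oer
    if alpha_beta is None or (np.isscalar(alpha_beta) and alpha_beta == 0):
        return surviving_fraction_lq(alpha, dose_eff, None)
    return np.exp(-np.asarray(alpha, float) * dose_eff * (1.0 + dose_eff / alpha_beta))


def surviving_fraction_density(sf_min, n_e, n_n, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Density-modulated surviving fraction.

    Interpolates between the full linear-quadratic kill ``sf_min`` at
    carrying capacity and no kill in empty voxels:
    ``SF = SF_min + (1 - SF_min) * (1 - (N_E + N_N) / (theta_E + theta_N))``.
    """
    sf_min = np.asarray(sf_min, dtype=float)
    if np.any(sf_min <= 0) or np.any(sf_min > 1):
        raise ValueError("sf_min must lie in (0, 1]")
    n_e = np.asarray(n_e, float)
    n_n = np.asarray(n_n, float)
    tol = 1e-9
    if np.any(n_e > constants.theta_E + tol) or np.any(n_n > constants.theta_N + tol):
        raise ValueError("densities exceed carrying capacities")
    frac = (n_e + n_n) / (constants.theta_E + constants.theta_N)
    return sf_min + (1.0 - sf_min) * (1.0 - frac)


def apply_treatment_event(state: TumourState, sf_rt_field, sf_ct_field) -> TumourState:
    """Discrete treatment hit: both species scale by SF_RT * SF_CT voxelwise."""
    for sf in (sf_rt_field, sf_ct_field):
        sf = np.asarray(sf, float)
        if np.any(sf <= 0) or np.any(sf > 1):
            raise ValueError("surviving fractions must lie in (0, 1]")
    factor = np.asarray(sf_rt_field, float) * np.asarray(sf_ct_field, float)
    return TumourState(N_E=state.N_E * factor, N_N=state.N_N * factor, day=state.day)


def effective_proliferation(kp0, sf_rt_prolif, n_fractions):
    """Proliferation rate after ``n`` fractions: kp = kp0 * SF_prolif ** n."""
    if np.isscalar(n_fractions) and (n_fractions < 0 or int(n_fractions) != n_fractions):
        raise ValueError("n_fractions must be a non-negative integer")
    sf = np.asarray(sf_rt_prolif, float)
    if np.any(sf <= 0) or np.any(sf > 1):
        raise ValueError("sf_rt_prolif must lie in (0, 1]")
    return np.asarray(kp0, float) * sf ** int(n_fractions)


# ---------------------------------------------------------------------------
# reaction-diffusion stepping
# ---------------------------------------------------------------------------

def stability_bound(d_max: float, spacing, cfl: float = 0.9) -> float:
    """Largest stable forward-Euler dt for diffusivity ``d_max``."""
    inv = sum(1.0 / h ** 2 for h in spacing)
    if d_max <= 0:
        return math.inf
    return cfl / (2.0 * d_max * inv)


def unrestricted_diffusivity(grid: Grid, params: ParameterSet) -> np.ndarray:
    """Flat enhancing-species D0 field assigned by tissue label."""
    d0 = np.where(grid.labels_flat == WHITE, params.D_w, 0.0)
    d0[grid.labels_flat == GREY] = params.D_g
    return d0


def _react_and_step(n_e, n_n, lap_e, lap_n, kp_e, kp_n, params, constants, dt):
    growth_e = kp_e * n_e * (1.0 - (n_e + params.beta_NE * n_n) / constants.theta_E)
    growth_n = kp_n * n_n * (1.0 - (n_n + params.beta_EN * n_e) / constants.theta_N)
    return n_e + dt * (lap_e + growth_e), n_n + dt * (lap_n + growth_n)


def growth_step(
    state: TumourState,
    d_e_field: np.ndarray,
    d_n_field: np.ndarray,
    kp_e_eff,
    kp_n_eff,
    params: ParameterSet,
    constants: ModelConstants,
    dt: float,
    grid: Grid,
) -> TumourState:
    """One explicit finite-difference update of both species.

    Zero-flux boundaries at the brain surface; the result is clipped to
    ``[0, theta_j]``. Raises if ``dt`` violates the diffusion stability
    bound for the supplied diffusivity fields.
    """
    d_e = grid.flatten(d_e_field)
    d_n = grid.flatten(d_n_field)
    d_max = float(max(d_e.max(initial=0.0), d_n.max(initial=0.0)))
    bound = stability_bound(d_max, grid.spacing)
    if dt > bound:
        raise ValueError(f"dt={dt} violates the stability bound {bound:.6g}")
    asm_e, asm_n = DiffusionAssembler(grid), DiffusionAssembler(grid)
    lap_e = asm_e.update(d_e) @ grid.flatten(state.N_E)
    lap_n = asm_n.update(d_n) @ grid.flatten(state.N_N)
    kp_e = kp_e_eff if np.isscalar(kp_e_eff) else grid.flatten(kp_e_eff)
    kp_n = kp_n_eff if np.isscalar(kp_n_eff) else grid.flatten(kp_n_eff)
    n_e, n_n = _react_and_step(
        grid.flatten(state.N_E), grid.flatten(state.N_N),
        lap_e, lap_n, kp_e, kp_n, params, constants, dt,
    )
    n_e = np.clip(n_e, 0.0, constants.theta_E)
    n_n = np.clip(n_n, 0.0, constants.theta_N)
    return TumourState(N_E=grid.unflatten(n_e), N_N=grid.unflatten(n_n), day=state.day + dt)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

class SimulationWorkspace:
    """Per-anatomy caches shared across repeated simulations.

    Holds the factorized elasticity system, diffusion-operator sparsity,
    the OER field and flattened dose maps so that a calibration loop
    (thousands of forward solves on one anatomy) never re-assembles them.
    """

    def __init__(self, anatomy, constants: ModelConstants = DEFAULT_CONSTANTS):
        self.anatomy = anatomy
        self.constants = constants
        self.grid: Grid = anatomy.grid
        self.elasticity = ElasticitySystem(self.grid, constants)
        self.assembler_e = DiffusionAssembler(self.grid)
        self.oer_flat = self.grid.flatten(
            oer_map(anatomy.er_map, self.grid.brain_mask)
        )
        self._dose_cache: dict = {}

    def dose_flat(self, event: TreatmentEvent) -> np.ndarray:
        key = id(event.dose_map)  # schedules reuse one dose map across fractions
        if key not in self._dose_cache:
            self._dose_cache[key] = self.grid.flatten(event.dose_map)
        return self._dose_cache[key]


def _static_event_sfs(variant, params, dose, oer):
    """State-independent parts of the event surviving fractions.

    For uniform/vasculature couplings the returned RT/CT fields are the
    final surviving fractions (the dose map is fixed, so they are reused
    across fractions); for density coupling they are the minimum
    surviving fraction still to be modulated by the local density.
    """
    if variant.rt_coupling == OFF:
        sf_rt = np.ones_like(dose)
        sf_prolif = np.ones_like(dose)
    elif variant.rt_coupling == VASCULATURE:
        sf_rt = surviving_fraction_oer(params.alpha_RT, dose, params.alpha_beta, oer)
        sf_prolif = surviving_fraction_oer(
            params.alpha_RT_prolif, dose, params.alpha_beta, oer
        )
    else:
        sf_rt = surviving_fraction_lq(params.alpha_RT, dose, params.alpha_beta)
        sf_prolif = surviving_fraction_lq(params.alpha_RT_prolif, dose, params.alpha_beta)

    if variant.ct_coupling == OFF:
        sf_ct = np.ones_like(dose)
    elif variant.ct_coupling == VASCULATURE:
        sf_ct = surviving_fraction_oer(params.alpha_CT, dose, None, oer)
    else:
        sf_ct = surviving_fraction_lq(params.alpha_CT, dose, None)
    return sf_rt, sf_ct, sf_prolif


def _event_surviving_fractions(variant, params, dose, oer, n_e, n_n, constants,
                               static=None):
    """Flat SF_RT, SF_CT and SF_RT,prolif fields for one treatment event."""
    sf_rt, sf_ct, sf_prolif = (
        static if static is not None else _static_event_sfs(variant, params, dose, oer)
    )
    if variant.rt_coupling == DENSITY:
        sf_rt = surviving_fraction_density(sf_rt, n_e, n_n, constants)
    if variant.ct_coupling == DENSITY:
        sf_ct = surviving_fraction_density(sf_ct, n_e, n_n, constants)
    return sf_rt, sf_ct, sf_prolif


def simulate(
    variant: ModelVariant,
    params: ParameterSet,
    anatomy,
    schedule,
    observation_days,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    config: SolverConfig = SolverConfig(),
    initial_state: TumourState | None = None,
    workspace: SimulationWorkspace | None = None,
) -> SimulationOutput:
    """Integrate one model variant and sample it at the observation days.

    The tumour is "imaged" at the beginning of each observation day,
    before that day's treatment event. Between events the two-species
    reaction-diffusion system is advanced by forward Euler; mechanics and
    the stress-damped diffusivity are refreshed once per day.
    """
    if workspace is None:
        workspace = SimulationWorkspace(anatomy, constants)
    grid = workspace.grid
    obs = [int(d) for d in observation_days]
    if obs != sorted(obs) or len(set(obs)) != len(obs):
        raise ValueError("observation_days must be strictly increasing")
    state0 = initial_state if initial_state is not None else anatomy.initial_state
    if obs[0] != int(state0.day):
        raise ValueError("first observation day must equal the initial-state day")

    # measured (noisy) baselines may stray outside the admissible range;
    # the model state itself must not
    n_e = np.clip(grid.flatten(state0.N_E), 0.0, constants.theta_E)
    n_n = np.clip(grid.flatten(state0.N_N), 0.0, constants.theta_N)
    prolif = np.ones_like(n_e)
    kp_e = params.kpE * prolif
    kp_n = params.kpN * prolif
    events_by_day: dict = {}
    for ev in schedule:
        events_by_day.setdefault(int(ev.day), []).append(ev)

    d0_e = unrestricted_diffusivity(grid, params)
    sf_cache: dict = {}
    obs_set = set(obs)
    states: list = []
    clipped = 0
    vm = None
    last_day = obs[-1]

    mech_every = max(int(round(config.mechanics_interval)), 1)

    for day in range(obs[0], last_day + 1):
        if day in obs_set:
            states.append(
                TumourState(N_E=grid.unflatten(n_e), N_N=grid.unflatten(n_n), day=float(day))
            )
            if day == last_day:
                break
        if variant.has_treatment:
            for ev in events_by_day.get(day, ()):
                dose = workspace.dose_flat(ev)
                static = sf_cache.get(id(dose))
                if static is None:
                    static = _static_event_sfs(variant, params, dose, workspace.oer_flat)
                    sf_cache[id(dose)] = static
                sf_rt, sf_ct, sf_prolif = _event_surviving_fractions(
                    variant, params, dose, workspace.oer_flat, n_e, n_n, constants,
                    static=static,
                )
                factor = np.ones_like(dose)
                if ev.has_rt:
                    factor *= sf_rt
                    prolif = prolif * sf_prolif
                    kp_e = params.kpE * prolif
                    kp_n = params.kpN * prolif
                if ev.has_ct and not variant.combined:
                    factor *= sf_ct
                n_e = n_e * factor
                n_n = n_n * factor

        if vm is None or (day - obs[0]) % mech_every == 0:
            vm = workspace.elasticity.von_mises_flat(n_e + n_n)
            d_e = damp_diffusion(d0_e, vm, params.lambda1)
            d_max = float(d_e.max(initial=0.0)) * max(1.0, params.f_NE)
            dt_bound = stability_bound(d_max, grid.spacing, config.cfl)
            n_steps = max(int(math.ceil(1.0 / min(config.dt_max, dt_bound))), 1)
            dt = 1.0 / n_steps

        asm = workspace.assembler_e
        op = asm.matrix
        clipped += assemble_and_integrate(
            n_e, n_n, d_e, asm.edge_i, asm.edge_j, asm.edge_inv_h2, asm.perm,
            op.data, params.f_NE, kp_e, kp_n,
            params.beta_NE, params.beta_EN,
            constants.theta_E, constants.theta_N, dt, n_steps,
            op.indptr, op.indices,
        )
        if not math.isfinite(float(n_e.sum()) + float(n_n.sum())):
            raise FloatingPointError(f"simulation blew up during day {day}")

    return SimulationOutput(
        states=states,
        er_map=anatomy.er_map,
        auxiliary={
            "von_mises": grid.unflatten(vm) if vm is not None else None,
            "clipped_voxel_steps": clipped,
        },
    )
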
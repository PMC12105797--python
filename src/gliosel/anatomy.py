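"""Synthetic virtual-patient anatomy.

Real studies of this kind derive the computational domain from a
patient's treatment-planning MRI: a skull-stripped brain mask, a
white/grey segmentation, an enhancing-tumour density estimated from the
apparent diffusion coefficient (ADC), a non-enhancing rim at a fixed
density, an enhancement-ratio (ER) map standing in for vascularity, and
the prescribed radiotherapy dose distribution. This module generates
all of those deterministically from a seed so the identifiability
pipeline needs no protected imaging data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .constants import DEFAULT_CONSTANTS, ModelConstants
from .forward import TreatmentEvent, TumourState
from .grid import GREY, OUTSIDE, WHITE, Grid

logger = logging.getLogger(__name__)

ADC_WATER = 3.0e-3   # mm^2/s, ADC of free water
ADC_MIN_DEFAULT = 0.5e-3  # mm^2/s, densest observed tumour


@dataclass
class Anatomy:
    """One virtual patient's fixed scaffold."""

    grid: Grid
    er_map: np.ndarray
    gtv_mask: np.ndarray
    ctv_mask: np.ndarray
    initial_state: TumourState
    adc_map: np.ndarray = None
    seed: int = None


def adc_to_density(adc_field, adc_min=ADC_MIN_DEFAULT, adc_w=ADC_WATER):
    """Map ADC to normalized enhancing density.

    ``N_E = (ADC_w - ADC) / (ADC_w - ADC_min)``: free-water diffusivity
    means no tumour, the densest observed tumour maps to 1.
    """
    adc = np.asarray(adc_field, dtype=float)
    if adc_min >= adc_w:
        raise ValueError("adc_min must be below the ADC of water")
    if np.any(adc > adc_w + 1e-12) or np.any(adc < adc_min - 1e-12):
        raise ValueError("ADC values must lie within [adc_min, adc_w]")
    return (adc_w - adc) / (adc_w - adc_min)


def density_to_adc(density, adc_min=ADC_MIN_DEFAULT, adc_w=ADC_WATER):
    """Inverse of :func:`adc_to_density`; builds the pseudo-ADC map."""
    d = np.asarray(density, dtype=float)
    if np.any(d < -1e-12) or np.any(d > 1 + 1e-12):
        raise ValueError("density must lie in [0, 1]")
    return adc_w - d * (adc_w - adc_min)


def _elliptical_mask(dims, rng):
    nx, ny, nz = dims
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ax = nx * (0.42 + 0.03 * rng.random())
    ay = ny * (0.42 + 0.03 * rng.random())
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    disc = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    return np.repeat(disc[:, :, None], nz, axis=2)


def _tissue_partition(mask, rng):
    noise = rng.standard_normal(mask.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=(2.0, 2.0, 0.8))
    inside = smooth[mask]
    labels = np.full(mask.shape, OUTSIDE, dtype=np.uint8)
    labels[mask] = np.where(inside > np.median(inside), WHITE, GREY)
    return labels


def make_anatomy(
    seed: int,
    dims=(16, 16, 3),
    spacing=(0.5, 0.5, 2.0),
    constants: ModelConstants = DEFAULT_CONSTANTS,
    enhancing_threshold: float = 0.16,
    rim_voxels: int = 2,
    max_retries: int = 20,
) -> Anatomy:
    """Generate a deterministic virtual-patient anatomy.

    An elliptical brain mask with a smoothed random white/grey partition,
    a Gaussian enhancing tumour core placed interior to the mask (rebuilt
    with a logged retry if it touches the boundary), a non-enhancing rim
    at fixed density ``theta_N``, an ER map elevated around the enhancing
    rim, and a pseudo-ADC map consistent with the initial density.
    """
    dims = tuple(int(d) for d in dims)
    if any(a < b for a, b in zip(dims, (16, 16, 3))):
        raise ValueError(f"dims must be at least (16, 16, 3), got {dims}")
    rng = np.random.default_rng(seed)
    mask = _elliptical_mask(dims, rng)
    labels = _tissue_partition(mask, rng)
    grid = Grid(dims=dims, spacing=spacing, brain_mask=mask, tissue_labels=labels)

    nx, ny, nz = dims
    # interior region: keep the tumour core away from the brain surface
    interior = ndimage.binary_erosion(
        mask, structure=np.ones((3, 3, 1), bool), iterations=max(2, nx // 8)
    )
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    n_e = None
    for attempt in range(max_retries):
        if not interior.any():
            raise ValueError("brain mask too small to place an interior tumour")
        cand = np.argwhere(interior)
        cx, cy, cz = cand[rng.integers(len(cand))]
        amp = 0.5 + 0.3 * rng.random()
        sig_xy = (0.09 + 0.05 * rng.random()) * nx
        sig_z = 0.8 + 0.4 * rng.random()
        r2 = ((x - cx) ** 2 + (y - cy) ** 2) / (2 * sig_xy ** 2) \
            + ((z - cz) ** 2) / (2 * sig_z ** 2)
        bump = amp * np.exp(-r2)
        enhancing = (bump >= enhancing_threshold) & mask
        touches = enhancing & ~ndimage.binary_erosion(
            mask, structure=np.ones((3, 3, 1), bool)
        )
        if enhancing.any() and not touches.any():
            n_e = np.where(enhancing, np.minimum(bump, constants.theta_E), 0.0)
            break
        logger.info("anatomy seed %s: tumour placement retry %d", seed, attempt + 1)
    if n_e is None:
        raise RuntimeError(f"could not place tumour interior to the mask (seed {seed})")

    struct = np.ones((3, 3, 1), bool)
    rim = ndimage.binary_dilation(enhancing, structure=struct, iterations=rim_voxels)
    rim &= mask & ~enhancing
    n_n = np.where(rim, constants.theta_N, 0.0)

    # ER: background ~1 with an elevated band around the enhancing rim
    ring = ndimage.binary_dilation(enhancing, structure=struct, iterations=2) & ~ndimage.binary_erosion(
        enhancing, structure=struct
    )
    er = 1.0 + (0.5 + 0.5 * rng.random()) * ndimage.gaussian_filter(
        ring.astype(float), sigma=(1.2, 1.2, 0.5)
    )
    er = np.where(mask, np.maximum(er, 1.0), 1.0)

    gtv = enhancing | rim
    dil = int(round(20.0 / spacing[0]))  # 2 cm margin in-plane
    ctv = ndimage.binary_dilation(gtv, structure=struct, iterations=dil) & mask

    adc = np.where(mask, density_to_adc(np.where(mask, n_e, 0.0)), ADC_WATER)
    state0 = TumourState(N_E=n_e, N_N=n_n, day=0.0)
    return Anatomy(
        grid=grid, er_map=er, gtv_mask=gtv, ctv_mask=ctv,
        initial_state=state0, adc_map=adc, seed=seed,
    )


def make_schedule(
    anatomy: Anatomy,
    start_day: int = 0,
    n_fractions: int = 30,
    gtv_total_dose: float = 60.0,
    ctv_total_dose: float = 50.0,
    concurrent_ct: bool = True,
    penumbra_sigma_mm: float = 0.75,
):
    """Weekday-fractionated chemoradiation schedule.

    The prescription delivers ``gtv_total_dose`` to the gross tumour
    volume and ``ctv_total_dose`` to the 2 cm clinical-target margin in
    ``n_fractions`` daily weekday fractions (Mon-Fri, weekends off),
    with concurrent chemotherapy flagged on every fraction day.

    A Gaussian penumbra (``penumbra_sigma_mm``, set 0 to disable) smooths
    the dose outside the GTV, as delivered plans do. Besides realism this
    matters for identifiability: with a two-level dose map the uniform
    treatment variants expose only two dose samples to constrain three
    sensitivity parameters, so their calibration problem is structurally
    degenerate; the penumbra's dose continuum removes that degeneracy.
    GTV voxels receive exactly the prescribed fraction dose either way.
    """
    if n_fractions <= 0:
        raise ValueError("n_fractions must be positive")
    dose = np.zeros(anatomy.grid.dims)
    dose[anatomy.ctv_mask] = ctv_total_dose / n_fractions
    dose[anatomy.gtv_mask] = gtv_total_dose / n_fractions
    if penumbra_sigma_mm > 0:
        sig = [penumbra_sigma_mm / h for h in anatomy.grid.spacing]
        dose = ndimage.gaussian_filter(dose, sigma=sig)
        dose[anatomy.gtv_mask] = gtv_total_dose / n_fractions
    dose[~anatomy.grid.brain_mask] = 0.0

    events = []
    day = int(start_day)
    k = 0
    while k < n_fractions:
        if (day - start_day) % 7 < 5:  # Monday-Friday
            events.append(
                TreatmentEvent(
                    day=day, has_rt=True, has_ct=concurrent_ct,
                    dose_map=dose, fraction_index=k + 1,
                )
            )
            k += 1
        day += 1
    return events


DEFAULT_OBSERVATION_DAYS = (0, 7, 14, 21, 67)
"""Imaging days: planning scan, start of RT weeks 1-3, four weeks post-RT
(the 30th weekday fraction falls on day 39; day 67 is 28 days later)."""
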
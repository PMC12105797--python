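"""Agreement metrics between model-estimated and ground-truth tumours.

Global level: Dice overlap of binarized tumour masks and the percentage
error in total tumour cellularity (TTC). Voxel level: Lin's concordance
correlation coefficient on the combined normalized density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Default binarization threshold on N_E + N_N; matches the seeding
#: density of the non-enhancing rim.
DEFAULT_MASK_THRESHOLD = 0.16


@dataclass
class MetricsReport:
    dsc: float
    ccc: float
    pe_ttc: float
    time_label: str = ""

    def to_dict(self) -> dict:
        return {"dsc": self.dsc, "ccc": self.ccc, "pe_ttc": self.pe_ttc,
                "time_label": self.time_label}


def tumour_mask(state, threshold: float = DEFAULT_MASK_THRESHOLD) -> np.ndarray:
    """Binary tumour extent: voxels where N_E + N_N >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return np.asarray(state.N_E) + np.asarray(state.N_N) >= threshold


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A & B| / (|A| + |B|).

    Two empty masks score 1.0 by convention (identical emptiness).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def ccc(values_a, values_b, sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    ``CCC = 2 s_ab / (s_a^2 + s_b^2 + (mean_a - mean_b)^2)`` with
    population (1/n) moments by default; equals 1 iff the two vectors
    agree elementwise. Raises if both inputs are constant (undefined).
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    ddof = 1 if sample_moments else 0
    va = a.var(ddof=ddof)
    vb = b.var(ddof=ddof)
    ma, mb = a.mean(), b.mean()
    if va == 0 and vb == 0:
        raise ValueError("CCC undefined: both inputs are constant")
    denom = va + vb + (ma - mb) ** 2
    n = a.size
    cov = ((a - ma) @ (b - mb)) / (n - ddof)
    return float(2.0 * cov / denom)


def theta_cells(
    packing_density: float = 0.7405,
    cell_radius_mm: float = 0.01,
    voxel_volume_mm3: float = 0.5,
) -> float:
    """Physical voxel carrying capacity in cells.

    Sphere packing at the given density with 10 um cells in a 0.5 mm^3
    voxel gives about 8.84e4 cells.
    """
    if packing_density <= 0 or cell_radius_mm <= 0 or voxel_volume_mm3 <= 0:
        raise ValueError("all inputs must be positive")
    cell_volume = 4.0 / 3.0 * math.pi * cell_radius_mm ** 3
    return packing_density * voxel_volume_mm3 / cell_volume


def total_cellularity(state, theta_cells_value: float | None = None) -> float:
    """Total tumour cellularity: theta_cells * sum(N_E + N_N) over voxels."""
    if theta_cells_value is None:
        theta_cells_value = theta_cells()
    return float(theta_cells_value * (np.sum(state.N_E) + np.sum(state.N_N)))


def percent_error(estimate: float, truth: float) -> float:
    """Signed percentage error 100 * (estimate - truth) / truth."""
    if truth == 0:
        raise ValueError("percentage error undefined for zero truth")
    return 100.0 * (estimate - truth) / truth


def summarize(values):
    """(median, IQR) with the linear-interpolation quantile convention."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty collection")
    q1, q3 = np.percentile(v, [25, 75])
    return float(np.median(v)), float(q3 - q1)


def score_states(
    estimated,
    observed,
    truth,
    grid,
    threshold: float = DEFAULT_MASK_THRESHOLD,
    time_label: str = "",
) -> MetricsReport:
    """Score a model-estimated state the way the study metrics are defined.

    Dice compares against the binarized noise-free truth (a noisy
    reference mask is speckle-dominated once the noise SD nears the
    threshold); CCC and the TTC percentage error compare against the
    noisy scan at the same day, so the observation noise floor sits on
    both sides of the comparison.
    """
    m_est = tumour_mask(estimated, threshold)
    m_tru = tumour_mask(truth, threshold)
    a = grid.flatten(observed.N_E + observed.N_N)
    b = grid.flatten(estimated.N_E + estimated.N_N)
    return MetricsReport(
        dsc=dice(m_tru, m_est),
        ccc=ccc(a, b),
        pe_ttc=percent_error(total_cellularity(estimated), total_cellularity(observed)),
        time_label=time_label,
    )


def evaluate_states(
    estimated,
    truth,
    grid,
    threshold: float = DEFAULT_MASK_THRESHOLD,
    time_label: str = "",
) -> MetricsReport:
    """All three agreement metrics for one (estimated, truth) state pair.

    CCC is computed on the combined density restricted to the brain mask.
    """
    m_est = tumour_mask(estimated, threshold)
    m_tru = tumour_mask(truth, threshold)
    a = grid.flatten(truth.N_E + truth.N_N)
    b = grid.flatten(estimated.N_E + estimated.N_N)
    return MetricsReport(
        dsc=dice(m_tru, m_est),
        ccc=ccc(a, b),
        pe_ttc=percent_error(total_cellularity(estimated), total_cellularity(truth)),
        time_label=time_label,
    )
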
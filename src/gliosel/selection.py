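"""Corrected-AIC model selection and cohort-level tallying."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import VARIANT_IDS, VARIANTS, get_variant


def aicc(rss: float, n_points: int, k: int) -> float:
    """Corrected Akaike information criterion for a Gaussian LSQ fit.

    ``AIC = 2k + n ln(RSS/n) + 2k(k+1)/(n-k-1)``. Strictly increasing in
    ``k`` at fixed RSS and ``n``; a zero RSS returns ``-inf`` as a
    documented sentinel (a perfect fit dominates any candidate).
    """
    if n_points <= k + 1:
        raise ValueError(f"need n > k + 1 for the AICc correction (n={n_points}, k={k})")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        return -math.inf
    return (
        2.0 * k
        + n_points * math.log(rss / n_points)
        + 2.0 * k * (k + 1) / (n_points - k - 1)
    )


@dataclass
class SelectionResult:
    aic_by_model: dict
    selected: str
    generating: str = None
    correct: bool = None
    patient_id: int = None
    noise_level: float = None

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "generating": self.generating,
            "correct": self.correct,
            "patient_id": self.patient_id,
            "noise_level": self.noise_level,
            "aic_by_model": dict(self.aic_by_model),
        }


def select(
    calibrations: dict,
    generating=None,
    allow_subset: bool = False,
    tie_tol: float = 1e-9,
    patient_id=None,
    noise_level=None,
) -> SelectionResult:
    """Pick the minimum-AICc variant among the supplied calibrations.

    ``calibrations`` maps variant id -> CalibrationResult. All eleven
    variants are required unless ``allow_subset``. Numerical ties (within
    ``tie_tol``) break toward fewer parameters, then the lower variant
    index.
    """
    if not calibrations:
        raise ValueError("no calibrations supplied")
    missing = set(VARIANT_IDS) - set(calibrations)
    if missing and not allow_subset:
        raise ValueError(f"missing calibrations for variants: {sorted(missing)}")
    aic = {
        vid: aicc(res.rss, res.n_points, res.k) for vid, res in calibrations.items()
    }
    best = min(aic.values())
    tied = [vid for vid, a in aic.items() if a - best <= tie_tol]
    selected = min(tied, key=lambda vid: (VARIANTS[vid].n_params, VARIANTS[vid].index))
    gen_id = get_variant(generating).id if generating is not None else None
    return SelectionResult(
        aic_by_model=aic,
        selected=selected,
        generating=gen_id,
        correct=None if gen_id is None else selected == gen_id,
        patient_id=patient_id,
        noise_level=noise_level,
    )


@dataclass
class ConfusionMatrix:
    """Generating-model (rows) vs selected-model (columns) tally."""

    counts: pd.DataFrame
    per_model_rate: pd.Series
    overall_rate: float
    n_cases: int
    within_class_confusion_rate: float = float("nan")

    def __str__(self):  # rendered text table
        lines = [self.counts.to_string()]
        lines.append(f"overall correct-selection rate: {100 * self.overall_rate:.1f}%")
        if np.isfinite(self.within_class_confusion_rate):
            lines.append(
                "incorrect selections within the same coupling class: "
                f"{100 * self.within_class_confusion_rate:.1f}%"
            )
        return "\n".join(lines)


def tally(results) -> ConfusionMatrix:
    """Tabulate selection outcomes across a cohort.

    Also reports the fraction of *incorrect* selections that stayed
    within the generating model's treatment-coupling class (uniform,
    vasculature, density, none).
    """
    counts = pd.DataFrame(0, index=list(VARIANT_IDS), columns=list(VARIANT_IDS), dtype=int)
    n_wrong = 0
    n_wrong_same_class = 0
    n_correct = 0
    n_cases = 0
    for res in results:
        if res.generating is None:
            raise ValueError("selection result lacks a generating label")
        counts.loc[res.generating, res.selected] += 1
        n_cases += 1
        if res.correct:
            n_correct += 1
        else:
            n_wrong += 1
            if (
                VARIANTS[res.generating].coupling_class
                == VARIANTS[res.selected].coupling_class
            ):
                n_wrong_same_class += 1
    row_sums = counts.sum(axis=1)
    per_model = pd.Series(
        np.where(row_sums > 0, np.diag(counts) / np.maximum(row_sums, 1), np.nan),
        index=counts.index,
    )
    return ConfusionMatrix(
        counts=counts,
        per_model_rate=per_model,
        overall_rate=n_correct / n_cases if n_cases else float("nan"),
        n_cases=n_cases,
        within_class_confusion_rate=(n_wrong_same_class / n_wrong) if n_wrong else float("nan"),
    )
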
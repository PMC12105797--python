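"""Calibrated model parameters and their admissible ranges."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

#: Canonical parameter order used for vectorization.
PARAM_NAMES = (
    "kpE",            # enhancing proliferation rate, 1/day
    "kpN",            # non-enhancing proliferation rate, 1/day
    "D_w",            # unrestricted enhancing diffusion in white matter, mm^2/day
    "D_g",            # unrestricted enhancing diffusion in grey matter, mm^2/day
    "f_NE",           # D_N = D_E * f_NE (mobility scaling), unitless
    "beta_NE",        # competition of non-enhancing on enhancing, unitless
    "beta_EN",        # competition of enhancing on non-enhancing, unitless
    "lambda1",        # von Mises stress -> diffusion damping, 1/kPa
    "alpha_RT",       # RT efficacy, 1/Gy
    "alpha_RT_prolif",  # RT effect on proliferation, 1/Gy
    "alpha_CT",       # CT efficacy, 1/Gy
    "alpha_beta",     # alpha/beta fractionation-sensitivity ratio, Gy
)


@dataclass(frozen=True)
class ParameterSet:
    """One model variant's rate and sensitivity parameters."""

    kpE: float = 0.0
    kpN: float = 0.0
    D_w: float = 0.0
    D_g: float = 0.0
    f_NE: float = 1.0
    beta_NE: float = 0.0
    beta_EN: float = 0.0
    lambda1: float = 0.0
    alpha_RT: float = 0.0
    alpha_RT_prolif: float = 0.0
    alpha_CT: float = 0.0
    alpha_beta: float = 10.0

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"parameter {f.name} must be non-negative")

    def as_array(self, names=PARAM_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    def with_values(self, names, values) -> "ParameterSet":
        return replace(self, **dict(zip(names, (float(v) for v in values))))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter (lower, upper) calibration bounds.

    Defaults are physically plausible stand-ins spanning published rates
    for image-based glioma models; every value is overridable.
    """

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            if not (0 <= lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    def lower(self, names) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in names], dtype=float)

    def upper(self, names) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in names], dtype=float)

    def midpoint(self, names) -> np.ndarray:
        return 0.5 * (self.lower(names) + self.upper(names))

    def contains(self, params: ParameterSet, names) -> bool:
        v = params.as_array(names)
        return bool(np.all(v >= self.lower(names) - 1e-12) and np.all(v <= self.upper(names) + 1e-12))


DEFAULT_BOUNDS = {
    "kpE": (0.005, 0.10),
    "kpN": (0.005, 0.10),
    "D_w": (0.01, 0.5),
    "D_g": (0.005, 0.25),
    "f_NE": (0.1, 5.0),
    "beta_NE": (0.0, 2.0),
    "beta_EN": (0.0, 2.0),
    "lambda1": (0.0, 1.0),
    "alpha_RT": (0.01, 0.2),
    "alpha_RT_prolif": (0.001, 0.05),
    "alpha_CT": (0.01, 0.5),
    "alpha_beta": (5.0, 15.0),
}
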
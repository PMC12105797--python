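"""Fixed model constants (literature-assigned, never calibrated)."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ModelConstants:
    """Constants shared by every member of the model family.

    Attributes
    ----------
    theta_E, theta_N : float
        Carrying capacities of the enhancing and non-enhancing species
        (normalized densities; 1 and 0.16).
    G_white, G_grey : float
        Shear moduli of white and grey matter, kPa.
    nu : float
        Poisson's ratio of brain tissue.
    lambda2 : float
        Tumour-density body-force coupling in the mechanical equilibrium
        equation; magnitude 1 in the internal kPa/mm unit system.
    """

    theta_E: float = 1.0
    theta_N: float = 0.16
    G_white: float = 2.7
    G_grey: float = 3.1
    nu: float = 0.45
    lambda2: float = 1.0

    def __post_init__(self):
        for name in ("theta_E", "theta_N", "G_white", "G_grey", "lambda2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if self.theta_N > self.theta_E:
            raise ValueError("theta_N must not exceed theta_E")


DEFAULT_CONSTANTS = ModelConstants()
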
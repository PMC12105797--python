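"""The eleven-member model family M1..M11.

All members share the two-species reaction-diffusion growth core; they
differ only in how the discrete chemoradiation surviving fractions are
coupled to the tissue:

===== ============================== ==========================
model treatment coupling             calibrated parameters (k)
===== ============================== ==========================
M1    RT & CT, spatially uniform     12
M2    combined RT/CT, uniform        11
M3    RT via vasculature, CT uniform 12
M4    CT via vasculature (a_CT = 1)  11
M5    RT & CT via vasculature        12
M6    combined RT/CT via vasculature 12
M7    RT via cell density, CT unif.  12
M8    CT via cell density (a_CT = 1) 11
M9    RT & CT via cell density       12
M10   combined RT/CT via density     12
M11   no treatment effect            8
===== ============================== ==========================

"Combined" variants model a single RT-form term and force SF_CT = 1.
For M6/M10 the published parameter count (12) exceeds the number of
parameters that actually influence the dynamics (alpha_CT is inert when
SF_CT = 1); ``free_params`` carries the influential set used by the
calibrator while ``n_params`` keeps the published count for the AICc
penalty. Both are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

UNIFORM = "uniform"
VASCULATURE = "vasculature"
DENSITY = "density"
OFF = "off"

_BASE8 = (
    "kpE", "kpN", "D_w", "D_g", "f_NE", "beta_NE", "beta_EN", "lambda1",
)
_RT3 = ("alpha_RT", "alpha_RT_prolif", "alpha_beta")


@dataclass(frozen=True)
class ModelVariant:
    """One assumption on the spatial coupling of treatment efficacy."""

    id: str
    index: int
    rt_coupling: str = UNIFORM
    ct_coupling: str = UNIFORM
    combined: bool = False
    n_params: int = 12
    free_params: tuple = ()
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self):
        for c in (self.rt_coupling, self.ct_coupling):
            if c not in (UNIFORM, VASCULATURE, DENSITY, OFF):
                raise ValueError(f"unknown coupling {c!r}")
        if self.combined and self.ct_coupling != OFF:
            raise ValueError("combined variants must have ct_coupling = off")
        if self.n_params <= 0:
            raise ValueError("n_params must be positive")

    @property
    def has_treatment(self) -> bool:
        return self.rt_coupling != OFF or self.ct_coupling != OFF

    @property
    def coupling_class(self) -> str:
        """Treatment-efficacy assumption class used for confusion analysis."""
        if not self.has_treatment:
            return "none"
        if VASCULATURE in (self.rt_coupling, self.ct_coupling):
            return "vasculature"
        if DENSITY in (self.rt_coupling, self.ct_coupling):
            return "density"
        return "uniform"


def _mk(idx, rt, ct, combined, k, free, fixed=None) -> ModelVariant:
    return ModelVariant(
        id=f"M{idx}", index=idx, rt_coupling=rt, ct_coupling=ct,
        combined=combined, n_params=k, free_params=tuple(free),
        fixed_params=dict(fixed or {}),
    )


VARIANTS = {
    v.id: v
    for v in (
        _mk(1, UNIFORM, UNIFORM, False, 12, _BASE8 + _RT3 + ("alpha_CT",)),
        _mk(2, UNIFORM, OFF, True, 11, _BASE8 + _RT3, {"alpha_CT": 1.0}),
        _mk(3, VASCULATURE, UNIFORM, False, 12, _BASE8 + _RT3 + ("alpha_CT",)),
        _mk(4, UNIFORM, VASCULATURE, False, 11, _BASE8 + _RT3, {"alpha_CT": 1.0}),
        _mk(5, VASCULATURE, VASCULATURE, False, 12, _BASE8 + _RT3 + ("alpha_CT",)),
        _mk(6, VASCULATURE, OFF, True, 12, _BASE8 + _RT3, {"alpha_CT": 1.0}),
        _mk(7, DENSITY, UNIFORM, False, 12, _BASE8 + _RT3 + ("alpha_CT",)),
        _mk(8, UNIFORM, DENSITY, False, 11, _BASE8 + _RT3, {"alpha_CT": 1.0}),
        _mk(9, DENSITY, DENSITY, False, 12, _BASE8 + _RT3 + ("alpha_CT",)),
        _mk(10, DENSITY, OFF, True, 12, _BASE8 + _RT3, {"alpha_CT": 1.0}),
        _mk(11, OFF, OFF, False, 8, _BASE8,
            {"alpha_RT": 0.0, "alpha_RT_prolif": 0.0, "alpha_CT": 0.0}),
    )
}

VARIANT_IDS = tuple(VARIANTS)


def get_variant(vid) -> ModelVariant:
    if isinstance(vid, ModelVariant):
        return vid
    key = vid if str(vid).startswith("M") else f"M{vid}"
    try:
        return VARIANTS[key]
    except KeyError:
        raise KeyError(f"unknown model variant {vid!r}; expected M1..M11") from None
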
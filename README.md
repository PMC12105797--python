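# gliosel

Parameter and model identifiability for image-based models of high-grade
glioma (HGG) response to chemoradiation, tested on virtual patient cohorts.

## The problem

Spatio-temporal reaction–diffusion models personalised from longitudinal MRI
can forecast how a glioma responds to radiotherapy (RT) and concurrent
chemotherapy (CT). But a family of such models differing only in *how*
treatment efficacy couples to the tissue (uniformly, through vasculature,
or through cell density) may fit the same scans almost equally well. Before
trusting a selected model — or parameters like the fractionation
sensitivity α/β — for treatment adaptation, one must ask: with imaging of
realistic quality, are the parameters recoverable, and is the generating
model selectable at all? `gliosel` answers this *in silico*: it grows
ground-truth tumours with known models and parameters on synthetic
anatomies, corrupts the "scans" with noise, re-calibrates every candidate
model, and scores recovery, selection and prediction.

## The model family

Eleven variants M1–M11 share a two-species logistic reaction–diffusion core
for the enhancing and non-enhancing tumour (carrying capacities θ_E = 1,
θ_N = 0.16) with mechanically damped diffusion,

    ∂N̂_i/∂t = ∇·(D_i ∇N̂_i) + k_p,i N̂_i (1 − (N̂_i + β_ij N̂_j)/θ_i),
    D_i = D_i,0 exp(−λ₁ σ_vm),

where σ_vm is the von Mises stress of the tumour-loaded linear-elastic
equilibrium state of the brain. Each RT fraction (60 Gy to the GTV in 30
weekday fractions, concurrent CT) multiplies the densities by
linear-quadratic surviving fractions, SF = exp(−α·D·(1 + D/(α/β))), with the
quadratic term dropped for CT, and shrinks the proliferation rate by
SF_RT,prolif per fraction. The variants couple SF uniformly, through the
oxygen enhancement ratio OER = max(ER) − ER + 1 (dose ÷ OER), or through
local density; to RT and CT separately, jointly, or as a single combined
term; M11 ignores treatment. Calibration is bounded Levenberg–Marquardt on
the voxelwise residuals of both species over weeks 1–3 of RT; model
selection minimises the corrected AIC,
AICc = 2k + n ln(RSS/n) + 2k(k+1)/(n−k−1); accuracy is scored with Dice
overlap, Lin's concordance correlation coefficient (CCC) and the percentage
error in total tumour cellularity (TTC), at the last calibration scan and
at a held-out scan four weeks post-RT. See `docs/methods.md` for details
and design choices.

## Worked example

```python
import numpy as np
import gliosel as g

# one virtual patient, tumour grown with the no-treatment model M11
patients, manifest = g.generate_cohort(
    n_patients=1, variants=("M11",), noise_levels=(0.05,), master_seed=7,
)
patient = patients[0]

# recalibrate the generating model from the noisy scans
obs = g.Observations.from_states(patient.observations[0.05], noise_level=0.05)
fit = g.levenberg_marquardt(
    "M11", patient.anatomy, patient.schedule, obs,
    bounds=g.ParameterBounds(),
)
truth = patient.true_params.to_dict()
for name in patient.generating_variant.free_params:
    est = fit.params_hat.to_dict()[name]
    print(f"{name:8s} truth {truth[name]:.4f}  estimate {est:.4f}  "
          f"error {100*abs(est-truth[name])/truth[name]:5.1f}%")
```

prints (seed 7, 5 % noise):

```
kpE      truth 0.0333  estimate 0.0117  error  64.8%
kpN      truth 0.0542  estimate 0.0472  error  12.9%
D_w      truth 0.2488  estimate 0.2104  error  15.5%
D_g      truth 0.0227  estimate 0.0186  error  18.3%
f_NE     truth 4.0007  estimate 4.4517  error  11.3%
beta_NE  truth 1.7436  estimate 0.0000  error 100.0%
beta_EN  truth 0.4480  estimate 0.8020  error  79.0%
lambda1  truth 0.2243  estimate 1.0000  error 345.8%
```

The fit itself is good (it converged on the 0.01 % parameter-change rule
with an RSS at the noise floor), yet several parameters land far from the
truth — the competition coefficient β_NE collapses to its lower bound and
the stress-diffusion coupling λ₁ saturates its upper bound. On this small
noise-free-anatomy world with only four scans, those directions are simply
not identified at 5 % noise, while the same calibration on noise-free data
recovers every parameter to machine precision (see the acceptance tests).
Distinguishing "well fit" from "well identified" is exactly the kind of
statement this package exists to quantify. The full experiments are
exposed both as functions (`run_parameter_identifiability`,
`run_model_identifiability`) and as a CLI:

```sh
gliosel cohort generate --n-patients 2 --seed 1 --out cohort/
gliosel identify params --n-patients 2 --noise 0.05 --seed 1 --out report/
gliosel identify model --n-patients 2 --noise 0.05 --seed 1 --out report/
gliosel report report/
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch at the given seed: the Dice and CCC
perfect-agreement identities, the OER value at the best-perfused voxel, and
— on a scaled-down seeded cohort (3 patients × 11 generating models ×
5/15 % noise, reduced LM iteration budget) — the median across model × noise
cells of the per-cell median week-3 Dice and TTC percentage error of
generating-model calibrations. It writes one JSON object mapping target ids
to `{"value": ..., "n": ...}` and takes about 11 minutes on one CPU.
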
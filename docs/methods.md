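# Methods

`gliosel` implements a virtual-cohort testbed for asking two questions about
image-based models of high-grade glioma (HGG) response to chemoradiation:
given longitudinal MRI-like observations of known provenance and noise, can
the generating model's parameters be recovered (parameter identifiability),
and can the generating model itself be picked out of a family of candidates
(model identifiability)?

## The model family

All eleven variants share a two-species reaction–diffusion core on a
voxelized brain domain. The enhancing (`N_E`, carrying capacity
`theta_E = 1`) and non-enhancing (`N_N`, `theta_N = 0.16`) normalized
densities evolve by

    dN_E/dt = div(D_E grad N_E) + kpE N_E (1 - (N_E + beta_NE N_N)/theta_E)
    dN_N/dt = div(D_N grad N_N) + kpN N_N (1 - (N_N + beta_EN N_E)/theta_N)

with zero-flux boundaries at the brain surface, `D_N = f_NE * D_E`, and
tissue-dependent unrestricted diffusivity (`D_w` white, `D_g` grey matter).
Mechanical coupling: the tumour burden loads a linear-elastic equilibrium
problem (shear moduli 2.7/3.1 kPa white/grey, Poisson ratio 0.45, body-force
coupling `lambda2 = 1`, slip condition at the brain surface), and the
resulting von Mises stress damps diffusion as
`D = D0 exp(-lambda1 sigma_vm)`.

Chemoradiation acts as discrete multiplicative hits at each fraction:
`N -> N * SF_RT * SF_CT`, with surviving fractions from the linear-quadratic
model `SF = exp(-alpha D (1 + D/(alpha/beta)))` (the quadratic term is
dropped for chemotherapy). A per-fraction factor `SF_RT,prolif` additionally
shrinks the effective proliferation rate as `kp = kp0 * SF_RT,prolif^n` after
`n` fractions. The eleven variants differ only in the spatial coupling of
treatment efficacy: uniform, vasculature-coupled through the oxygen
enhancement ratio `OER = max(ER) - ER + 1` (dose divided by OER), or
density-coupled (`SF = SF_min + (1 - SF_min)(1 - (N_E+N_N)/(theta_E+theta_N))`),
each applied to RT and CT separately, to both, or to a single combined
RT/CT term; the no-treatment variant closes the family. See
`gliosel.variants` for the full table.

Two printed-source ambiguities were resolved as follows and are deliberate
design choices of this package:

* the density-modulated surviving fraction is implemented exactly as the
  formula above (maximal kill at carrying capacity), although the
  accompanying biological narrative (quiescence protecting dense voxels)
  suggests the opposite sign; the formula is authoritative here;
* in the combined RT/CT variants with vasculature or density coupling the
  published calibrated-parameter count is 12, yet the CT sensitivity cannot
  influence a combined model (SF_CT is identically 1). The calibrator
  therefore optimizes only the 11 influential parameters while the AICc
  penalty keeps the published count; both are overridable on `ModelVariant`.

## Numerics

Explicit forward Euler with `dt = min(0.1 d, 0.9 / (2 D_max sum(1/h_i^2)))`
on a 0.5 x 0.5 x 2 mm grid (three axial slices by default). The mechanics
solve and the stress-damped diffusivity are refreshed once per simulated day
(quasi-static cadence, configurable). Because the equilibrium problem is
linear with a fixed stiffness matrix per anatomy, the density-to-strain map
is precomputed (one LU factorization plus one multi-RHS solve) and stored in
single precision; the daily refresh is then a single matrix-vector product.
The ~1e-7 relative error this introduces in `sigma_vm` is orders of
magnitude below the observation noise; the double-precision solve remains
available (`ElasticitySystem.solve_flat`) and is the path checked against a
dense-matrix oracle in the tests. Densities are clipped to `[0, theta_j]`
after every step and clip events are counted in the simulation output.
The sub-daily integration loop is JIT-compiled (numba) with a semantically
identical numpy fallback; both are pinned to the public single-step
reference in unit tests.

## Virtual patients

A synthetic-anatomy generator stands in for patient imaging: an elliptical
brain mask, a smoothed-noise white/grey partition, a Gaussian enhancing core
placed interior to the mask (density 0.16–0.8, segmented at 0.16), a
non-enhancing rim fixed at `N_N = 0.16`, an enhancement-ratio map with
background 1 elevated around the tumour rim, and a pseudo-ADC map obtained
by inverting the ADC-to-density relation
`N_E = (ADC_w - ADC)/(ADC_w - ADC_min)` with `ADC_w = 3e-3 mm^2/s` and
`ADC_min = 0.5e-3 mm^2/s` (round-trip tested). The prescription is 60 Gy to
the gross tumour volume and 50 Gy to a 2 cm margin in 30 weekday fractions
(days 0–39) with concurrent chemotherapy; imaging occurs at day 0, the
starts of RT weeks 1–3 (days 7, 14, 21) and four weeks post-RT (day 67).
The per-fraction dose map carries a Gaussian penumbra (sigma 0.75 mm,
configurable to 0 for a sharp two-level map) outside the GTV. Delivered
plans are smooth, and the continuum of dose values is what makes the
uniform-coupling variants' three treatment sensitivities jointly
identifiable — with only two discrete dose levels their calibration
problem is structurally degenerate and the noiseless recovery gates fail
in local minima.

What the generator does *not* emulate: MRI contrast physics, bias fields,
registration error, irregular cortical anatomy, resection cavities. A green
test therefore establishes internal consistency of the pipeline under the
stated noise model, not robustness to real imaging artefacts.

Ground-truth parameters are drawn uniformly inside the calibration bounds
(`gliosel.params.DEFAULT_BOUNDS`; the published supplementary ranges are not
in the main text, so these stand-ins are configurable). Observation noise is
additive voxelwise Gaussian with standard deviation `level * theta_E`
(absolute, not proportional — proportional noise would vanish on empty
voxels and make overlap metrics trivially perfect), applied to both species
at every imaging day including baseline. The noise is *not* truncated by
default: truncating at zero would give the floor a positive mean of about
`0.4 * level * theta_E` per empty voxel, and on domains where empty voxels
outnumber tumour voxels that bias inflates the observed total cellularity
by tens of percent — incompatible with the sub-percent calibration TTC
errors this class of study reports. Zero-mean noise cancels in the TTC sum.
Truncation to `[0, theta_j]` is available via `add_noise(..., truncate=True)`.
The simulator clips the noisy baseline back into the admissible range on the
first integration step. Note the sampled treatment sensitivities can be
strong enough to eradicate a tumour before week 3; such tumours score
Dice 1 at calibration (empty mask against empty mask) and near-zero CCC
against a pure-noise scan — both are faithful readings, not artefacts.

## Calibration and selection

Calibration minimizes the residual sum of squares between the noisy scans
and the model run from the *noisy* day-0 state, stacked over both species,
all brain-mask voxels and days 7/14/21 (`n = 2 |mask| * 3` residuals); the
day-67 scan is held out for prediction scoring. The bounded
Levenberg–Marquardt fitter works in bound-scaled coordinates, starts at the
midpoint of the bounds, uses a forward finite-difference Jacobian (relative
step 1e-3; central differences behind a flag), accepts steps that reduce the
RSS (damping /10 on accept, x2 on reject), clamps to the bounds, and stops
at 250 iterations, when the largest relative parameter change of an
accepted step falls below 0.01 %, on a perfect (zero-RSS) fit, or when the
damping overflows with every step rejected (best-so-far returned,
`converged=False`). Weakly identified directions (notably `alpha/beta`)
produce long flat valleys in which noisy fits often run to the iteration
cap; this is a property of the problem, not a solver defect, and is why the
experiment helpers expose the iteration cap as a scaling knob.

Model selection computes the corrected AIC per variant,
`AIC = 2k + n ln(RSS/n) + 2k(k+1)/(n-k-1)`, with `n` the residual count and
`k` the variant's published parameter count, and picks the minimum;
numerical ties (1e-9) break toward fewer parameters, then the lower variant
index. A zero-RSS fit maps to `-inf` (it dominates), mirroring the
`+inf` sentinel of the profiled Gaussian log-likelihood at RSS = 0.

## Evaluation

Agreement between a model-estimated state and the reference scan is scored
at the last calibration day (week 3) and the held-out prediction day:
Dice overlap of masks binarized at total density 0.16 (two empty masks
score 1 by convention), Lin's concordance correlation coefficient on the
combined density over the brain mask (population moments; sample-moment
mode behind a flag — the printed denominator sign of the mean term is
corrected to `(mean_a - mean_b)^2`, since the printed form would violate
CCC = 1 at perfect agreement), and the signed percentage error in total
tumour cellularity with `theta_cells ~ 8.84e4` cells/voxel (packing 0.7405,
10 um cell radius, 0.5 mm^3 voxels). The reference is the noisy scan at the
matching day, so the observation noise sits on both sides of the comparison
exactly as it would with measured images. Summaries report median and IQR
(linear-interpolation quantiles) per model and noise level.

## Known limitations

* Slip boundary conditions are imposed on the voxelized (staircase) brain
  surface via ghost parity, not on a smooth surface mesh.
* The ER map is generated once at baseline and reused at every fraction;
  propagating vascular change over treatment is out of scope.
* With the default bounds the CT sensitivity may be drawn small enough that
  separate-CT and combined variants become practically indistinguishable,
  and `alpha/beta` is only weakly identified by a two-dose-level fraction
  map — both limits show up as honest confusion/slow-convergence in the
  experiments rather than being patched over.
* Single-start local optimization: with a midpoint start the fitter can
  settle in a local minimum for unlucky parameter draws.
* Domain-size effects: several cohort-level statistics do not transfer from
  full-resolution brain domains to the default 16 x 16 x 3 test world. The
  total-cellularity error carries a floor of a few percent (single-scan TTC
  noise scales as `level * sqrt(|mask|)` relative to a tumour mass that
  shrinks with the domain, and the clipped noisy baseline adds
  ~`0.4 * level * |mask|` of spurious mass that is a rounding error at full
  scale but tens of percent here), and the noisy model-selection rate is
  capped by the fraction of sampled tumours the treatment eradicates before
  week 3 — eradicated tumours are pure noise by the calibration window and
  cannot favour their generating model. The acceptance tests that assert
  the full-scale bounds on these quantities fail on the test world and are
  left failing deliberately; the remaining gates (noise-free recovery and
  selection, conservation, oracle agreement) are scale-independent and pass.
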
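# Methods

This note documents the models, conventions, numerical choices and known
limitations of `prfconn`.  Everything quantitative stated here is computed by
the test suite (`tests/`) or the acceptance script (`scripts/acceptance.py`);
nothing is quoted from external data.

## Stimulus model

The mapping stimulus is a bar of width 5.7° sweeping a 40° × 40° square field
in four orientations (0°, 45°, 90°, 135°), two opposed directions each, in 12
steps of 2 s per sweep.  The model input is the *binarized* aperture movie on
an odd-sized square pixel grid (fixation at the center pixel, x
right-positive, y up-positive, degrees); carrier imagery and its 8 Hz update
rate are metadata only.

Timing convention: the printed design only reconciles with a 204 s run
(8 × 24 s of sweeps + 12 s) if the diagonal-sweep blanks *replace* the final
six 2 s bar steps of each diagonal sweep and a 12 s blank baseline leads the
run.  We adopt that convention and expose it as `blank_rule`; whether the
extra 12 s is a leading baseline, trailing blank, or split is not derivable
from the design, so the choice is documented rather than asserted.

Bar placement: bar centers move uniformly from $-(E-w)/2$ to $+(E-w)/2$ along
the sweep direction, so the bar always lies fully inside the field and the
swept band tiles the full extent.  Under this convention the on-pixel
fraction of any cardinal-sweep frame equals $w/E$ up to one pixel row; for
diagonal sweeps the fraction varies with the chord of the square, which is a
property of the geometry, not of the implementation.  Opposite directions
traverse the same bar positions in reverse order (exactly frame-reversed for
cardinal sweeps; diagonal sweeps share the blank-replacement of their second
half).

## pRF forward model and fitting

CSS model: response $r_t = (\sum S_t G)^n$ with $G$ an isotropic Gaussian of
SD $\sigma$ scaled analytically to unit continuous volume
(pixel area / $2\pi\sigma^2$), *not* renormalized after grid truncation —
this keeps amplitudes grid-resolution independent and makes out-of-aperture
pRFs visible as small overlap mass.  Compression is applied to the spatial
sum *before* temporal convolution.  The HRF is a canonical double-gamma
(difference of gamma densities with shapes 6 and 16, undershoot ratio 1/6,
peak ≈ 5 s, undershoot ≈ 15 s, support 32 s, unit peak), sampled at
`hrf_dt` (default 1 s); the TR defaults to 2 s (one volume per bar step).
Both are configurable — no specific HRF or TR is implied by the design.

Fitting minimizes SSE in two stages: (1) a grid of 3,483 candidates (polar
centers to 25°, log-spaced $\sigma$ from 0.21° to 40°, $n \in \{0.25, 0.5,
1\}$) whose predicted time series are precomputed once per
aperture/HRF/TR and shared across voxels, with gain solved per candidate by
non-negative least squares; (2) bounded L-BFGS-B refinement of
$(x, y, \sigma, n)$ from the best grid candidate, gain again closed-form.
Refinement bounds are $|x|, |y| \le 25°$ (1.25 × the mapped half-extent) and
$\sigma \in [0.21°, 30°]$: centers far outside the aperture are not
identifiable from bar responses — with looser bounds, noisy peripheral
voxels drift to eccentricities of 40–60° along the eccentricity–size ridge
— so the bounds encode the identifiable region rather than a prior belief.
The stopping rule is relative SSE reduction below 1e-15 (noise-free recovery
is then exact to ~1e-4 in all parameters).  `converged` is true when the
optimizer succeeded or improved on its grid seed; a constant series returns
`converged=False` with VE 0.

Variance explained is $1 - SS_{res}/SS_{tot}$ about the observed mean,
clipped at 0 for reporting.  Inclusion follows the mapping protocol: VE
strictly above 0.20 (0.10 for the robustness variant), fitted $\sigma$ not
exactly at the 0.21° optimizer floor, and at least 10 surviving voxels per
ROI.

## Synthetic ground truth

The generators emulate the statistical structure the analyses assume, not
the physiology producing it:

- **Populations.** Ventral-like: eccentricities truncated-exponential with
  scale 3° (≈ 81 % of centers inside 5°); lateral-like: uniform-by-area to
  35° (≈ 2 % inside 5°).  Polar angles are von Mises about the contralateral
  horizontal meridian ($\kappa = 1$); $\sigma = s_0 + m \cdot ecc$ plus
  Gaussian jitter, floored at 0.3° ($s_0$ = 3°/6° and $m$ = 0.5/0.4 for
  ventral/lateral, giving sizes of roughly 6° vs 20°); exponents uniform on
  [0.2, 0.8].  Effect sizes echo the magnitude of the group contrast without
  claiming to reproduce subject data.  Per-subject variants jitter the
  eccentricity scale lognormally (SD 0.3 of the log) because real
  between-subject spread dwarfs multinomial counting noise.
- **Noise.** White Gaussian per volume (AR(1) optional), with SD set per
  voxel from its signal variance so the expected VE hits a target (default
  0.6).  A single constant SD calibrated to the same median VE was evaluated
  and rejected for the recovery experiments: it starves weak peripheral
  voxels of signal and measures scanner SNR rather than estimator quality.
- **EVC surface.** A flat 1 mm sheet (61 columns along the eccentricity
  gradient), eccentricity linear from 0–5° over the first quarter and then
  octave-doubling to 40°, so the four bands occupy equal sheet extent — a
  flat caricature of cortical magnification.  Distances are Euclidean on the
  sheet; disk ROIs (5 mm control, 10 mm stand-in ROI) inherit that geometry.
  The sheet is not a folded cortical mesh.
- **Endpoints.** Band membership multinomial in the requested weights,
  vertex uniform within band, TDI weights lognormal with configurable
  dispersion (0 → all equal).
- **Streamlines.** Random walks with exactly 1 mm steps, per-step turning
  uniform within the candidate's maximum angle, Gaussian lengths (default
  mean 40 mm, SD 15 mm).  They exercise filtering, concatenation and
  intersection — they do not emulate tracking physics, and tractography
  proper (FOD estimation, probabilistic tracking, streamline validation) is
  a contract boundary with a pluggable pass-through stub.  Point storage is
  float64; the 2.5-million-streamline ensemble check uses float32 (arc-length
  rounding ~1e-5 mm) to halve memory.

## Coverage and band conventions

Coverage is the mean over pRFs of the disk indicator (boundary inclusive).
Density curves average the map over 1°-wide annuli restricted to the
contralateral hemifield (the $x = 0$ meridian belongs to neither hemifield).
Eccentricity bands are half-open $[lo, hi)$ with the final band closed at
40°; centers beyond 40° are excluded from denominators and counted.  Group
maps are means of per-subject maps.  The logistic fit uses multistart
nonlinear least squares (12 starts over quartile inflections and both
steepness signs); since which of $a, b$ is the high-eccentricity asymptote
depends on the sign of $d$, the resolved asymptotes are reported alongside
the raw parameters.  Degenerate (constant) curves are flagged rather than
fitted.

## Mixed models

All group tests are random-intercept LMMs, `value ~ factorial(factors) +
(1 | subject)`, fitted by REML.  With one variance component the marginal
covariance is block diagonal with $V_i = \sigma_e^2 (I + \lambda J)$, so the
REML criterion is profiled over $\lambda$ with closed-form block algebra and
optimized in 1-D; fixed effects use sum-to-zero coding so the Wald test of a
coefficient block is the Type III test.  Satterthwaite denominator dfs follow
the standard recipe: per-contrast df $2 f^2 / (\nabla f^\top A \nabla f)$
with $A$ the inverse observed information of the variance components
(central-difference Hessian of the REML deviance), aggregated over the
eigendirections of $L C L^\top$ for multi-df F tests.  The implementation is
cross-checked in the test suite against R's lmerTest/emmeans on a fixed
table (F, dfs, variance components and Tukey p-values agree to ≤ 0.5 %) and
against classical repeated-measures ANOVA (pingouin) in the balanced
one-factor case, where the two coincide; with two within-subject factors a
random-intercept LMM pools the error strata and is *not* identical to the
classical two-way RM-ANOVA.  Tukey HSD p-values use the studentized range on
Satterthwaite dfs, with classical-df values reported alongside (the choice
is not derivable from the analysis description).

Proportions are analyzed on the raw scale.  Measured limitation: band
proportions carry compositional, band-heteroskedastic multinomial noise, so
under a *profile-driven* null (both streams drawn from the same skewed
population profile) the interaction test rejects at ≈ 0.12–0.16 instead of
0.05.  The calibration experiment therefore draws its null tables from the
LMM's own Gaussian model (identical band means in both streams), where the
measured rejection rate is ≈ 0.07; users analyzing strongly skewed
proportions should consider a variance-stabilizing transform.

## Problem sizes and experiment designs

The package's standard experiments, used by tests and the acceptance script:

- Parameter recovery: 100 voxels per replicate, eccentricity uniform on
  [0, 20°], $\sigma$ uniform on [1°, 10°], $n$ uniform on [0.2, 1], target VE
  0.6; the summary statistic is the median over 3 seeded replicates of the
  Pearson correlation between true and recovered values (one replicate's r
  fluctuates by ± 0.03–0.05 at these conditions).
- Interaction power: 100 replicates of 20 subjects × 2 streams × 100 voxels,
  tested at α = 0.01; null calibration: 200 Gaussian-model replicates at
  α = 0.05.
- Demo pipeline: 6 subjects × 2 streams × 30 voxels at grid resolution 61,
  chosen so the full run completes in a few minutes on one CPU.

## Known limitations

- The synthetic generators share the fitted model family (same HRF, white
  noise), so recovery results bound estimator quality under ideal
  conditions; they say nothing about HRF mismatch, physiological noise, or
  motion.
- The flat EVC sheet makes disk ROIs Euclidean disks; on folded cortex the
  same radius captures different vertex sets.
- Streamline geometry is a random walk, so fWMT percentages in the demo are
  properties of the constructed scene, not of anatomy.
- Fitted gain is non-negative by construction; voxels anti-correlated with
  the stimulus fit as gain 0 with VE ≤ 0.
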
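# prfconn

Spatial computations in high-level visual cortex differ between processing
streams: face-selective regions on the ventral surface analyze the center of
gaze, while face-selective regions on the lateral surface spread their
receptive fields into the periphery — and the white-matter connections each
stream receives from early visual cortex (EVC) mirror that split.  `prfconn`
reimplements the full analysis chain behind that comparison as a tested,
seeded pipeline running on synthetic ground truth: population receptive field
(pRF) modelling with compressive spatial summation, visual field coverage
analytics, eccentricity-band statistics, and eccentricity-resolved
quantification of streamline endpoints in EVC.

It is written for researchers who want to validate, extend, or teach this
kind of retinotopy + tractography analysis without access to the original
fMRI/dMRI data: every stage consumes either standard files (NIfTI, TCK/TRK,
TSV, YAML) or outputs of the package's own generators with known ground
truth.

## The model

Each voxel's pRF is an isotropic 2-D Gaussian with center $(x, y)$ and
standard deviation $\sigma$ (degrees of visual angle).  Its response to a
binarized stimulus frame $S_t$ follows compressive spatial summation (CSS):

$$r_t = \Big(\sum_{\text{pixels}} S_t \, G_{x,y,\sigma}\Big)^{n}, \qquad 0 < n \le 1,$$

and the predicted BOLD signal is $\beta\,(r * h)(t)$ sampled at the TR, with
$h$ a canonical double-gamma HRF.  Parameters are estimated per voxel by
minimizing the sum of squared errors — a coarse grid search over
$(x, y, \sigma, n)$ with the gain $\beta$ solved in closed form, followed by
bounded local refinement.  The effective pRF size is $\sigma/\sqrt{n}$, and
eccentricity/phase follow from the center.  Downstream analyses use:

- **Visual field coverage**: the proportion of an ROI's pRFs (binary disks of
  diameter $2\sigma/\sqrt{n}$) covering each point of the visual field, its
  eccentricity profile, and linear ($y = ax + b$) and generalized-logistic
  ($y = a + (b-a)/(1 + 10^{(c-x)\,d})$) fits to that profile.
- **Eccentricity bands**: proportions of pRF centers, or of TDI-weighted
  streamline endpoints, in the four annuli 0–5°, 5–10°, 10–20°, 20–40°.
- **Group statistics**: band × stream linear mixed models with a random
  intercept per subject, Type III F tests with Satterthwaite degrees of
  freedom, Tukey HSD post-hocs, paired t-tests, Cohen's *d* and partial
  $\eta^2$.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic conditions (6 subjects, one ventral-like and one lateral-like
population of 30 voxels each, noise set for a median variance explained of
0.6):

```bash
python analysis/01_simulate.py
python analysis/02_fit_prfs.py
python analysis/03_coverage.py
python analysis/05_stats.py
```

prints, among other things:

```
fitted 360 voxels in 12 populations; median VE = 0.620
mean proportion of pRF centers in the 0-5 deg band:
lateral    0.028
ventral    0.739
mean density slope and median pRF size by stream:
lateral -0.010       19.487
ventral -0.032        6.342
center_band_proportions: band x stream interaction F(3, 45.0) = 342.2, p = 5.59e-31
```

Read: the ventral-like population concentrates ~74 % of its pRF centers in
the central 5° while the lateral-like one holds ~3 % there; lateral pRFs are
three times larger; coverage falls off with eccentricity three times faster
ventrally; and the band × stream interaction that formalizes the contrast is
overwhelming.  `analysis/04_connectivity.py` shows the same contrast in
TDI-weighted endpoint proportions, and `analysis/06_parameter_recovery.py`
reports how faithfully the fitting stage recovers known parameters
(noise-free: exact to ~1e-4; at VE ≈ 0.6: r ≈ 0.93 for eccentricity).

A `prfconn` command-line tool exposes the same stages
(`prfconn run --out DIR [--config cfg.yaml] [--seed N]`, plus `simulate`,
`fit`, `coverage`, `connectivity`, `stats`, and `make-fixtures`).

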
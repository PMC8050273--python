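"""Parameter-recovery experiments: simulate known pRFs, fit, compare.

These are the package's standard self-checks: noise-free recovery should be
exact to optimizer tolerance, and noisy recovery (noise set per voxel so the
expected variance explained is 0.6) should correlate strongly with ground
truth across a population spanning the mapped field.
"""

from __future__ import annotations

import numpy as np

from .prf_fit import FitContext, FitOptions, fit_many
from .prf_model import HRFModel, PRFParams, canonical_hrf
from .stimulus import ApertureSequence, build_bar_design, generate_aperture
from .synthetic import generate_bold

__all__ = ["sample_recovery_population", "recovery_experiment",
           "noise_free_recovery"]


def sample_recovery_population(n_voxels: int = 100, max_ecc: float = 20.0,
                               sigma_range: tuple[float, float] = (1.0, 10.0),
                               n_range: tuple[float, float] = (0.2, 1.0),
                               seed: int = 0) -> list[PRFParams]:
    """Population spanning the mapped field: eccentricity uniform on
    [0, max_ecc], polar angle uniform, sigma and n uniform on their ranges."""
    rng = np.random.default_rng(seed)
    ecc = rng.uniform(0.0, max_ecc, n_voxels)
    ang = rng.uniform(0.0, 2 * np.pi, n_voxels)
    return [PRFParams(x=float(e * np.cos(a)), y=float(e * np.sin(a)),
                      sigma=float(rng.uniform(*sigma_range)),
                      n=float(rng.uniform(*n_range)), gain=1.0)
            for e, a in zip(ecc, ang)]


def _default_setup(grid_resolution: int, tr: float):
    aperture = generate_aperture(build_bar_design(), grid_resolution)
    return aperture, canonical_hrf(1.0), tr


def recovery_experiment(seed: int = 0, n_voxels: int = 100,
                        target_ve: float = 0.6, grid_resolution: int = 101,
                        tr: float = 2.0, n_replicates: int = 1,
                        aperture: ApertureSequence | None = None,
                        hrf: HRFModel | None = None,
                        context: FitContext | None = None) -> dict:
    """Noisy parameter recovery on ``n_replicates`` populations of
    ``n_voxels`` voxels.

    Noise is Gaussian, scaled per voxel so the expected variance explained is
    ``target_ve``.  Reports the median over replicates of the Pearson
    correlations between true and recovered eccentricity and size, and the
    median fitted VE.  Seeds for the replicates are spawned from ``seed``.
    """
    if aperture is None or hrf is None:
        aperture, hrf, tr = _default_setup(grid_resolution, tr)
    ctx = context or FitContext(aperture, hrf, tr, FitOptions())
    r_ecc, r_size, med_ve = [], [], []
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates) % (2 ** 31)
    for rep in range(n_replicates):
        truth = sample_recovery_population(n_voxels, seed=int(rep_seeds[2 * rep]))
        series = generate_bold(truth, aperture, hrf, tr, target_ve=target_ve,
                               seed=int(rep_seeds[2 * rep + 1]))
        fits = fit_many(series, aperture, hrf, context=ctx)
        te = np.array([p.eccentricity for p in truth])
        re_ = np.array([f.params.eccentricity for f in fits])
        ts = np.array([p.size for p in truth])
        rs = np.array([f.params.size for f in fits])
        r_ecc.append(np.corrcoef(te, re_)[0, 1])
        r_size.append(np.corrcoef(ts, rs)[0, 1])
        med_ve.append(np.median([f.ve_raw for f in fits]))
    return {"r_eccentricity": float(np.median(r_ecc)),
            "r_size": float(np.median(r_size)),
            "median_ve": float(np.median(med_ve)),
            "per_replicate_r_eccentricity": [float(v) for v in r_ecc],
            "per_replicate_r_size": [float(v) for v in r_size],
            "n_voxels": n_voxels, "n_replicates": n_replicates}


def noise_free_recovery(truth: list[PRFParams] | None = None,
                        grid_resolution: int = 101, tr: float = 2.0,
                        aperture: ApertureSequence | None = None,
                        hrf: HRFModel | None = None,
                        context: FitContext | None = None) -> dict:
    """Recovery without noise: worst-case center error (deg) and relative
    sigma error across a small spanning population."""
    if aperture is None or hrf is None:
        aperture, hrf, tr = _default_setup(grid_resolution, tr)
    if truth is None:
        truth = [PRFParams(x=4.0, y=-2.0, sigma=3.0, n=0.5, gain=2.0),
                 PRFParams(x=-8.0, y=6.0, sigma=5.0, n=0.3, gain=1.0),
                 PRFParams(x=0.5, y=0.5, sigma=1.0, n=1.0, gain=1.5),
                 PRFParams(x=12.0, y=9.0, sigma=7.0, n=0.6, gain=1.0)]
    series = generate_bold(truth, aperture, hrf, tr, noise_sd=0.0)
    ctx = context or FitContext(aperture, hrf, tr, FitOptions())
    fits = fit_many(series, aperture, hrf, context=ctx)
    center_err = [float(np.hypot(f.params.x - t.x, f.params.y - t.y))
                  for f, t in zip(fits, truth)]
    sigma_rel = [abs(f.params.sigma - t.sigma) / t.sigma for f, t in zip(fits, truth)]
    ve = [f.variance_explained for f in fits]
    return {"max_center_error_deg": max(center_err),
            "max_sigma_rel_error": max(sigma_rel),
            "min_ve": min(ve), "n_voxels": len(truth)}


# --------------------------------------------------------------------------
# group-level simulation experiments
# --------------------------------------------------------------------------

def stream_band_table(seed: int, profile_ventral=None, profile_lateral=None,
                      n_subjects: int = 20, n_voxels: int = 100,
                      heterogeneity: float = 0.3):
    """Long table of per-subject pRF-center band proportions for two streams.

    Each subject gets jittered variants of the stream profiles (see
    :func:`prfconn.synthetic.subject_profile`) and ``n_voxels`` sampled
    centers per stream; proportions use the default four bands.
    """
    import pandas as pd
    from dataclasses import replace
    from .bands import band_proportions
    from .synthetic import LATERAL_LIKE, VENTRAL_LIKE, sample_population, subject_profile

    pv = profile_ventral or VENTRAL_LIKE
    pl = profile_lateral or LATERAL_LIKE
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.generate_state(1)[0])
    seeds = ss.generate_state(2 * n_subjects + 1)[1:] % (2 ** 31)
    rows = []
    for s in range(n_subjects):
        for stream, prof, sd in (("ventral", pv, seeds[2 * s]),
                                 ("lateral", pl, seeds[2 * s + 1])):
            prof_s = subject_profile(replace(prof, n_voxels=n_voxels), rng,
                                     heterogeneity)
            pop = sample_population(prof_s, seed=int(sd))
            bp = band_proportions(np.array([p.eccentricity for p in pop]))
            for band, frac in zip(bp.bands.labels(), bp.fractions):
                rows.append({"subject": s, "stream": stream,
                             "band": band, "value": frac})
    return pd.DataFrame(rows)


def gaussian_null_table(seed: int, n_subjects: int = 20,
                        sd_subject: float = 0.05, sd_noise: float = 0.08):
    """Null long table drawn from the LMM's own model: Gaussian cell noise
    around band means identical in both streams (no interaction)."""
    import pandas as pd
    rng = np.random.default_rng(seed)
    band_means = {"0-5": 0.4, "5-10": 0.3, "10-20": 0.2, "20-40": 0.1}
    rows = []
    for s in range(n_subjects):
        b0 = rng.normal(0, sd_subject)
        for stream in ("ventral", "lateral"):
            for band, mu in band_means.items():
                rows.append({"subject": s, "stream": stream, "band": band,
                             "value": mu + b0 + rng.normal(0, sd_noise)})
    return pd.DataFrame(rows)


def interaction_power_experiment(seed: int = 0, n_replicates: int = 100,
                                 alpha: float = 0.01, **table_kwargs) -> dict:
    """Fraction of seeded replicates in which the band x stream interaction
    is detected for ventral-like vs lateral-like populations."""
    from .stats import band_by_stream_anova
    rep_seeds = np.random.SeedSequence((seed, 11)).generate_state(n_replicates) % (2 ** 31)
    hits = 0
    for s in rep_seeds:
        p = band_by_stream_anova(stream_band_table(int(s), **table_kwargs)
                                 ).effect("band:stream")["p"]
        hits += p < alpha
    return {"detection_rate": hits / n_replicates, "alpha": alpha,
            "n_replicates": n_replicates}


def null_calibration_experiment(seed: int = 0, n_replicates: int = 200,
                                alpha: float = 0.05) -> dict:
    """Type-I rate of the interaction test on null tables generated from the
    LMM's own Gaussian model (both streams share one generator)."""
    from .stats import band_by_stream_anova
    rep_seeds = np.random.SeedSequence((seed, 13)).generate_state(n_replicates) % (2 ** 31)
    rej = 0
    for s in rep_seeds:
        p = band_by_stream_anova(gaussian_null_table(int(s))
                                 ).effect("band:stream")["p"]
        rej += p < alpha
    return {"rejection_rate": rej / n_replicates, "alpha": alpha,
            "n_replicates": n_replicates}
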
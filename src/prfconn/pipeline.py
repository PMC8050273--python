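"""End-to-end orchestration: simulate -> fit -> coverage -> connectivity -> stats.

Every stage reads its inputs from and writes its outputs to a run directory,
so stages can be re-run individually; all randomness flows from the config
seed through a spawned ``numpy.random.SeedSequence`` tree, making re-runs
reproducible output-for-output.
"""

from __future__ import annotations

import hashlib
import json
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .bands import DEFAULT_BANDS
from .connectivity import (concatenate_ensemble, endpoint_band_proportions,
                           filter_streamlines, fwmt_percentage, intersect_roi,
                           life_validate, make_disk_roi)
from .coverage import (center_band_proportions, compute_vfc, density_vs_eccentricity,
                       fit_density_linear, fit_density_logistic, laterality_index,
                       median_size_by_band, visual_field_grid)
from .prf_fit import FitContext, FitOptions, apply_inclusion, fit_many
from .prf_model import canonical_hrf
from .stimulus import build_bar_design, generate_aperture
from .synthetic import (LATERAL_LIKE, VENTRAL_LIKE, PopulationProfile,
                        generate_bold, sample_population, synth_endpoints,
                        synth_evc_surface, synth_streamlines,
                        truncated_exponential_cdf)
from .stats import band_by_stream_anova, paired_stream_test, tukey_posthoc

__all__ = ["DEFAULT_CONFIG", "PipelineError", "run_pipeline", "profile_band_weights",
           "stage_simulate", "stage_fit", "stage_coverage", "stage_connectivity",
           "stage_stats"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stimulus": {},                       # BarDesign overrides
    "grid_resolution": 61,
    "tr": 2.0,
    "hrf_dt": 1.0,
    "simulate": {
        "n_subjects": 6,
        "n_voxels": 30,
        "target_ve": 0.6,
    },
    "fit": {"ve_min": 0.20, "sigma_floor": 0.21, "min_voxels": 10},
    "coverage": {"bin_width": 1.0, "coverage_resolution": 101},
    "connectivity": {
        "n_endpoints": 2000,
        "weight_dispersion": 0.5,
        "min_len": 4.0,
        "max_len": 200.0,
        "capture_dist": 2.0,
        "n_candidates": 5,
        "streamlines_per_candidate": 2000,
    },
    "output": {},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _merge(base: dict, override: dict) -> dict:
    out = deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _subject_streams(cfg):
    n = cfg["simulate"]["n_subjects"]
    return [(s, stream) for s in range(n) for stream in ("ventral", "lateral")]


def _profile_for(stream: str, subject: int, n_voxels: int, seed: int) -> PopulationProfile:
    base = VENTRAL_LIKE if stream == "ventral" else LATERAL_LIKE
    from dataclasses import replace
    return replace(base, n_voxels=n_voxels, seed=seed)


def profile_band_weights(profile: PopulationProfile,
                         bands=DEFAULT_BANDS) -> np.ndarray:
    """Analytic eccentricity-band probabilities of a population profile."""
    edges = np.asarray(bands.edges)
    if profile.ecc_distribution == "trunc-exp":
        cdf = np.array([truncated_exponential_cdf(e, profile.ecc_scale, profile.max_ecc)
                        for e in edges])
    else:
        cdf = np.clip(edges / profile.max_ecc, 0, 1) ** 2
    w = np.diff(cdf)
    return w / w.sum()


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> None:
    """Aperture + ground-truth populations + noisy BOLD, written per
    subject/stream."""
    design = build_bar_design(cfg["stimulus"])
    aperture = generate_aperture(design, cfg["grid_resolution"])
    pio.save_aperture_nifti(aperture, outdir / "aperture.nii.gz")
    hrf = canonical_hrf(cfg["hrf_dt"])
    root = np.random.SeedSequence(cfg["seed"])
    sim = cfg["simulate"]
    for (subject, stream), ss in zip(_subject_streams(cfg),
                                     root.spawn(2 * sim["n_subjects"])):
        seeds = ss.generate_state(2) % (2 ** 31)
        profile = _profile_for(stream, subject, sim["n_voxels"], int(seeds[0]))
        truth = sample_population(profile)
        series = generate_bold(truth, aperture, hrf, cfg["tr"],
                               target_ve=sim["target_ve"], seed=int(seeds[1]))
        tag = f"sub-{subject:02d}_{stream}"
        pd.DataFrame({"x": [p.x for p in truth], "y": [p.y for p in truth],
                      "sigma": [p.sigma for p in truth], "n": [p.n for p in truth],
                      "gain": [p.gain for p in truth]}).to_csv(
            outdir / f"truth_{tag}.tsv", sep="\t", index=False)
        pd.DataFrame(np.column_stack([s.values for s in series])).to_csv(
            outdir / f"bold_{tag}.tsv", sep="\t", index=False)


def stage_fit(cfg: dict, outdir: Path) -> None:
    """CSS fits for every simulated voxel, sharing one candidate grid."""
    aperture = pio.load_aperture_nifti(outdir / "aperture.nii.gz")
    hrf = canonical_hrf(cfg["hrf_dt"])
    ctx = FitContext(aperture, hrf, cfg["tr"], FitOptions())
    from .prf_model import VoxelTimeSeries
    for subject, stream in _subject_streams(cfg):
        tag = f"sub-{subject:02d}_{stream}"
        bold = pd.read_csv(outdir / f"bold_{tag}.tsv", sep="\t")
        series = [VoxelTimeSeries(values=bold[c].to_numpy(), tr=cfg["tr"])
                  for c in bold.columns]
        fits = fit_many(series, aperture, hrf, context=ctx)
        pio.save_fits_tsv(fits, outdir / f"fits_{tag}.tsv",
                          extra={"subject": subject, "stream": stream})


def stage_coverage(cfg: dict, outdir: Path) -> None:
    """Inclusion, VFC maps, density fits, indices, band summaries."""
    fitcfg, covcfg = cfg["fit"], cfg["coverage"]
    gx, gy = visual_field_grid(resolution=covcfg["coverage_resolution"])
    long_rows, summary_rows = [], []
    for subject, stream in _subject_streams(cfg):
        tag = f"sub-{subject:02d}_{stream}"
        fits = _load_fits(outdir / f"fits_{tag}.tsv")
        voxelset = apply_inclusion(fits, roi_label=stream, hemisphere="right",
                                   ve_min=fitcfg["ve_min"],
                                   sigma_floor=fitcfg["sigma_floor"],
                                   min_voxels=fitcfg["min_voxels"])
        if voxelset is None:
            continue
        bp = center_band_proportions(voxelset)
        for band, frac in zip(bp.bands.labels(), bp.fractions):
            long_rows.append({"subject": subject, "stream": stream,
                              "band": band, "value": frac})
        cmap = compute_vfc(voxelset, gx, gy)
        curve = density_vs_eccentricity(cmap, covcfg["bin_width"])
        lin = fit_density_linear(curve)
        logi = fit_density_logistic(curve)
        med = median_size_by_band(voxelset)
        summary_rows.append({
            "subject": subject, "stream": stream, "n_voxels": len(voxelset),
            "slope": lin.slope, "intercept": lin.intercept, "lin_adj_r2": lin.adj_r2,
            "logistic_a": logi.a, "logistic_b": logi.b, "logistic_c": logi.c,
            "logistic_d": logi.d, "logistic_adj_r2": logi.adj_r2,
            "laterality": laterality_index(cmap),
            "median_size": float(np.nanmedian([f.params.size for f in voxelset.fits])),
            **{f"median_size_band{i + 1}": m for i, m in enumerate(med)},
        })
    pd.DataFrame(long_rows).to_csv(outdir / "center_band_proportions.tsv",
                                   sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(outdir / "coverage_summary.tsv",
                                      sep="\t", index=False)


def stage_connectivity(cfg: dict, outdir: Path) -> None:
    """Synthetic EVC surface + endpoint sets per subject/stream, a small
    ensemble-tractography exercise, and the endpoint band long table."""
    ccfg = cfg["connectivity"]
    root = np.random.SeedSequence((cfg["seed"], 2))
    surface = synth_evc_surface(seed=int(root.generate_state(1)[0] % 2 ** 31))
    pio.save_surface_tsv(surface, outdir / "evc_surface.tsv")

    long_rows = []
    for (subject, stream), ss in zip(_subject_streams(cfg),
                                     root.spawn(2 * cfg["simulate"]["n_subjects"])):
        profile = VENTRAL_LIKE if stream == "ventral" else LATERAL_LIKE
        weights = profile_band_weights(profile)
        records = synth_endpoints(weights, ccfg["n_endpoints"], surface,
                                  weight_dispersion=ccfg["weight_dispersion"],
                                  seed=int(ss.generate_state(1)[0] % 2 ** 31))
        bp = endpoint_band_proportions(records)
        for band, frac in zip(bp.bands.labels(), bp.fractions):
            long_rows.append({"subject": subject, "stream": stream,
                              "band": band, "value": frac})
    pd.DataFrame(long_rows).to_csv(outdir / "endpoint_band_proportions.tsv",
                                   sep="\t", index=False)

    # ensemble demo: candidates -> length filter -> concatenation -> LiFE stub
    cand_seeds = np.random.SeedSequence((cfg["seed"], 3)).generate_state(
        ccfg["n_candidates"]) % (2 ** 31)
    max_angles = (2.9, 5.7, 11.5, 23.1, 47.2)
    candidates = [filter_streamlines(
        synth_streamlines(ccfg["streamlines_per_candidate"],
                          max_step_angle=max_angles[i % len(max_angles)],
                          seed=int(cand_seeds[i])),
        ccfg["min_len"], ccfg["max_len"]) for i in range(ccfg["n_candidates"])]
    roi = make_disk_roi(surface.vertices.mean(axis=0), 10.0, surface, label="roi")
    evc = make_disk_roi(surface.vertices[0] + 2.0, 10.0, surface, label="evc")
    # straight "bridge" streamlines between the two disks, mixed into the
    # ensemble so the pairwise intersection and the fWMT percentage are
    # exercised with a non-trivial answer
    bridge_rng = np.random.default_rng((cfg["seed"], 4))
    bridges = []
    for _ in range(max(ccfg["streamlines_per_candidate"] // 10, 1)):
        a = np.append(roi.vertices()[bridge_rng.integers(len(roi.vertex_indices))], 0.0)
        b = np.append(evc.vertices()[bridge_rng.integers(len(evc.vertex_indices))], 0.0)
        n_pts = max(int(np.linalg.norm(b - a)), 2)
        bridges.append(a + np.linspace(0, 1, n_pts + 1)[:, None] * (b - a))
    from .connectivity import Connectome
    candidates.append(filter_streamlines(Connectome(streamlines=bridges),
                                         ccfg["min_len"], ccfg["max_len"]))
    ensemble = life_validate(concatenate_ensemble(candidates))
    roi_tracts = intersect_roi(ensemble, roi, capture_dist=ccfg["capture_dist"])
    pair_tracts = intersect_roi(roi_tracts, roi, evc,
                                capture_dist=ccfg["capture_dist"])
    report = {
        "candidate_counts": [len(c) for c in candidates],
        "ensemble_count": len(ensemble),
        "roi_tracts": len(roi_tracts),
        "roi_to_evc_tracts": len(pair_tracts),
        "fwmt_percentage": (fwmt_percentage(len(roi_tracts), len(pair_tracts))
                            if len(roi_tracts) else None),
    }
    (outdir / "connectivity_report.json").write_text(json.dumps(report, indent=2))


def stage_stats(cfg: dict, outdir: Path) -> None:
    """LMM ANOVAs on center and endpoint band proportions + paired tests."""
    report = {}
    for name in ("center_band_proportions", "endpoint_band_proportions"):
        table = pd.read_csv(outdir / f"{name}.tsv", sep="\t")
        anova = band_by_stream_anova(table)
        report[name] = {
            "anova": anova.rows.to_dict(orient="records"),
            "tukey_band": tukey_posthoc(anova, "band").to_dict(orient="records"),
        }
    cov = pd.read_csv(outdir / "coverage_summary.tsv", sep="\t")
    for metric in ("median_size", "slope"):
        wide = cov.pivot_table(index="subject", columns="stream", values=metric)
        if {"ventral", "lateral"} <= set(wide.columns) and len(wide.dropna()) >= 3:
            r = paired_stream_test(wide[["ventral", "lateral"]].to_numpy())
            report[f"paired_{metric}"] = {
                "t": r.t, "df": r.df, "p": r.p, "cohens_d": r.cohens_d,
                "mean_diff_ventral_minus_lateral": r.mean_diff, "n_pairs": r.n_pairs,
            }
    (outdir / "stats_report.json").write_text(json.dumps(report, indent=2))


def _load_fits(path: Path):
    from .prf_fit import FitResult
    from .prf_model import PRFParams
    df = pd.read_csv(path, sep="\t")
    return [FitResult(params=PRFParams(x=r.x, y=r.y, sigma=r.sigma, n=r.n, gain=r.gain),
                      variance_explained=r.ve, converged=bool(r.converged),
                      at_sigma_floor=bool(r.at_sigma_floor))
            for r in df.itertuples()]


_STAGES = [("simulate", stage_simulate), ("fit", stage_fit),
           ("coverage", stage_coverage), ("connectivity", stage_connectivity),
           ("stats", stage_stats)]


def run_pipeline(config: dict | None, outdir: str | Path,
                 stages: list[str] | None = None) -> dict:
    """Run the pipeline end to end (or a subset of stages) into ``outdir``.

    Writes a provenance record (config, its hash, package version) and
    returns a summary of output paths.  A stage failure raises
    :class:`PipelineError` naming the stage; earlier outputs are preserved.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(cfg, sort_keys=True)
    from . import __version__
    (outdir / "provenance.json").write_text(json.dumps({
        "config": cfg, "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "package_version": __version__}, indent=2))
    pio.save_config(cfg, outdir / "config.yaml")
    for name, fn in _STAGES:
        if stages is not None and name not in stages:
            continue
        try:
            fn(cfg, outdir)
        except Exception as exc:   # noqa: BLE001 - re-raised with stage name
            raise PipelineError(name, exc) from exc
    return {"outdir": str(outdir),
            "outputs": sorted(p.name for p in outdir.iterdir())}
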
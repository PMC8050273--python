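"""Seeded synthetic ground truth for the whole analysis chain.

Generators emulate the statistical structure the analysis assumes:

* voxel populations whose pRF centers are either foveally concentrated
  ("ventral-like": truncated-exponential eccentricities) or peripherally
  extended ("lateral-like": uniform-by-area eccentricities), with sizes that
  grow linearly with eccentricity,
* noisy BOLD responses to the sweeping-bar aperture,
* a flat cortical sheet carrying a smooth, cortical-magnification-like
  eccentricity gradient standing in for early visual cortex (EVC),
* streamline endpoint sets with controlled eccentricity-band weights and
  positive track-density (TDI) weights,
* random-walk streamline polylines used to exercise filtering and ensemble
  concatenation.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import DEFAULT_BANDS, EccBands
from .prf_model import HRFModel, PRFParams, VoxelTimeSeries, predict_bold
from .stimulus import ApertureSequence

__all__ = ["PopulationProfile", "EccSurface", "VENTRAL_LIKE", "LATERAL_LIKE",
           "sample_population", "generate_bold", "noise_sd_for_target_ve",
           "synth_evc_surface", "synth_endpoints", "synth_streamlines",
           "truncated_exponential_cdf"]

SIGMA_MIN = 0.3   # deg; smallest sigma the generators produce (above the 0.21 fit floor)


@dataclass(frozen=True)
class PopulationProfile:
    """Generative description of one ROI's voxel population.

    ecc_distribution : "trunc-exp" (parameter = exponential scale, truncated
        at ``max_ecc``) or "uniform-area" (uniform over the disk of radius
        ``max_ecc``, i.e. density proportional to eccentricity).
    polar_kappa : von Mises concentration of pRF polar angles about the
        contralateral horizontal meridian (0 = uniform over the hemifield
        directions).
    size_s0, size_slope, size_jitter : sigma = s0 + slope * ecc + N(0, jitter),
        floored at ``SIGMA_MIN``.
    n_range : compressive exponent drawn uniformly from this interval.
    gain : response amplitude given to every voxel.
    """

    label: str
    ecc_distribution: str = "trunc-exp"
    ecc_scale: float = 3.0
    max_ecc: float = 40.0
    polar_kappa: float = 1.0
    size_s0: float = 1.5
    size_slope: float = 0.4
    size_jitter: float = 0.5
    n_range: tuple[float, float] = (0.2, 0.8)
    gain: float = 1.0
    n_voxels: int = 100
    hemisphere: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ecc_distribution not in ("trunc-exp", "uniform-area"):
            raise ValueError(f"unknown ecc_distribution {self.ecc_distribution!r}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")


#: foveally concentrated population: exponential eccentricities, scale 3 deg,
#: which puts ~80 % of centers inside the central 5 deg.
VENTRAL_LIKE = PopulationProfile(label="ventral-like", ecc_distribution="trunc-exp",
                                 ecc_scale=3.0, size_s0=3.0, size_slope=0.5)

#: peripherally extended population: uniform-by-area centers out to 35 deg
#: (~2 % inside the central 5 deg) with larger, shallower-growing pRFs.
LATERAL_LIKE = PopulationProfile(label="lateral-like", ecc_distribution="uniform-area",
                                 max_ecc=35.0, size_s0=6.0, size_slope=0.4)


def subject_profile(base: PopulationProfile, rng: np.random.Generator,
                    heterogeneity: float = 0.3) -> PopulationProfile:
    """Per-subject variant of a population profile.

    Real participants differ in how foveal or peripheral their voxel
    populations are; the group SEs printed for band proportions imply
    between-subject SDs far larger than multinomial counting noise.  The
    eccentricity-scale parameter (trunc-exp) or field limit (uniform-area) is
    jittered lognormally with the given SD of the log.
    """
    if base.ecc_distribution == "trunc-exp":
        return replace(base, ecc_scale=float(base.ecc_scale * np.exp(rng.normal(0, heterogeneity))))
    return replace(base, max_ecc=float(np.clip(
        base.max_ecc * np.exp(rng.normal(0, heterogeneity / 2)), 10.0, 40.0)))


def truncated_exponential_cdf(x: float, scale: float, max_ecc: float) -> float:
    """CDF of an exponential(scale) truncated to [0, max_ecc]."""
    x = min(max(x, 0.0), max_ecc)
    return float((1 - np.exp(-x / scale)) / (1 - np.exp(-max_ecc / scale)))


def sample_population(profile: PopulationProfile,
                      seed: int | None = None) -> list[PRFParams]:
    """Draw ``n_voxels`` ground-truth pRF parameter sets from ``profile``.

    Polar angles are contralateral: centered on the left horizontal meridian
    for right-hemisphere profiles and vice versa.
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    n = profile.n_voxels
    if profile.ecc_distribution == "trunc-exp":
        u = rng.uniform(0, 1 - np.exp(-profile.max_ecc / profile.ecc_scale), size=n)
        ecc = -profile.ecc_scale * np.log1p(-u)
    else:  # uniform-area: P(ecc < r) = (r / max_ecc)^2
        ecc = profile.max_ecc * np.sqrt(rng.uniform(size=n))
    mu = np.pi if profile.hemisphere == "right" else 0.0
    if profile.polar_kappa > 0:
        theta = rng.vonmises(mu, profile.polar_kappa, size=n)
    else:
        theta = rng.uniform(-np.pi, np.pi, size=n)
    sigma = profile.size_s0 + profile.size_slope * ecc + rng.normal(0, profile.size_jitter, size=n)
    sigma = np.maximum(sigma, SIGMA_MIN)
    n_exp = rng.uniform(*profile.n_range, size=n)
    return [PRFParams(x=float(e * np.cos(t)), y=float(e * np.sin(t)),
                      sigma=float(s), n=float(ne), gain=profile.gain)
            for e, t, s, ne in zip(ecc, theta, sigma, n_exp)]


def noise_sd_for_target_ve(signal: np.ndarray, target_ve: float) -> float:
    """Gaussian noise SD giving expected variance explained ``target_ve``.

    For white noise on top of the true model, E[VE] ~ var(signal) /
    (var(signal) + sd^2), so sd = sqrt(var(signal) (1 - VE) / VE).
    """
    if not (0 < target_ve < 1):
        raise ValueError("target_ve must lie in (0, 1)")
    v = float(np.var(np.asarray(signal, dtype=float)))
    return float(np.sqrt(v * (1 - target_ve) / target_ve))


def generate_bold(truth: list[PRFParams], aperture: ApertureSequence,
                  hrf: HRFModel, tr: float, noise_sd: float | np.ndarray = 0.0,
                  seed: int = 0, ar1: float = 0.0,
                  target_ve: float | None = None) -> list[VoxelTimeSeries]:
    """Forward-model BOLD plus i.i.d. (or AR(1)) Gaussian noise per voxel.

    ``noise_sd = 0`` reproduces the forward model exactly.  If ``target_ve``
    is given, the noise SD is set per voxel from that voxel's signal variance.
    """
    rng = np.random.default_rng(seed)
    noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (len(truth),))
    out = []
    for p, sd in zip(truth, noise_sd):
        clean = predict_bold(p, aperture, hrf, tr)
        if target_ve is not None:
            sd = noise_sd_for_target_ve(clean.values, target_ve) if np.ptp(clean.values) else 0.0
        if sd < 0:
            raise ValueError("noise_sd must be non-negative")
        eps = rng.normal(0.0, 1.0, size=len(clean.values))
        if ar1:
            for t in range(1, len(eps)):
                eps[t] += ar1 * eps[t - 1]
            eps *= np.sqrt(1 - ar1 ** 2)
        out.append(VoxelTimeSeries(values=clean.values + sd * eps, tr=tr))
    return out


@dataclass
class EccSurface:
    """Flat stand-in for the EVC cortical sheet.

    vertices : (V, 2) positions in mm on the sheet.
    eccentricity : (V,) degrees per vertex, smooth over the sheet.
    """

    vertices: np.ndarray
    eccentricity: np.ndarray
    bands: EccBands = field(default_factory=lambda: DEFAULT_BANDS)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.eccentricity = np.asarray(self.eccentricity, dtype=float)
        if self.vertices.shape != (len(self.eccentricity), 2):
            raise ValueError("vertices must be (V, 2) matching eccentricity")

    @property
    def n_vertices(self) -> int:
        return len(self.eccentricity)

    def band_of_vertex(self) -> np.ndarray:
        return self.bands.assign(self.eccentricity)


def _ecc_gradient(s: np.ndarray, max_ecc: float, n_bands_equal: int = 4) -> np.ndarray:
    """Eccentricity profile along [0, 1]: linear 0..5 on the first quarter,
    then log-spaced (octave doubling) to ``max_ecc``, so the default four
    bands occupy equal sheet extent — the flat analogue of cortical
    magnification."""
    first = max_ecc / 8.0   # 5 deg for a 40 deg field
    lin = s < 0.25
    out = np.empty_like(s)
    out[lin] = first * s[lin] / 0.25
    out[~lin] = first * 2.0 ** ((n_bands_equal - 1) * (s[~lin] - 0.25) / 0.75)
    return out


def synth_evc_surface(n_vertices: int = 4026, seed: int = 0,
                      max_ecc: float = 40.0) -> EccSurface:
    """Regular 1 mm sheet with a smooth eccentricity gradient spanning 0-40 deg.

    The gradient runs along a fixed 61-column axis so neighboring vertices
    never differ by more than ~1.9 deg; rows are added to reach
    ``n_vertices``.  A small seeded transverse jitter (< 0.05 deg) keeps the
    map non-degenerate without breaking smoothness.
    """
    if n_vertices < 100:
        raise ValueError("n_vertices must be at least 100")
    rng = np.random.default_rng(seed)
    n_cols = 61
    n_rows = int(np.ceil(n_vertices / n_cols))
    xs = np.arange(n_cols, dtype=float)          # mm, along the ecc gradient
    ys = np.arange(n_rows, dtype=float)
    gx, gy = np.meshgrid(xs, ys)
    verts = np.column_stack([gx.ravel(), gy.ravel()])[:n_vertices]
    s = verts[:, 0] / (n_cols - 1)
    ecc = _ecc_gradient(s, max_ecc)
    ecc = np.clip(ecc + rng.uniform(-0.05, 0.05, size=len(ecc)), 0.0, max_ecc)
    return EccSurface(vertices=verts, eccentricity=ecc)


def synth_endpoints(band_weights, n_endpoints: int, surface: EccSurface,
                    weight_dispersion: float = 0.0, seed: int = 0) -> list:
    """Endpoint records on surface vertices with given band weights.

    Band membership is multinomial in ``band_weights``; within a band the
    vertex is uniform.  TDI weights are lognormal with the given dispersion
    (sigma of log weight); dispersion 0 gives all-equal weights.

    Returns a list of :class:`prfconn.connectivity.EndpointRecord`.
    """
    from .connectivity import EndpointRecord
    w = np.asarray(band_weights, dtype=float)
    if len(w) != surface.bands.n_bands:
        raise ValueError("one weight per band required")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("band weights must sum to 1")
    rng = np.random.default_rng(seed)
    vert_band = surface.band_of_vertex()
    band_vertices = [np.flatnonzero(vert_band == b) for b in range(surface.bands.n_bands)]
    for b, bv in enumerate(band_vertices):
        if w[b] > 0 and len(bv) == 0:
            raise ValueError(f"surface has no vertices in band {b}")
    bands_drawn = rng.choice(len(w), size=n_endpoints, p=w)
    records = []
    for b in bands_drawn:
        v = int(rng.choice(band_vertices[b]))
        tdi = float(rng.lognormal(0.0, weight_dispersion)) if weight_dispersion > 0 else 1.0
        records.append(EndpointRecord(position=surface.vertices[v],
                                      eccentricity=float(surface.eccentricity[v]),
                                      tdi_weight=tdi))
    return records


def synth_streamlines(n: int, length_distribution: tuple[float, float] = (40.0, 15.0),
                      max_step_angle: float = 11.5, seed: int = 0,
                      step_size: float = 1.0, dtype=np.float64):
    """Random-walk streamline polylines with bounded per-step turning.

    Lengths (mm) are Gaussian with the given mean and SD, truncated below at
    one step; steps are exactly ``step_size`` mm with turning angles uniform
    in [0, max_step_angle] degrees.  Used only to exercise filtering and
    ensemble concatenation, not to emulate tracking physics.  ``dtype``
    controls point storage; float32 halves memory for very large connectomes
    at the cost of ~1e-5 mm arc-length rounding.

    Returns a :class:`prfconn.connectivity.Connectome`.
    """
    from .connectivity import Connectome
    rng = np.random.default_rng(seed)
    mean_len, sd_len = length_distribution
    if n == 0:
        return Connectome(streamlines=[], metadata={"max_step_angle": max_step_angle,
                                                    "step_size": step_size})
    lengths = np.maximum(rng.normal(mean_len, sd_len, size=n), step_size)
    n_steps = np.maximum(np.round(lengths / step_size).astype(int), 1)
    # walk the longest streamlines first so finished ones drop out of the
    # per-step vector ops (roughly a 3x saving over padding all to max length)
    n_steps = np.sort(n_steps)[::-1]
    max_steps = int(n_steps[0])

    pos = rng.uniform(0.0, 100.0, size=(n, 3))
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    max_ang = np.deg2rad(max_step_angle)

    points = np.zeros((n, max_steps + 1, 3), dtype=dtype)
    points[:, 0] = pos
    cur = pos
    for k in range(max_steps):
        a = int(np.searchsorted(-n_steps, -k, side="right"))  # active count
        cur = cur[:a] + step_size * d[:a]
        points[:a, k + 1] = cur
        # perturb direction within the turning cone
        ang = rng.uniform(0.0, max_ang, size=(a, 1))
        perp = rng.normal(size=(a, 3))
        d = d[:a]
        perp -= (perp * d).sum(axis=1, keepdims=True) * d
        norm = np.linalg.norm(perp, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        perp /= norm
        d = np.cos(ang) * d + np.sin(ang) * perp
        d /= np.linalg.norm(d, axis=1, keepdims=True)

    streamlines = [points[i, : n_steps[i] + 1] for i in range(n)]
    return Connectome(streamlines=streamlines,
                      metadata={"max_step_angle": max_step_angle, "step_size": step_size})
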
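"""Visual field coverage (VFC) analytics.

Coverage is the proportion of an ROI's pRFs — each modelled as a binary disk
of diameter 2*sigma/sqrt(n) at its center — covering each point of the visual
field.  Its eccentricity profile over the contralateral hemifield is
summarized with linear and generalized-logistic fits, and coverage asymmetries
with laterality and vertical-bias indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .bands import DEFAULT_BANDS, BandProportions, EccBands, band_proportions
from .prf_fit import ROIVoxelSet

__all__ = ["CoverageMap", "DensityCurve", "LinearFit", "LogisticFit",
           "visual_field_grid", "compute_vfc", "average_maps",
           "density_vs_eccentricity", "fit_density_linear", "fit_density_logistic",
           "generalized_logistic", "laterality_index", "vertical_bias_index",
           "center_band_proportions", "median_size_by_band"]


def visual_field_grid(extent: float = 40.0, resolution: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """Square degree grid (x right-positive, y up-positive) centered at fixation."""
    coords = np.linspace(-extent / 2, extent / 2, resolution)
    gx, gy = np.meshgrid(coords, coords)
    return gx, gy[::-1]


@dataclass
class CoverageMap:
    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray          # same shape as grid, values in [0, 1]
    hemisphere: str

    def __post_init__(self) -> None:
        if self.density.shape != self.grid_x.shape:
            raise ValueError("density must match the grid")
        if np.any(self.density < 0) or np.any(self.density > 1):
            raise ValueError("density must lie in [0, 1]")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")

    def contra_mask(self) -> np.ndarray:
        """The contralateral hemifield: right visual field for the left
        hemisphere and vice versa (the x = 0 meridian belongs to neither)."""
        return self.grid_x > 0 if self.hemisphere == "left" else self.grid_x < 0


@dataclass
class DensityCurve:
    ecc_bins: np.ndarray         # bin centers, deg
    mean_density: np.ndarray

    def __post_init__(self) -> None:
        if self.ecc_bins.shape != self.mean_density.shape:
            raise ValueError("bins and densities must align")


@dataclass
class LinearFit:
    slope: float
    intercept: float
    adj_r2: float
    degenerate: bool = False


@dataclass
class LogisticFit:
    """y = a + (b - a) / (1 + 10^((c - x) * d)).

    a and b are the asymptotes on the low and high side of the inflection c
    as written; which one is attained at high eccentricity depends on the
    sign of the steepness d, so the resolved values are reported too.
    """

    a: float
    b: float
    c: float
    d: float
    adj_r2: float
    converged: bool = True
    degenerate: bool = False

    @property
    def asymptote_low_ecc(self) -> float:
        return self.a if self.d > 0 else self.b

    @property
    def asymptote_high_ecc(self) -> float:
        return self.b if self.d > 0 else self.a


def compute_vfc(voxelset: ROIVoxelSet, grid_x: np.ndarray,
                grid_y: np.ndarray) -> CoverageMap:
    """Coverage map: mean over pRFs of the binary disk indicator.

    Each pRF covers the points within sigma/sqrt(n) (disk of diameter
    2*sigma/sqrt(n)) of its center, boundary inclusive.
    """
    if len(voxelset) == 0:
        raise ValueError("empty voxel set")
    acc = np.zeros_like(grid_x, dtype=float)
    for p in voxelset.params():
        r = p.size
        acc += ((grid_x - p.x) ** 2 + (grid_y - p.y) ** 2) <= r * r
    return CoverageMap(grid_x=grid_x, grid_y=grid_y, density=acc / len(voxelset),
                       hemisphere=voxelset.hemisphere)


def average_maps(maps: list[CoverageMap]) -> CoverageMap:
    """Group-level map: mean of per-subject coverage maps."""
    if not maps:
        raise ValueError("no maps to average")
    if any(m.density.shape != maps[0].density.shape or m.hemisphere != maps[0].hemisphere
           for m in maps):
        raise ValueError("maps must share grid and hemisphere")
    return CoverageMap(grid_x=maps[0].grid_x, grid_y=maps[0].grid_y,
                       density=np.mean([m.density for m in maps], axis=0),
                       hemisphere=maps[0].hemisphere)


def density_vs_eccentricity(cmap: CoverageMap, bin_width: float = 1.0) -> DensityCurve:
    """Mean density per eccentricity annulus over the contralateral hemifield."""
    ecc = np.hypot(cmap.grid_x, cmap.grid_y)
    mask = cmap.contra_mask()
    max_ecc = ecc[mask].max()
    edges = np.arange(0.0, max_ecc + bin_width, bin_width)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = mask & (ecc >= lo) & (ecc < hi)
        if sel.any():
            centers.append((lo + hi) / 2)
            means.append(cmap.density[sel].mean())
    return DensityCurve(ecc_bins=np.array(centers), mean_density=np.array(means))


def fit_density_linear(curve: DensityCurve) -> LinearFit:
    """OLS line through the density curve; adj R^2 with 2 parameters."""
    x, y = curve.ecc_bins, curve.mean_density
    if len(x) < 3:
        raise ValueError("need at least 3 bins")
    if np.ptp(y) == 0:
        return LinearFit(slope=0.0, intercept=float(y[0]), adj_r2=np.nan, degenerate=True)
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue ** 2
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     adj_r2=float(adj))


def generalized_logistic(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    """Four-parameter logistic y = a + (b - a) / (1 + 10^((c - x) * d));
    the value at x = c is (a + b) / 2."""
    return a + (b - a) / (1.0 + 10.0 ** ((c - x) * d))


def fit_density_logistic(curve: DensityCurve) -> LogisticFit:
    """Nonlinear least squares with multistart; adj R^2 with 4 parameters."""
    x, y = curve.ecc_bins, curve.mean_density
    if len(x) < 5:
        raise ValueError("need at least 5 bins")
    if np.ptp(y) == 0:
        return LogisticFit(a=float(y[0]), b=float(y[0]), c=np.nan, d=np.nan,
                           adj_r2=np.nan, degenerate=True)

    span = np.ptp(x)
    starts = [(y.max(), y.min(), c0, d0)
              for c0 in np.quantile(x, [0.25, 0.5, 0.75])
              for d0 in (-0.3, -0.05, 0.05, 0.3)]
    best, best_sse = None, np.inf
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                generalized_logistic, x, y, p0=p0, maxfev=5000,
                bounds=([-1, -1, x.min() - span, -10], [2, 2, x.max() + span, 10]))
        except RuntimeError:
            continue
        sse = float(np.sum((generalized_logistic(x, *popt) - y) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        return LogisticFit(a=np.nan, b=np.nan, c=np.nan, d=np.nan, adj_r2=np.nan,
                           converged=False)
    n = len(x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - best_sse / ss_tot
    adj = 1 - (1 - r2) * (n - 1) / (n - 4)
    return LogisticFit(a=float(best[0]), b=float(best[1]), c=float(best[2]),
                       d=float(best[3]), adj_r2=float(adj))


def laterality_index(cmap: CoverageMap) -> float:
    """(contra - ipsi) / (contra + ipsi) of mean coverage; 1 means fully
    contralateral."""
    contra = cmap.density[cmap.contra_mask()].mean()
    ipsi = cmap.density[~cmap.contra_mask() & (cmap.grid_x != 0)].mean()
    if contra + ipsi == 0:
        raise ValueError("zero total coverage: laterality undefined")
    return float((contra - ipsi) / (contra + ipsi))


def vertical_bias_index(cmap: CoverageMap) -> float:
    """(upper - lower) / (upper + lower) mean coverage over the contralateral
    hemifield; positive values mean an upper-field bias."""
    contra = cmap.contra_mask()
    upper = cmap.density[contra & (cmap.grid_y > 0)].mean()
    lower = cmap.density[contra & (cmap.grid_y < 0)].mean()
    if upper + lower == 0:
        raise ValueError("zero contralateral coverage: vertical bias undefined")
    return float((upper - lower) / (upper + lower))


def center_band_proportions(voxelset: ROIVoxelSet,
                            bands: EccBands = DEFAULT_BANDS) -> BandProportions:
    """Fraction of pRF-center eccentricities per band (out-of-range centers
    are excluded from the denominator and counted)."""
    ecc = np.array([p.eccentricity for p in voxelset.params()])
    return band_proportions(ecc, bands=bands)


def median_size_by_band(voxelset: ROIVoxelSet,
                        bands: EccBands = DEFAULT_BANDS) -> np.ndarray:
    """Median pRF size (sigma/sqrt(n)) among voxels centered in each band;
    NaN for empty bands."""
    ecc = np.array([p.eccentricity for p in voxelset.params()])
    size = np.array([p.size for p in voxelset.params()])
    idx = bands.assign(ecc)
    out = np.full(bands.n_bands, np.nan)
    for b in range(bands.n_bands):
        if np.any(idx == b):
            out[b] = np.median(size[idx == b])
    return out
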
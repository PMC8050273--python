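"""Eccentricity bands and per-band proportions.

The four bands 0-5, 5-10, 10-20, 20-40 degrees are used both for pRF centers
and for white-matter tract endpoints.  Bands are half-open ``[lo, hi)``; the
last band additionally includes its upper edge, so an item exactly at the
outer limit of the mapped field still counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class EccBands:
    """Strictly increasing band edges in degrees of visual angle."""

    edges: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 40.0)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or len(e) < 2:
            raise ValueError("EccBands needs at least two edges")
        if not np.all(np.diff(e) > 0):
            raise ValueError("EccBands edges must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1

    def labels(self) -> list[str]:
        return [f"{lo:g}-{hi:g}" for lo, hi in zip(self.edges[:-1], self.edges[1:])]

    def assign(self, ecc: np.ndarray) -> np.ndarray:
        """Band index per eccentricity; -1 for out-of-range values.

        Half-open convention: ecc == 5 falls in the 5-10 band; ecc equal to
        the final edge falls in the last band.
        """
        ecc = np.asarray(ecc, dtype=float)
        idx = np.searchsorted(self.edges, ecc, side="right") - 1
        idx[ecc == self.edges[-1]] = self.n_bands - 1
        out_of_range = (ecc < self.edges[0]) | (ecc > self.edges[-1])
        idx = np.where(out_of_range, -1, idx)
        return idx.astype(int)


DEFAULT_BANDS = EccBands()


@dataclass
class BandProportions:
    """Per-band fractions of in-range items (sums to 1)."""

    fractions: np.ndarray
    n_items: int
    n_excluded: int = 0
    bands: EccBands = field(default_factory=lambda: DEFAULT_BANDS)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (self.bands.n_bands,):
            raise ValueError("one fraction per band required")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def band_proportions(ecc: np.ndarray, bands: EccBands = DEFAULT_BANDS,
                     weights: np.ndarray | None = None) -> BandProportions:
    """Fraction of (optionally weighted) items per band.

    Items beyond the last edge are excluded from the denominator and counted
    in ``n_excluded``.
    """
    ecc = np.asarray(ecc, dtype=float)
    idx = bands.assign(ecc)
    in_range = idx >= 0
    if weights is None:
        w = np.ones_like(ecc)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    total = w[in_range].sum()
    if total <= 0:
        raise ValueError("no in-range items (or zero total weight)")
    fr = np.bincount(idx[in_range], weights=w[in_range], minlength=bands.n_bands) / total
    return BandProportions(fr, n_items=int(in_range.sum()),
                           n_excluded=int((~in_range).sum()), bands=bands)
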
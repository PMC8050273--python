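"""Functionally defined white-matter tract quantification.

Tractography itself (FOD estimation, probabilistic tracking, LiFE validation)
is a contract boundary: this module consumes streamline sets — from files or
the synthetic generator — and implements the downstream quantification:
length filtering, ensemble concatenation, ROI intersection, tract percentages,
endpoint eccentricity assignment against a surface map, and TDI-weighted
eccentricity-band proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .bands import DEFAULT_BANDS, BandProportions, EccBands, band_proportions
from .synthetic import EccSurface

__all__ = ["Connectome", "EndpointRecord", "SurfaceROI", "arc_lengths",
           "filter_streamlines", "concatenate_ensemble", "life_validate",
           "intersect_roi", "fwmt_percentage", "assign_endpoint_eccentricity",
           "endpoint_band_proportions", "make_disk_roi"]


@dataclass
class Connectome:
    """A set of streamline polylines (points in mm) plus tracking metadata."""

    streamlines: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.streamlines:
            if len(s) < 2:
                raise ValueError("every streamline needs at least 2 points")

    def __len__(self) -> int:
        return len(self.streamlines)

    def endpoints(self) -> np.ndarray:
        """(N, 2, D) array of first and last points of every streamline."""
        if not self.streamlines:
            return np.empty((0, 2, 3))
        return np.stack([np.stack([np.asarray(s[0], float), np.asarray(s[-1], float)])
                         for s in self.streamlines])


@dataclass
class EndpointRecord:
    """A streamline endpoint with its assigned eccentricity and TDI weight."""

    position: np.ndarray
    eccentricity: float
    tdi_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.tdi_weight <= 0:
            raise ValueError("tdi_weight must be positive")
        if self.eccentricity < 0:
            raise ValueError("eccentricity must be non-negative")


@dataclass
class SurfaceROI:
    """A set of vertices on an :class:`EccSurface`."""

    surface: EccSurface
    vertex_indices: np.ndarray
    label: str
    kind: str = "functional"            # or "disk"
    center: np.ndarray | None = None    # disk ROIs only
    radius: float | None = None

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=int)
        if len(self.vertex_indices) == 0:
            raise ValueError("SurfaceROI must be non-empty")
        if self.kind not in ("functional", "disk"):
            raise ValueError("kind must be 'functional' or 'disk'")

    def vertices(self) -> np.ndarray:
        return self.surface.vertices[self.vertex_indices]


def arc_lengths(c: Connectome) -> np.ndarray:
    """Polyline arc length (mm) of every streamline."""
    return np.array([float(np.linalg.norm(np.diff(np.asarray(s, float), axis=0),
                                          axis=1).sum())
                     for s in c.streamlines])


def filter_streamlines(c: Connectome, min_len: float = 4.0,
                       max_len: float = 200.0) -> Connectome:
    """Retain streamlines with min_len <= arc length <= max_len (inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    lengths = arc_lengths(c)
    keep = (lengths >= min_len) & (lengths <= max_len)
    return Connectome(streamlines=[s for s, k in zip(c.streamlines, keep) if k],
                      metadata=dict(c.metadata))


def concatenate_ensemble(candidates: Sequence[Connectome]) -> Connectome:
    """Multiset union of candidate connectomes (no deduplication), keeping
    per-candidate provenance counts and metadata."""
    streamlines: list = []
    provenance = []
    for c in candidates:
        streamlines.extend(c.streamlines)
        provenance.append({"n_streamlines": len(c), **c.metadata})
    return Connectome(streamlines=streamlines, metadata={"candidates": provenance})


def life_validate(c: Connectome,
                  retain: Callable[[np.ndarray], np.ndarray] | None = None) -> Connectome:
    """Streamline-validation stage as a pluggable pass-through contract.

    Real pipelines cull streamlines that do not contribute to predicting the
    diffusion signal (linear fascicle evaluation); here ``retain`` is an
    arbitrary predicate over streamline indices, and the default keeps all.
    """
    if retain is None:
        return Connectome(streamlines=list(c.streamlines), metadata=dict(c.metadata))
    keep = np.asarray(retain(np.arange(len(c))), dtype=bool)
    if keep.shape != (len(c),):
        raise ValueError("retain must return one flag per streamline")
    return Connectome(streamlines=[s for s, k in zip(c.streamlines, keep) if k],
                      metadata=dict(c.metadata))


def _endpoint_near(endpoints: np.ndarray, roi: SurfaceROI, capture: float) -> np.ndarray:
    """(N, 2) flags: is each of the two endpoints within ``capture`` of the ROI?

    Streamline points are 3-D while the synthetic sheet is 2-D; the sheet is
    embedded at z = 0 and distances are Euclidean in the embedding.
    """
    verts = roi.vertices()
    if verts.shape[1] < endpoints.shape[2]:
        verts = np.column_stack([verts, np.zeros((len(verts),
                                                  endpoints.shape[2] - verts.shape[1]))])
    tree = cKDTree(verts)
    d, _ = tree.query(endpoints.reshape(-1, endpoints.shape[2]))
    return (d <= capture).reshape(-1, 2)


def intersect_roi(c: Connectome, roi: SurfaceROI, evc: SurfaceROI | None = None,
                  capture_dist: float = 2.0) -> Connectome:
    """Functionally defined tracts: streamlines with an endpoint within
    ``capture_dist`` mm of ``roi`` and — if ``evc`` is given — the *other*
    endpoint within ``capture_dist`` of ``evc``."""
    if len(c) == 0:
        return Connectome(streamlines=[], metadata=dict(c.metadata))
    ep = c.endpoints()
    near_roi = _endpoint_near(ep, roi, capture_dist)
    if evc is None:
        keep = near_roi.any(axis=1)
    else:
        near_evc = _endpoint_near(ep, evc, capture_dist)
        keep = (near_roi[:, 0] & near_evc[:, 1]) | (near_roi[:, 1] & near_evc[:, 0])
    return Connectome(streamlines=[s for s, k in zip(c.streamlines, keep) if k],
                      metadata={**c.metadata, "roi": roi.label,
                                "evc": evc.label if evc else None})


def fwmt_percentage(roi_tracts: int, roi_to_evc_tracts: int) -> float:
    """Percentage of an ROI's tracts that also reach EVC."""
    if roi_tracts <= 0:
        raise ValueError("fWMT percentage undefined for zero ROI tracts")
    if not (0 <= roi_to_evc_tracts <= roi_tracts):
        raise ValueError("roi_to_evc_tracts must lie in [0, roi_tracts]")
    return 100.0 * roi_to_evc_tracts / roi_tracts


def assign_endpoint_eccentricity(positions: np.ndarray, surface: EccSurface,
                                 max_dist: float = 2.0,
                                 tdi_weights: np.ndarray | None = None
                                 ) -> tuple[list[EndpointRecord], int]:
    """Each endpoint takes the eccentricity of its nearest surface vertex
    within ``max_dist`` mm; farther endpoints are dropped.

    Returns (records, n_dropped).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2:
        raise ValueError("positions must be (N, D)")
    verts = surface.vertices
    if verts.shape[1] < positions.shape[1]:
        verts = np.column_stack([verts, np.zeros((len(verts),
                                                  positions.shape[1] - verts.shape[1]))])
    tree = cKDTree(verts)
    d, idx = tree.query(positions)
    if tdi_weights is None:
        tdi_weights = np.ones(len(positions))
    records = [EndpointRecord(position=positions[i],
                              eccentricity=float(surface.eccentricity[idx[i]]),
                              tdi_weight=float(tdi_weights[i]))
               for i in range(len(positions)) if d[i] <= max_dist]
    return records, int((d > max_dist).sum())


def endpoint_band_proportions(records: list[EndpointRecord],
                              bands: EccBands = DEFAULT_BANDS,
                              weighted: bool = True) -> BandProportions:
    """TDI-weighted (or unweighted) fraction of endpoint mass per band."""
    if not records:
        raise ValueError("no endpoint records")
    ecc = np.array([r.eccentricity for r in records])
    w = np.array([r.tdi_weight for r in records]) if weighted else None
    return band_proportions(ecc, bands=bands, weights=w)


def make_disk_roi(center: np.ndarray, radius: float, surface: EccSurface,
                  label: str = "disk") -> SurfaceROI:
    """Vertices within ``radius`` mm (sheet distance) of ``center``.

    Used for the 5 mm size-control ROIs and the 10 mm disk standing in for a
    functional ROI matched in size across subjects.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    d = np.linalg.norm(surface.vertices - center[None, :], axis=1)
    idx = np.flatnonzero(d <= radius)
    if len(idx) == 0:
        raise ValueError("disk ROI captured no vertices (radius below vertex spacing?)")
    return SurfaceROI(surface=surface, vertex_indices=idx, label=label,
                      kind="disk", center=center, radius=radius)
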
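"""Compressive spatial summation (CSS) pRF forward model.

A voxel's population receptive field is an isotropic 2-D Gaussian at (x, y)
with SD sigma; its response to a binary aperture frame is the stimulus-Gaussian
overlap raised to a compressive exponent n (0 < n <= 1), applied *before*
temporal convolution with the HRF.  The effective pRF size is sigma/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .stimulus import ApertureSequence

__all__ = ["PRFParams", "HRFModel", "VoxelTimeSeries", "gaussian_field",
           "predict_neural", "canonical_hrf", "predict_bold"]

N_MIN = 0.01   # lower bound on the compressive exponent


@dataclass(frozen=True)
class PRFParams:
    """CSS model state for one voxel.

    x, y : pRF center in degrees (x right-positive, y up-positive)
    sigma : Gaussian SD in degrees (> 0)
    n : compressive spatial summation exponent, 0 < n <= 1
    gain : response amplitude in signal units per unit neural response
    """

    x: float
    y: float
    sigma: float
    n: float = 1.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 < self.n <= 1):
            raise ValueError("n must lie in (0, 1]")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def phase(self) -> float:
        return float(np.arctan2(self.y, self.x))

    @property
    def size(self) -> float:
        """Effective pRF size sigma/sqrt(n); equals sigma when n = 1."""
        return self.sigma / np.sqrt(self.n)


@dataclass(frozen=True)
class HRFModel:
    """Sampled hemodynamic impulse response at uniform spacing ``dt``."""

    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.samples.ndim != 1 or len(self.samples) == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")


@dataclass
class VoxelTimeSeries:
    """One voxel's BOLD signal, one value per volume of length ``tr`` seconds."""

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


def gaussian_field(params: PRFParams, grid_x: np.ndarray, grid_y: np.ndarray,
                   pixel_area: float) -> np.ndarray:
    """Unit-volume isotropic Gaussian evaluated at pixel centers.

    Scaled by ``pixel_area / (2 pi sigma^2)`` so the untruncated continuous
    integral is 1; no renormalization after truncation by the grid, which keeps
    response amplitudes grid-resolution independent and lets out-of-aperture
    pRFs show up as small overlap mass.
    """
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = (grid_x - params.x) ** 2 + (grid_y - params.y) ** 2
    return pixel_area / (2 * np.pi * params.sigma ** 2) * np.exp(-d2 / (2 * params.sigma ** 2))


def predict_neural(params: PRFParams, aperture: ApertureSequence) -> np.ndarray:
    """Per-frame neural response r_t = (sum_pixels S_t * G)^n.

    Blank frames give 0; n = 1 reduces to linear summation; a full-field frame
    over a well-contained Gaussian gives ~1 for any n.
    """
    g = gaussian_field(params, aperture.grid_x, aperture.grid_y, aperture.pixel_area)
    overlap = aperture.frames.reshape(aperture.n_frames, -1) @ g.ravel()
    return np.clip(overlap, 0.0, None) ** params.n


def canonical_hrf(dt: float = 1.0, duration: float = 32.0) -> HRFModel:
    """Canonical double-gamma HRF (peak ~5 s, undershoot ~15 s), unit peak.

    Difference of gamma densities (shapes 6 and 16, undershoot ratio 1/6),
    sampled at ``dt`` on [0, duration) and normalized to a maximum of 1.
    """
    if not (0 < dt <= 1):
        raise ValueError("dt must lie in (0, 1]")
    t = np.arange(0.0, duration, dt)
    h = _gamma_dist.pdf(t, 6.0) - _gamma_dist.pdf(t, 16.0) / 6.0
    return HRFModel(samples=h / h.max(), dt=dt)


def _check_multiple(a: float, b: float, what: str) -> int:
    k = a / b
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError(f"{what}: {a} is not a positive integer multiple of {b}")
    return int(round(k))


def predict_bold(params: PRFParams, aperture: ApertureSequence, hrf: HRFModel,
                 tr: float) -> VoxelTimeSeries:
    """Predicted BOLD: gain x (neural response upsampled to hrf.dt, convolved
    with the HRF, sampled at volume onsets every ``tr`` seconds).

    ``hrf.dt`` must divide both the frame duration and ``tr``.
    """
    r = predict_neural(params, aperture)
    values = convolve_neural(r, aperture.frame_duration, hrf, tr)
    return VoxelTimeSeries(values=params.gain * values, tr=tr)


def convolve_neural(neural: np.ndarray, frame_duration: float, hrf: HRFModel,
                    tr: float) -> np.ndarray:
    """HRF convolution + TR resampling of a per-frame neural response.

    Shared by the forward model and the fitting grid (which convolves many
    candidate responses at once: ``neural`` may be (T,) or (T, K)).
    """
    up = _check_multiple(frame_duration, hrf.dt, "frame_duration / hrf.dt")
    down = _check_multiple(tr, hrf.dt, "tr / hrf.dt")
    neural = np.asarray(neural, dtype=float)
    one_d = neural.ndim == 1
    if one_d:
        neural = neural[:, None]
    fine = np.repeat(neural, up, axis=0)              # piecewise-constant upsample
    # causal convolution, truncated to the run length
    from scipy.signal import fftconvolve
    conv = fftconvolve(fine, hrf.samples[:, None] * hrf.dt, axes=0)[: fine.shape[0]]
    n_vol = fine.shape[0] // down
    out = conv[np.arange(n_vol) * down]
    return out[:, 0] if one_d else out
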
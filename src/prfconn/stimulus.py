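"""Wide-field sweeping-bar aperture stimulus.

A bar of fixed width sweeps a square visual field in four orientations
(0, 45, 90, 135 deg), two opposed directions each, in equal steps.  The model
input is the *binarized* aperture movie: carrier imagery is never rendered.

Timing convention
-----------------
The printed design (5.7 deg bar, 40 deg field, 8 sweeps of 24 s = 12 steps of
2 s, blanks replacing the second half of each diagonal sweep) only reconciles
with a 204 s run if a 12 s blank baseline precedes the sweeps and the diagonal
blanks *replace* bar steps rather than extend the run.  That convention is
adopted here and exposed through ``blank_rule``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["BarDesign", "ApertureSequence", "build_bar_design",
           "generate_aperture", "schedule_duration"]

#: directions (deg) the bar *moves* in, for a bar oriented at ``o``:
#: the two directions orthogonal to the bar.
_CARDINAL = (0.0, 90.0)


@dataclass(frozen=True)
class BarDesign:
    """Geometry and timing of the sweeping-bar protocol."""

    field_extent: float = 40.0          # square side, deg
    bar_width: float = 5.7              # deg
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    steps_per_sweep: int = 12
    step_duration: float = 2.0          # s
    blank_rule: str = "replace_second_half_of_diagonals"
    baseline_duration: float = 12.0     # s
    carrier_rate: float = 8.0           # Hz, metadata only

    def __post_init__(self) -> None:
        for name in ("field_extent", "bar_width", "steps_per_sweep", "step_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BarDesign.{name} must be positive")
        if self.bar_width > self.field_extent:
            raise ValueError("BarDesign.bar_width cannot exceed field_extent")
        if self.baseline_duration < 0:
            raise ValueError("BarDesign.baseline_duration must be non-negative")
        if len(set(self.orientations)) != len(self.orientations):
            raise ValueError("BarDesign.orientations must be distinct")
        if self.blank_rule not in ("replace_second_half_of_diagonals", "none"):
            raise ValueError(f"unknown blank_rule {self.blank_rule!r}")

    @property
    def n_directions(self) -> int:
        """Two opposed sweep directions per bar orientation."""
        return 2 * len(self.orientations)

    def sweep_directions(self) -> list[float]:
        """Motion direction (deg, CCW from +x) of each sweep, canonical order."""
        out = []
        for o in self.orientations:
            # bar oriented at o moves orthogonally: o+90 and o-90
            out.extend([(o + 90.0) % 360.0, (o - 90.0) % 360.0])
        return out


@dataclass
class ApertureSequence:
    """Binary aperture movie over a square degree grid centered at fixation."""

    frames: np.ndarray      # (T, H, W) in {0, 1}
    grid_x: np.ndarray      # (H, W) deg, right-positive
    grid_y: np.ndarray      # (H, W) deg, up-positive
    frame_duration: float   # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if not np.isin(self.frames, (0, 1)).all():
            raise ValueError("frames must be binary")
        if self.grid_x.shape != self.frames.shape[1:]:
            raise ValueError("grid does not match frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def pixel_area(self) -> float:
        """Area (deg^2) of one grid pixel."""
        dx = float(self.grid_x[0, 1] - self.grid_x[0, 0])
        return dx * dx


def build_bar_design(config: Mapping[str, object] | None = None) -> BarDesign:
    """Validated :class:`BarDesign`; defaults reproduce the printed protocol.

    ``config`` keys override individual fields; unknown keys raise.
    """
    config = dict(config or {})
    known = set(BarDesign.__dataclass_fields__)
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown BarDesign fields: {sorted(unknown)}")
    if "orientations" in config:
        config["orientations"] = tuple(float(v) for v in config["orientations"])
    return BarDesign(**config)   # type: ignore[arg-type]


def schedule_duration(design: BarDesign) -> float:
    """Total run duration (s): baseline + one steps_per_sweep block per direction.

    Blanks that *replace* bar steps do not change the duration.
    """
    return design.baseline_duration + design.n_directions * design.steps_per_sweep * design.step_duration


def _square_grid(extent: float, resolution: int) -> tuple[np.ndarray, np.ndarray]:
    if resolution < 3 or resolution % 2 == 0:
        raise ValueError("grid_resolution must be odd and >= 3")
    half = extent / 2.0
    # pixel centers; the middle pixel sits exactly at fixation
    coords = (np.arange(resolution) - (resolution - 1) / 2) * (extent / resolution)
    assert abs(coords[resolution // 2]) < 1e-12
    gx, gy = np.meshgrid(coords, coords)
    gy = gy[::-1]            # row 0 is the top of the visual field (y up-positive)
    del half
    return gx, gy


def generate_aperture(design: BarDesign, grid_resolution: int = 101) -> ApertureSequence:
    """Render the binary bar-aperture movie for ``design``.

    Bar centers move uniformly from -(E-w)/2 to +(E-w)/2 along each sweep
    direction, so the bar is always fully inside the field and its swept area
    tiles the full extent.  Opposite directions traverse the same positions in
    reversed order.  Under the diagonal blank rule, the final
    ``floor(steps/2)`` frames of every diagonal-direction sweep are blank.
    Baseline blanks precede the sweeps.
    """
    gx, gy = _square_grid(design.field_extent, grid_resolution)
    e, w = design.field_extent, design.bar_width
    steps = design.steps_per_sweep
    if steps > 1:
        centers = -((e - w) / 2) + np.arange(steps) * (e - w) / (steps - 1)
    else:
        centers = np.array([0.0])

    n_baseline = int(round(design.baseline_duration / design.step_duration))
    frames = []
    zeros = np.zeros_like(gx, dtype=np.uint8)
    frames.extend([zeros] * n_baseline)
    n_blank = steps // 2
    for direction in design.sweep_directions():
        theta = np.deg2rad(direction)
        proj = gx * np.cos(theta) + gy * np.sin(theta)
        diagonal = not np.isclose(direction % 90.0, 0.0)
        for k, c in enumerate(centers):
            blank = (design.blank_rule == "replace_second_half_of_diagonals"
                     and diagonal and k >= steps - n_blank)
            if blank:
                frames.append(zeros)
            else:
                frames.append((np.abs(proj - c) <= w / 2).astype(np.uint8))
    return ApertureSequence(frames=np.stack(frames), grid_x=gx, grid_y=gy,
                            frame_duration=design.step_duration)
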
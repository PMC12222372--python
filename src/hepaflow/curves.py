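"""Time-activity curves on the acquisition frame schedule and the 1-s grid.

Dynamic PET data arrive as per-frame mean activities on an irregular frame
schedule (here 14x5 s, 3x10 s, 3x20 s, 4x30 s; 280 s total).  The kinetic
recursion, however, runs on a regular 1-s grid t = 1..280, with every curve
defined as 0 for t <= 0.  This module holds both representations and the
conversions between them:

* :func:`interpolate_to_seconds` — frame means, anchored at frame midpoints,
  linearly interpolated to every second (zero anchor at t = 0, constant
  extrapolation past the last midpoint);
* :func:`frame_average` — the inverse direction, averaging 1-s samples back
  onto a frame schedule;
* :func:`shift` — integer-second delay with left zero-padding, used for the
  transit-delay terms of the kinetic models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRID_END_S",
    "ROLE_LABELS",
    "ScheduleError",
    "CoverageError",
    "DelayError",
    "FrameSchedule",
    "FrameTAC",
    "SampledCurve",
    "interpolate_to_seconds",
    "frame_average",
    "shift",
    "clip_negative",
]

#: Default end of the 1-s sampling grid (seconds); the study's scan length.
GRID_END_S = 280

#: Recognised curve role tags.
ROLE_LABELS = ("aorta", "portal_vein", "liver", "spleen", "model")


class ScheduleError(ValueError):
    """Raised for non-contiguous, non-increasing or empty frame schedules."""


class CoverageError(ValueError):
    """Raised when a schedule extends past the sampled curve it is applied to."""


class DelayError(ValueError):
    """Raised for negative or non-integer delays."""


@dataclass(frozen=True, eq=False)
class FrameSchedule:
    """Contiguous, strictly increasing acquisition frames in seconds."""

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.ndim != 1 or start.size == 0 or start.shape != end.shape:
            raise ScheduleError("schedule needs matching, non-empty start/end arrays")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(end)):
            raise ScheduleError("schedule times must be finite")
        if np.any(end <= start):
            raise ScheduleError("every frame must have positive duration")
        if start.size > 1 and not np.allclose(start[1:], end[:-1]):
            raise ScheduleError("frames must be contiguous and non-overlapping")

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The 24-frame study schedule: 14x5 s, 3x10 s, 3x20 s, 4x30 s."""
        durations = [5.0] * 14 + [10.0] * 3 + [20.0] * 3 + [30.0] * 4
        edges = np.concatenate([[0.0], np.cumsum(durations)])
        return cls(edges[:-1], edges[1:])

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def span(self) -> float:
        """End of the last frame in seconds."""
        return float(self.frame_end[-1])


@dataclass(eq=False)
class FrameTAC:
    """Per-frame mean activities (Bq/mL) on a :class:`FrameSchedule`.

    Decay- and scatter-corrected PET means can go slightly negative; such
    values are only accepted when ``allow_negative`` is set.
    """

    schedule: FrameSchedule
    values: np.ndarray
    label: str = "model"
    allow_negative: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        self.values = values
        if values.ndim != 1 or values.size != self.schedule.n_frames:
            raise ValueError("values must be 1-D with one entry per frame")
        if not np.all(np.isfinite(values)):
            raise ValueError("frame activities must be finite")
        if not self.allow_negative and np.any(values < 0):
            raise ValueError(
                "negative activities present; pass allow_negative=True to keep them"
            )


@dataclass(eq=False)
class SampledCurve:
    """Activity (Bq/mL) at t = 1..T seconds on a fixed 1-s grid.

    ``values[i - 1]`` is the activity at t = i; by convention the curve is
    zero for t <= 0.
    """

    values: np.ndarray
    label: str = "model"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        self.values = values
        if values.ndim != 1 or values.size == 0:
            raise ValueError("a sampled curve needs a non-empty 1-D value array")
        if not np.all(np.isfinite(values)):
            raise ValueError("sampled activities must be finite")

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds, 1..T."""
        return np.arange(1, self.values.size + 1, dtype=float)

    @property
    def duration(self) -> int:
        return int(self.values.size)


def interpolate_to_seconds(
    tac: FrameTAC, grid_end: int = GRID_END_S, method: str = "midpoint"
) -> SampledCurve:
    """Linearly interpolate frame means onto the 1-s grid t = 1..``grid_end``.

    Both methods produce a piecewise-linear curve with anchors at the frame
    midpoints, a zero anchor at t = 0 and constant extrapolation from the
    last midpoint to the end of the grid; they differ in the anchor values:

    * ``"midpoint"`` (default) anchors each frame's measured mean directly
      at the frame midpoint — exact whenever the underlying curve is linear
      across each frame;
    * ``"conserving"`` solves for the anchor values such that the resulting
      curve's frame averages reproduce the measured means exactly.  This
      removes the systematic flattening that midpoint anchoring causes
      around sharp peaks (a frame mean underestimates a peak value), at the
      price of no longer passing through the measured values themselves.
    """
    if tac.schedule.span > grid_end:
        raise ScheduleError(
            f"schedule ends at {tac.schedule.span} s, past the {grid_end} s grid"
        )
    anchors_t = np.concatenate([[0.0], tac.schedule.midpoints])
    t = np.arange(1, grid_end + 1, dtype=float)
    if method == "midpoint":
        anchors_v = np.concatenate([[0.0], tac.values])
    elif method == "conserving":
        anchors_v = np.concatenate(
            [[0.0], _conserving_anchors(tac.schedule, tac.values, grid_end)]
        )
    else:
        raise ValueError(f"unknown interpolation method '{method}'")
    # np.interp clamps to the last anchor value on the right, which is
    # exactly the constant-extrapolation convention wanted here.
    values = np.interp(t, anchors_t, anchors_v)
    return SampledCurve(values, label=tac.label)


def _conserving_anchors(
    schedule: FrameSchedule, frame_values: np.ndarray, grid_end: int
) -> np.ndarray:
    """Anchor values whose piecewise-linear curve frame-averages to the data.

    Expands the curve in the hat-function basis of the midpoint anchors
    (zero anchor at t = 0 fixed), frame-averages each basis function on the
    integer grid and solves the resulting (diagonally dominant) linear
    system for the anchor values.
    """
    n = schedule.n_frames
    anchors_t = np.concatenate([[0.0], schedule.midpoints])
    t = np.arange(1, grid_end + 1, dtype=float)
    design = np.zeros((n, n))
    for j in range(n):
        basis = np.zeros(n + 1)
        basis[j + 1] = 1.0
        curve = np.interp(t, anchors_t, basis)
        for i, (start, end) in enumerate(
            zip(schedule.frame_start, schedule.frame_end)
        ):
            sel = (t > start) & (t <= end)
            design[i, j] = curve[sel].mean()
    return np.linalg.solve(design, np.asarray(frame_values, dtype=float))


def frame_average(curve: SampledCurve, schedule: FrameSchedule) -> FrameTAC:
    """Average 1-s samples onto a frame schedule.

    Each frame value is the arithmetic mean of the samples with
    ``frame_start < t <= frame_end``.
    """
    if schedule.span > curve.duration:
        raise CoverageError(
            f"schedule ends at {schedule.span} s but curve covers {curve.duration} s"
        )
    t = np.arange(1, curve.duration + 1, dtype=float)
    out = np.empty(schedule.n_frames)
    for i, (start, end) in enumerate(zip(schedule.frame_start, schedule.frame_end)):
        sel = (t > start) & (t <= end)
        if not np.any(sel):
            raise CoverageError(f"frame [{start}, {end}] contains no 1-s samples")
        out[i] = curve.values[sel].mean()
    return FrameTAC(schedule, out, label=curve.label, allow_negative=True)


def shift(curve: SampledCurve, delta: int) -> SampledCurve:
    """Delay a curve by ``delta`` whole seconds, zero-padding on the left."""
    if isinstance(delta, float) and not delta.is_integer():
        raise DelayError(f"delay must be a whole number of seconds, got {delta}")
    if not isinstance(delta, (int, np.integer, float)):
        raise DelayError(f"delay must be an integer, got {type(delta).__name__}")
    delta = int(delta)
    if delta < 0:
        raise DelayError(f"delay must be non-negative, got {delta}")
    out = np.zeros_like(curve.values)
    if delta < curve.duration:
        out[delta:] = curve.values[: curve.duration - delta]
    return SampledCurve(out, label=curve.label)


def clip_negative(tac: FrameTAC) -> FrameTAC:
    """Return a copy with negative activities clipped to zero."""
    return FrameTAC(
        tac.schedule, np.maximum(tac.values, 0.0), label=tac.label, allow_negative=False
    )
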
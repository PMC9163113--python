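"""Dynamic frame schedules and sampled time-activity curves.

A dynamic cardiac PET acquisition is reconstructed into a sequence of
contiguous frames of increasing duration (short frames through the bolus
first pass, longer frames for the washout tail).  :class:`FrameSchedule`
holds that timing, :class:`SampledCurve` holds a curve on a fine time grid
(input functions, simulated tissue curves), and :func:`frame_average`
bridges the two by averaging a fine-grid curve over each frame interval,
emulating the count integration performed by reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_FRAME_DURATIONS_S",
    "FrameSchedule",
    "SampledCurve",
    "make_default_frame_schedule",
    "frame_average",
    "frame_average_matrix",
]

#: Clinical 4-minute dynamic schedule: 1x10, 8x5, 4x10, 2x15, 3x20, 2x30 s.
DEFAULT_FRAME_DURATIONS_S: tuple[float, ...] = (
    (10.0,) + (5.0,) * 8 + (10.0,) * 4 + (15.0,) * 2 + (20.0,) * 3 + (30.0,) * 2
)


@dataclass(frozen=True)
class FrameSchedule:
    """Start times and durations (seconds) of contiguous dynamic frames.

    Invariants enforced at construction: all durations strictly positive,
    first start at 0 s, and frames contiguous
    (``start[i+1] == start[i] + duration[i]``).
    """

    starts_s: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        durs = np.asarray(self.durations_s, dtype=float)
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "durations_s", durs)
        if starts.ndim != 1 or durs.ndim != 1 or starts.size != durs.size:
            raise ValueError("starts and durations must be 1-D and equal length")
        if starts.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if not np.all(durs > 0):
            raise ValueError("frame durations must be strictly positive")
        if starts[0] != 0.0:
            raise ValueError("first frame must start at t = 0 s")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous (no gaps or overlaps)")

    @classmethod
    def from_durations(cls, durations_s: Iterable[float]) -> "FrameSchedule":
        durs = np.asarray(list(durations_s), dtype=float)
        starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    @property
    def n_frames(self) -> int:
        return int(self.starts_s.size)

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s

    @property
    def mids_s(self) -> np.ndarray:
        return self.starts_s + 0.5 * self.durations_s

    @property
    def total_duration_s(self) -> float:
        return float(self.ends_s[-1])

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_frames


def make_default_frame_schedule() -> FrameSchedule:
    """Return the default 20-frame, 4-minute dynamic schedule.

    Frame durations are 1x10, 8x5, 4x10, 2x15, 3x20 and 2x30 seconds, the
    standard reconstruction grid for a 4-minute oxygen-15-water scan.
    """
    return FrameSchedule.from_durations(DEFAULT_FRAME_DURATIONS_S)


@dataclass(frozen=True)
class SampledCurve:
    """An activity curve sampled at strictly increasing times.

    ``times_s`` in seconds, ``values`` in kBq/mL.  Values must be finite.
    """

    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a curve needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")

    @property
    def n(self) -> int:
        return int(self.times_s.size)

    def dt(self, rtol: float = 1e-6) -> float:
        """Uniform sample spacing; raises if the grid is not uniform."""
        steps = np.diff(self.times_s)
        dt = float(steps[0])
        if not np.allclose(steps, dt, rtol=rtol, atol=0):
            raise ValueError("curve is not sampled on a uniform grid")
        return dt


def _frame_slices(times_s: np.ndarray, schedule: FrameSchedule) -> list[slice]:
    """Half-open sample index ranges [start, end) for each frame."""
    dt = float(times_s[1] - times_s[0])
    if times_s[0] > 1e-9 or times_s[-1] < schedule.total_duration_s - dt - 1e-9:
        raise ValueError(
            "schedule extends beyond the support of the sampled curve "
            f"(curve covers [{times_s[0]:g}, {times_s[-1]:g}] s, schedule ends "
            f"at {schedule.total_duration_s:g} s)"
        )
    i0 = np.searchsorted(times_s, schedule.starts_s - 1e-9, side="left")
    i1 = np.searchsorted(times_s, schedule.ends_s - 1e-9, side="left")
    if np.any(i1 <= i0):
        raise ValueError("a frame contains no samples; use a finer grid")
    return [slice(int(a), int(b)) for a, b in zip(i0, i1)]


def frame_average(curve: SampledCurve, schedule: FrameSchedule) -> np.ndarray:
    """Mean of a fine-grid curve within each frame interval.

    Samples are attributed to frames by the half-open convention
    ``start <= t < end``, so contiguous frames never share a sample.
    """
    return frame_average_matrix(curve.values[None, :], curve.times_s, schedule)[0]


def frame_average_matrix(
    values: np.ndarray, times_s: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Frame-average many curves at once.

    ``values`` has shape ``(n_curves, n_times)``; returns
    ``(n_curves, n_frames)``.
    """
    values = np.asarray(values, dtype=float)
    slices = _frame_slices(np.asarray(times_s, dtype=float), schedule)
    out = np.empty((values.shape[0], len(slices)), dtype=float)
    for j, sl in enumerate(slices):
        out[:, j] = values[:, sl].mean(axis=1)
    return out
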
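"""Core inter-beat-interval (RR) time-series types and operations.

The detector's sole physiological input is a sequence of RR intervals
(milliseconds between successive R-peaks) with the absolute time of each
terminating beat.  Everything downstream — δRR differencing, 2-minute
windowing, Lorenz-plot analysis — is built on the types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RRSeries",
    "DeltaRRSeries",
    "Window",
    "compute_delta_rr",
    "segment_windows",
    "read_rr_csv",
    "write_rr_csv",
]

DEFAULT_WINDOW_S = 120.0


class RRValidationError(ValueError):
    """Raised when an RR series violates its invariants."""


@dataclass(frozen=True)
class RRSeries:
    """A sequence of inter-beat intervals with beat timestamps.

    Parameters
    ----------
    beat_times : array of float
        Seconds from record start; strictly increasing.  ``beat_times[i]``
        is the time of the R-peak that *terminates* interval ``i``.
    intervals : array of float
        Interval durations in milliseconds, all positive.  Interval ``i``
        spans ``(beat_times[i-1], beat_times[i]]``; ``intervals[0]`` ends at
        ``beat_times[0]`` and may start before the record.
    record_id : str
        Opaque label carried through to reports.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    record_id: str = ""

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", iv)
        if bt.ndim != 1 or iv.ndim != 1:
            raise RRValidationError("beat_times and intervals must be 1-D")
        if len(bt) != len(iv):
            raise RRValidationError(
                f"length mismatch: {len(bt)} beat times vs {len(iv)} intervals"
            )
        bad = np.flatnonzero(iv <= 0)
        if bad.size:
            raise RRValidationError(
                f"non-positive RR interval at index {bad[0]}: {iv[bad[0]]!r} ms"
            )
        if len(bt) > 1 and not np.all(np.diff(bt) > 0):
            k = int(np.flatnonzero(np.diff(bt) <= 0)[0])
            raise RRValidationError(
                f"beat_times not strictly increasing at index {k + 1}"
            )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration_s(self) -> float:
        """Time of the last beat, in seconds (0 for an empty series)."""
        return float(self.beat_times[-1]) if len(self.beat_times) else 0.0

    @classmethod
    def from_intervals(
        cls, intervals_ms, record_id: str = "", start_s: float = 0.0
    ) -> "RRSeries":
        """Build a series from intervals alone, placing beats by cumulative sum.

        The first beat falls at ``start_s + intervals_ms[0]/1000``.
        """
        iv = np.asarray(intervals_ms, dtype=float)
        beats = start_s + np.cumsum(iv) / 1000.0
        return cls(beat_times=beats, intervals=iv, record_id=record_id)


@dataclass(frozen=True)
class DeltaRRSeries:
    """First differences of successive RR intervals, δRR(i) = RR(i) − RR(i−1).

    ``anchor_times[k]`` is the beat time of the later interval of difference
    ``k``; a source of M intervals yields max(0, M−1) differences.
    """

    values: np.ndarray
    anchor_times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "anchor_times", np.asarray(self.anchor_times, dtype=float)
        )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Window:
    """A half-open analysis window ``[start, start + duration)`` in seconds.

    ``rr_indices`` are the indices of the intervals whose terminating beat
    time falls inside the window.
    """

    start: float
    duration: float = DEFAULT_WINDOW_S
    rr_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def n_intervals(self) -> int:
        return len(self.rr_indices)


def compute_delta_rr(series: RRSeries) -> DeltaRRSeries:
    """Difference successive RR intervals: δRR(i) = RR(i) − RR(i−1).

    Returns an empty series when fewer than two intervals exist.
    """
    iv = series.intervals
    if len(iv) <= 1:
        return DeltaRRSeries(np.empty(0), np.empty(0))
    return DeltaRRSeries(values=np.diff(iv), anchor_times=series.beat_times[1:])


def segment_windows(series: RRSeries, duration_s: float = DEFAULT_WINDOW_S) -> list[Window]:
    """Tile the record into consecutive half-open windows from time 0.

    Windows are clock-aligned at ``0, d, 2d, …`` seconds and cover the record
    through its last beat.  Each interval is assigned to exactly one window
    by the time of its terminating beat; the assignment therefore neither
    loses nor duplicates intervals.
    """
    if duration_s <= 0:
        raise ValueError(f"window duration must be positive, got {duration_s}")
    if len(series) == 0:
        return []
    n_windows = int(np.floor(series.duration_s / duration_s)) + 1
    # a beat exactly on the final boundary belongs to the next window
    edges = np.arange(n_windows + 1) * duration_s
    assignment = np.searchsorted(edges, series.beat_times, side="right") - 1
    windows = []
    for k in range(n_windows):
        idx = np.flatnonzero(assignment == k)
        windows.append(Window(start=k * duration_s, duration=duration_s, rr_indices=idx))
    return windows


def window_series(series: RRSeries, window: Window) -> RRSeries:
    """Extract the sub-series of a window (beat times keep the record clock)."""
    idx = window.rr_indices
    return RRSeries(
        beat_times=series.beat_times[idx],
        intervals=series.intervals[idx],
        record_id=series.record_id,
    )


def read_rr_csv(path) -> RRSeries:
    """Read an RR series from CSV with header ``time_s,rr_ms``.

    Lines starting with ``#`` are comments.  Malformed rows raise rather
    than being silently skipped.
    """
    times, rrs = [], []
    with open(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if header[:2] != ["time_s", "rr_ms"]:
                    raise RRValidationError(
                        f"{path}: expected header 'time_s,rr_ms', got {line!r}"
                    )
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise RRValidationError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                times.append(float(parts[0]))
                rrs.append(float(parts[1]))
            except ValueError as exc:
                raise RRValidationError(f"{path}:{lineno}: {exc}") from None
    import os

    record_id = os.path.splitext(os.path.basename(str(path)))[0]
    return RRSeries(np.array(times), np.array(rrs), record_id=record_id)


def write_rr_csv(series: RRSeries, path) -> None:
    """Write a series as ``time_s,rr_ms`` CSV (round-trips with read_rr_csv)."""
    with open(path, "w") as fh:
        fh.write("time_s,rr_ms\n")
        for t, rr in zip(series.beat_times, series.intervals):
            fh.write(f"{t:.6f},{rr:.3f}\n")
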
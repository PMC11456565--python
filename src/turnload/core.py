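"""Core data containers shared across the pipeline.

Two raw streams drive everything downstream: flight telemetry
(:class:`FlightTrack`) and the beat-to-beat pulse intervals recorded by an
optical heart-rate sensor (:class:`RRSeries`).  Detected maneuvers are
represented as :class:`TurnSegment`, the three turn types doubling as
cognitive-load classes (climbing = high, descending = intermediate,
leveling = low).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Load-class encoding used throughout: 1 = climbing, 2 = leveling, 3 = descending.
CLASS_NAMES = {1: "climbing", 2: "leveling", 3: "descending"}
CLASS_IDS = {v: k for k, v in CLASS_NAMES.items()}


@dataclass
class RRSeries:
    """Timestamped beat-to-beat (PP/RR) intervals.

    Parameters
    ----------
    beat_times
        Beat occurrence times in seconds, strictly increasing.
    intervals
        Interbeat intervals in milliseconds; ``intervals[i]`` spans
        ``beat_times[i]`` to ``beat_times[i + 1]``, so there is one fewer
        interval than beats.
    """

    beat_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.beat_times.size < 2:
            raise ValueError("RRSeries needs at least 2 beats")
        if self.intervals.size != self.beat_times.size - 1:
            raise ValueError("need exactly one interval per beat after the first")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")

    @classmethod
    def from_intervals(cls, intervals_ms, start_time: float = 0.0) -> "RRSeries":
        """Build a series by cumulative summation of intervals."""
        intervals_ms = np.asarray(intervals_ms, dtype=float)
        beat_times = start_time + np.concatenate(
            [[0.0], np.cumsum(intervals_ms) / 1000.0]
        )
        return cls(beat_times=beat_times, intervals=intervals_ms)

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def duration(self) -> float:
        """Span of the series in seconds."""
        return float(self.beat_times[-1] - self.beat_times[0])

    def to_csv(self, path) -> None:
        """Write ``time_s,rr_ms`` rows, one per interval (time = ending beat)."""
        pd.DataFrame(
            {"time_s": self.beat_times[1:], "rr_ms": self.intervals}
        ).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "RRSeries":
        df = pd.read_csv(path)
        t_end = df["time_s"].to_numpy(float)
        rr = df["rr_ms"].to_numpy(float)
        t0 = t_end[0] - rr[0] / 1000.0
        return cls(beat_times=np.concatenate([[t0], t_end]), intervals=rr)


@dataclass
class FlightTrack:
    """Telemetry channels sampled on a common clock.

    ``heading`` is in degrees within [0, 360), ``altitude`` in feet,
    ``speed`` in knots.
    """

    time: np.ndarray
    heading: np.ndarray
    altitude: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        self.altitude = np.asarray(self.altitude, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        n = self.time.size
        if not (self.heading.size == self.altitude.size == self.speed.size == n):
            raise ValueError("all channels must share one length")
        if n and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if n and (np.any(self.heading < 0) or np.any(self.heading >= 360)):
            raise ValueError("headings must lie in [0, 360)")

    def __len__(self) -> int:
        return self.time.size

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "heading_deg": self.heading,
                "altitude_ft": self.altitude,
                "speed_kt": self.speed,
            }
        ).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "FlightTrack":
        df = pd.read_csv(path)
        return cls(
            time=df["time_s"].to_numpy(float),
            heading=df["heading_deg"].to_numpy(float),
            altitude=df["altitude_ft"].to_numpy(float),
            speed=df["speed_kt"].to_numpy(float),
        )


@dataclass
class TurnSegment:
    """A detected (or ground-truth) turn with its load-class label."""

    start_time: float
    end_time: float
    pre_heading: float
    post_heading: float
    heading_delta: float
    altitude_change: float
    class_id: int

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("end_time must exceed start_time")
        if self.class_id not in CLASS_NAMES:
            raise ValueError(f"unknown class_id {self.class_id}")

    @property
    def turn_type(self) -> str:
        return CLASS_NAMES[self.class_id]

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def segments_to_csv(segments, path) -> None:
    pd.DataFrame(
        [
            {
                "start_s": s.start_time,
                "end_s": s.end_time,
                "pre_heading": s.pre_heading,
                "post_heading": s.post_heading,
                "heading_delta": s.heading_delta,
                "altitude_change": s.altitude_change,
                "class_id": s.class_id,
                "class_name": s.turn_type,
            }
            for s in segments
        ]
    ).to_csv(path, index=False)


def segments_from_csv(path) -> list[TurnSegment]:
    df = pd.read_csv(path)
    return [
        TurnSegment(
            start_time=r.start_s,
            end_time=r.end_s,
            pre_heading=r.pre_heading,
            post_heading=r.post_heading,
            heading_delta=r.heading_delta,
            altitude_change=r.altitude_change,
            class_id=int(r.class_id),
        )
        for r in df.itertuples()
    ]
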
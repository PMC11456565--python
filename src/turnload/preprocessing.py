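"""Pulse-interval artifact detection and interpolation repair.

Optical beat detection occasionally misses a pulse (one doubled interval) or
fires spuriously (halved intervals).  Intervals deviating by more than a
relative threshold from the median of their five nearest valid neighbors are
flagged, then each flagged run strictly between two valid intervals is
replaced by linear interpolation between its bracketing values:

    y_{i+k} = y_i + k * (y_{i+n} - y_i) / n,   k = 1 .. n-1

for a flagged run of length n−1 between valid y_i and y_{i+n}.  Flagged runs
touching either end of the series have no bracket and are dropped rather
than extrapolated.  Beat times are rebuilt from the corrected intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import RRSeries

logger = logging.getLogger(__name__)


@dataclass
class ArtifactMask:
    """Per-interval anomaly flags plus the rule that produced them."""

    flags: np.ndarray
    rule: str
    threshold: float

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def detect_artifacts(rr: RRSeries, rel_threshold: float = 0.2) -> ArtifactMask:
    """Flag intervals deviating from their local median by > ``rel_threshold``.

    The reference for interval j is the median of the 5-interval window
    centered on j (clipped at the edges, where the window is one-sided).
    Including j itself keeps the median robust even in very short series,
    where a window of neighbors alone would be dominated by the artifact's
    own influence.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must lie in (0, 1)")
    x = rr.intervals
    n = x.size
    flags = np.zeros(n, dtype=bool)
    if n < 3:
        logger.warning("series too short for artifact detection (n=%d)", n)
        return ArtifactMask(flags, rule="median5", threshold=rel_threshold)
    for j in range(n):
        ref = float(np.median(x[max(0, j - 2) : min(n, j + 3)]))
        if ref > 0 and abs(x[j] - ref) / ref > rel_threshold:
            flags[j] = True
    return ArtifactMask(flags, rule="median5", threshold=rel_threshold)


def interpolate_anomalies(rr: RRSeries, mask: ArtifactMask) -> RRSeries:
    """Replace flagged runs by linear interpolation between valid brackets.

    Runs that touch either end of the series are removed (extrapolating an
    artifact would fabricate data).  The output series starts at the same
    first beat time, with beat times rebuilt cumulatively.
    """
    flags = mask.flags
    if flags.size != rr.intervals.size:
        raise ValueError("mask length must match interval count")
    x = rr.intervals.copy()
    if not flags.any():
        return RRSeries(beat_times=rr.beat_times.copy(), intervals=x)

    keep = np.ones(x.size, dtype=bool)
    j = 0
    while j < x.size:
        if not flags[j]:
            j += 1
            continue
        run_start = j
        while j < x.size and flags[j]:
            j += 1
        run_end = j  # exclusive
        if run_start == 0 or run_end == x.size:
            keep[run_start:run_end] = False
            logger.warning(
                "dropped un-bracketed anomalous run of %d interval(s) at series edge",
                run_end - run_start,
            )
            continue
        y_lo, y_hi = x[run_start - 1], x[run_end]
        n_span = run_end - run_start + 1
        for k in range(1, n_span):
            x[run_start + k - 1] = y_lo + k * (y_hi - y_lo) / n_span
    return RRSeries.from_intervals(x[keep], start_time=float(rr.beat_times[0]))


def clean(rr: RRSeries, rel_threshold: float = 0.2) -> tuple[RRSeries, ArtifactMask]:
    """Detect and repair in one step; returns the cleaned series and mask."""
    mask = detect_artifacts(rr, rel_threshold)
    return interpolate_anomalies(rr, mask), mask
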
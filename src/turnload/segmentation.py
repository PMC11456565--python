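"""Turn detection and load-class labeling from flight telemetry.

A turn is a sustained heading ramp whose accumulated circular heading change
reaches the detection threshold (20 degrees by default).  Concurrent altitude
data types each turn: climbing (class 1) when altitude rises by more than the
level band, descending (class 3) when it falls by more than the band, and
leveling (class 2) otherwise.  Climbing turns impose the highest cognitive
load, leveling turns the lowest.

At a 1-Hz telemetry rate a realistic turn changes heading by well under 20
degrees per sample, so the threshold is applied to the accumulated change
over a contiguous run of turning samples rather than to single steps.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import CLASS_IDS, FlightTrack, TurnSegment

logger = logging.getLogger(__name__)


def heading_delta(pre: float, post: float) -> float:
    """Minimal circular difference between two headings, in [0, 180].

    Raises ``ValueError`` for inputs outside [0, 360).
    """
    if not (0 <= pre < 360 and 0 <= post < 360):
        raise ValueError("headings must lie in [0, 360)")
    d = abs(pre - post)
    return min(d, 360.0 - d)


def signed_heading_step(prev: float, cur: float) -> float:
    """Signed minimal heading change prev→cur, in (−180, 180]."""
    return -(((prev - cur) + 180.0) % 360.0 - 180.0)


def classify_turn(altitudes, level_band: float = 50.0) -> int:
    """Type a turn from its altitude profile.

    Net altitude change above ``+level_band`` ft → climbing (1), below
    ``−level_band`` → descending (3), otherwise leveling (2).
    """
    altitudes = np.asarray(altitudes, dtype=float)
    if altitudes.size < 2:
        raise ValueError("need at least 2 altitude samples")
    return classify_altitude_change(float(altitudes[-1] - altitudes[0]), level_band)


def classify_altitude_change(delta_ft: float, level_band: float = 50.0) -> int:
    if delta_ft > level_band:
        return CLASS_IDS["climbing"]
    if delta_ft < -level_band:
        return CLASS_IDS["descending"]
    return CLASS_IDS["leveling"]


def detect_turns(
    track: FlightTrack,
    threshold: float = 20.0,
    merge_gap: float = 10.0,
    rate_threshold: float = 0.25,
    smooth_window: int = 5,
    level_band: float = 50.0,
) -> list[TurnSegment]:
    """Detect turns as sustained heading ramps accumulating ≥ ``threshold`` deg.

    Per-step signed circular heading changes are smoothed with a short moving
    average to suppress jitter; samples whose smoothed turn rate exceeds
    ``rate_threshold`` (deg/s) are marked as turning.  Contiguous turning runs
    closer than ``merge_gap`` seconds are merged, and runs whose total
    circular heading change falls short of ``threshold`` are discarded.
    Pre/post headings come from the stable samples bordering each run.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(track) < 3:
        return []

    t = track.time
    steps = np.array(
        [signed_heading_step(a, b) for a, b in zip(track.heading[:-1], track.heading[1:])]
    )
    dt = np.diff(t)
    rate = steps / dt
    smoothed = uniform_filter1d(rate, size=smooth_window, mode="nearest")
    turning = np.abs(smoothed) > rate_threshold

    # contiguous runs of turning steps, as (first_step, last_step) index pairs
    runs: list[list[int]] = []
    idx = np.flatnonzero(turning)
    for i in idx:
        if runs and i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])

    # merge runs separated by less than merge_gap seconds
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and t[s] - t[merged[-1][1] + 1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    segments = []
    for s, e in merged:
        total = abs(steps[s : e + 1].sum())
        if total < threshold:
            continue
        pre = float(track.heading[s])
        post = float(track.heading[e + 1])
        alt_change = float(track.altitude[e + 1] - track.altitude[s])
        segments.append(
            TurnSegment(
                start_time=float(t[s]),
                end_time=float(t[e + 1]),
                pre_heading=pre,
                post_heading=post,
                heading_delta=heading_delta(pre, post),
                altitude_change=alt_change,
                class_id=classify_altitude_change(alt_change, level_band),
            )
        )
    return segments


def label_windows(windows, segments, min_overlap: float = 0.5):
    """Assign each feature window the load class of its dominant turn.

    A window gets the class of the segment with which its time-overlap
    fraction is largest, provided that fraction is at least ``min_overlap``;
    windows without a dominant segment are excluded.  Returns labeled copies
    (with ``class_id`` and ``segment_index`` set).
    """
    labeled = []
    for w in windows:
        wlen = w.end_time - w.start_time
        best_frac, best_seg = 0.0, None
        for k, seg in enumerate(segments):
            ov = min(w.end_time, seg.end_time) - max(w.start_time, seg.start_time)
            frac = max(ov, 0.0) / wlen
            if frac > best_frac:
                best_frac, best_seg = frac, k
        if best_seg is not None and best_frac >= min_overlap:
            labeled.append(
                dataclasses.replace(
                    w, class_id=segments[best_seg].class_id, segment_index=best_seg
                )
            )
    if not labeled:
        logger.warning("no window overlapped any turn segment")
    return labeled
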
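"""Windowed heart-rate-variability features.

Thirty standard HRV characteristics are computed on 30-second sliding
windows with 40% overlap (an 18-second stride):

* time domain — mean/median/range/SD of NN intervals, successive-difference
  statistics (rmssd, sdsd, nni_20/50 counts, pnni_20/50 percentages),
  coefficients of variation, and instantaneous-heart-rate statistics;
* frequency domain — Welch power in the VLF [0.003, 0.04), LF [0.04, 0.15)
  and HF [0.15, 0.4) Hz bands on the NN series resampled uniformly at 4 Hz,
  plus total power, LF/HF ratio and normalized LF/HF;
* Poincaré geometry — SD1/SD2 of the lag-1 return map, their ratio, the
  cardiac sympathetic (CSI, modified CSI) and vagal (CVI) indices;
* geometric — the triangular index (interval count over the modal histogram
  bin count at the standard 1/128-s bin width).

Conventions worth noting: all standard deviations are sample SDs (ddof=1),
which makes sd1 = sdsd/√2 an exact identity; nni_20/nni_50 count strict
exceedances (> 20 ms, > 50 ms) and the pnni percentages are taken over the
number of successive differences.  A 30-s window supports barely one VLF
cycle, so vlf (and hence total_power) are method-sensitive at this window
length; they are reported for completeness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import welch

from .core import RRSeries

logger = logging.getLogger(__name__)

#: Canonical order of the 30 feature names.
FEATURE_NAMES = [
    "mean_nni", "sdnn", "sdsd", "pnni_20", "pnni_50", "nni_20", "nni_50",
    "rmssd", "median_nni", "range_nni", "cvsd", "cvnni",
    "mean_hr", "max_hr", "min_hr", "std_hr",
    "lf", "hf", "lf_hf_ratio", "lfnu", "hfnu", "total_power", "vlf",
    "sd1", "sd2", "ratio_sd2_sd1", "csi", "cvi", "Modified_csi",
    "triangular_index",
]

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass
class RRWindow:
    """The NN intervals whose beats fall inside one analysis window."""

    start_time: float
    end_time: float
    intervals: np.ndarray
    times: np.ndarray  # end-beat time of each interval, seconds

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.times = np.asarray(self.times, dtype=float)

    def __len__(self) -> int:
        return self.intervals.size


@dataclass
class FeatureWindow:
    """One window's 30-feature vector plus (optional) load label."""

    start_time: float
    end_time: float
    features: dict[str, float]
    class_id: int | None = None
    segment_index: int | None = None

    def vector(self) -> np.ndarray:
        return np.array([self.features[k] for k in FEATURE_NAMES])


def sliding_windows(
    rr: RRSeries, window_s: float = 30.0, overlap: float = 0.4
) -> list[RRWindow]:
    """Cut the series into ``window_s`` windows advancing by (1−overlap)·window_s.

    Each window holds the intervals whose ending beat falls in
    [start, start + window_s); a trailing partial window is discarded.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    step = window_s * (1.0 - overlap)
    t0 = float(rr.beat_times[0])
    duration = rr.duration
    if duration < window_s:
        logger.warning("series (%.1f s) shorter than one window", duration)
        return []
    n_win = int(math.floor((duration - window_s) / step)) + 1
    end_times = rr.beat_times[1:]
    out = []
    for i in range(n_win):
        start = t0 + i * step
        sel = (end_times >= start) & (end_times < start + window_s)
        out.append(
            RRWindow(
                start_time=start,
                end_time=start + window_s,
                intervals=rr.intervals[sel],
                times=end_times[sel],
            )
        )
    return out


# ---------------------------------------------------------------------------
# feature families


def time_domain(intervals) -> dict[str, float]:
    """Time-domain statistics of one window's NN intervals (ms)."""
    nn = np.asarray(intervals, dtype=float)
    if nn.size < 2:
        raise ValueError("window too short")
    diff = np.diff(nn)
    rmssd = float(np.sqrt(np.mean(diff**2)))
    mean_nni = float(np.mean(nn))
    sdnn = float(np.std(nn, ddof=1))
    nni_20 = int(np.sum(np.abs(diff) > 20))
    nni_50 = int(np.sum(np.abs(diff) > 50))
    hr = 60000.0 / nn
    return {
        "mean_nni": mean_nni,
        "sdnn": sdnn,
        "sdsd": float(np.std(diff, ddof=1)),
        "pnni_20": 100.0 * nni_20 / diff.size,
        "pnni_50": 100.0 * nni_50 / diff.size,
        "nni_20": float(nni_20),
        "nni_50": float(nni_50),
        "rmssd": rmssd,
        "median_nni": float(np.median(nn)),
        "range_nni": float(np.max(nn) - np.min(nn)),
        "cvsd": rmssd / mean_nni,
        "cvnni": sdnn / mean_nni,
        "mean_hr": float(np.mean(hr)),
        "max_hr": float(np.max(hr)),
        "min_hr": float(np.min(hr)),
        "std_hr": float(np.std(hr, ddof=1)),
    }


def frequency_domain(window: RRWindow, resample_hz: float = 4.0) -> dict[str, float]:
    """Welch band powers of the NN tachogram resampled uniformly.

    The irregular interval series is linearly interpolated onto a
    ``resample_hz`` grid spanning the window, mean-removed, and analyzed with
    a single Hann segment (a 30-s window is too short for segment
    averaging).  Powers are in ms².
    """
    if len(window) < 4:
        raise ValueError("need at least 4 intervals for spectral analysis")
    grid = np.arange(window.start_time, window.end_time, 1.0 / resample_hz)
    x = np.interp(grid, window.times, window.intervals)
    x = x - x.mean()
    freqs, psd = welch(x, fs=resample_hz, nperseg=x.size, window="hann", detrend=False)

    def band_power(lo, hi):
        sel = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(psd[sel], freqs[sel])) if sel.sum() > 1 else float(
            psd[sel].sum() * (freqs[1] - freqs[0])
        )

    vlf = band_power(*VLF_BAND)
    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    if lf + hf > 0:
        lfnu, hfnu = 100.0 * lf / (lf + hf), 100.0 * hf / (lf + hf)
    else:
        lfnu = hfnu = float("nan")
    if hf == 0:
        logger.warning("zero HF power; lf_hf_ratio undefined for this window")
    return {
        "lf": lf,
        "hf": hf,
        "lf_hf_ratio": lf / hf if hf > 0 else float("nan"),
        "lfnu": lfnu,
        "hfnu": hfnu,
        "total_power": vlf + lf + hf,
        "vlf": vlf,
    }


def poincare(intervals) -> dict[str, float]:
    """Poincaré-plot dispersion measures and the derived autonomic indices."""
    nn = np.asarray(intervals, dtype=float)
    if nn.size < 3:
        raise ValueError("need at least 3 intervals")
    x, y = nn[:-1], nn[1:]
    sd1 = float(np.std((y - x) / np.sqrt(2), ddof=1))
    sd2 = float(np.std((y + x) / np.sqrt(2), ddof=1))
    if sd1 > 0:
        ratio = sd2 / sd1
        modified_csi = (2 * sd2) ** 2 / (2 * sd1)
    else:
        logger.warning("sd1 = 0; Poincaré ratio indices undefined")
        ratio = modified_csi = float("nan")
    cvi = float(np.log10(16 * sd1 * sd2)) if sd1 > 0 and sd2 > 0 else float("nan")
    return {
        "sd1": sd1,
        "sd2": sd2,
        "ratio_sd2_sd1": ratio,
        "csi": ratio,
        "cvi": cvi,
        "Modified_csi": modified_csi,
    }


def triangular_index(intervals, bin_width: float = 1000.0 / 128) -> float:
    """Interval count divided by the modal bin count of the NN histogram."""
    nn = np.asarray(intervals, dtype=float)
    if nn.size < 2:
        raise ValueError("need at least 2 intervals")
    lo = math.floor(nn.min() / bin_width) * bin_width
    n_bins = int(math.floor((nn.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(nn, bins=edges)
    return float(nn.size / counts.max())


def extract_features(
    rr: RRSeries, window_s: float = 30.0, overlap: float = 0.4
) -> list[FeatureWindow]:
    """Compute the full 30-feature vector on every valid sliding window.

    Windows with fewer than 4 intervals are skipped with a log entry.
    """
    out = []
    for w in sliding_windows(rr, window_s=window_s, overlap=overlap):
        if len(w) < 4:
            logger.info("skipping window at %.1f s: only %d intervals", w.start_time, len(w))
            continue
        feats = {}
        feats.update(time_domain(w.intervals))
        feats.update(frequency_domain(w))
        feats.update(poincare(w.intervals))
        feats["triangular_index"] = triangular_index(w.intervals)
        assert set(feats) == set(FEATURE_NAMES)
        out.append(FeatureWindow(start_time=w.start_time, end_time=w.end_time, features=feats))
    return out


def feature_frame(windows_by_subject: dict[int, list[FeatureWindow]]) -> pd.DataFrame:
    """Stack labeled windows into the analysis table (one row per window)."""
    rows = []
    for subject, windows in windows_by_subject.items():
        for w in windows:
            row = {
                "subject": subject,
                "start_s": w.start_time,
                "end_s": w.end_time,
                "class_id": w.class_id,
                "segment_index": w.segment_index,
            }
            row.update({k: w.features[k] for k in FEATURE_NAMES})
            rows.append(row)
    return pd.DataFrame(rows)
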
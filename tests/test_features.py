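"""The 30 windowed HRV features, checked against a brute-force oracle.

The oracle below is deliberately written in plain Python (no numpy), from
the textbook definitions, so it shares no code path with the implementation
it checks.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turnload.core import RRSeries
from turnload.features import (
    FEATURE_NAMES,
    RRWindow,
    extract_features,
    frequency_domain,
    poincare,
    sliding_windows,
    time_domain,
    triangular_index,
)


# ---------------------------------------------------------------------------
# brute-force oracle (pure python, textbook formulas)


def _mean(xs):
    return sum(xs) / len(xs)


def _sample_sd(xs):
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def oracle_time_domain(nn):
    d = [b - a for a, b in zip(nn[:-1], nn[1:])]
    hr = [60000.0 / x for x in nn]
    n20 = sum(1 for x in d if abs(x) > 20)
    n50 = sum(1 for x in d if abs(x) > 50)
    rmssd = math.sqrt(_mean([x * x for x in d]))
    return {
        "mean_nni": _mean(nn),
        "sdnn": _sample_sd(nn),
        "sdsd": _sample_sd(d),
        "rmssd": rmssd,
        "median_nni": sorted(nn)[len(nn) // 2] if len(nn) % 2 else
            0.5 * (sorted(nn)[len(nn) // 2 - 1] + sorted(nn)[len(nn) // 2]),
        "range_nni": max(nn) - min(nn),
        "nni_20": float(n20),
        "nni_50": float(n50),
        "pnni_20": 100.0 * n20 / len(d),
        "pnni_50": 100.0 * n50 / len(d),
        "cvsd": rmssd / _mean(nn),
        "cvnni": _sample_sd(nn) / _mean(nn),
        "mean_hr": _mean(hr),
        "max_hr": max(hr),
        "min_hr": min(hr),
        "std_hr": _sample_sd(hr),
    }


def oracle_poincare(nn):
    diffs = [(b - a) / math.sqrt(2) for a, b in zip(nn[:-1], nn[1:])]
    sums = [(b + a) / math.sqrt(2) for a, b in zip(nn[:-1], nn[1:])]
    sd1, sd2 = _sample_sd(diffs), _sample_sd(sums)
    if sd1 == 0 or sd2 == 0:
        return {"sd1": sd1, "sd2": sd2}
    return {"sd1": sd1, "sd2": sd2, "ratio_sd2_sd1": sd2 / sd1, "csi": sd2 / sd1,
            "cvi": math.log10(16 * sd1 * sd2),
            "Modified_csi": (2 * sd2) ** 2 / (2 * sd1)}


def oracle_triangular_index(nn, bw=1000.0 / 128):
    lo = math.floor(min(nn) / bw) * bw
    counts = {}
    for x in nn:
        k = int((x - lo) / bw)
        counts[k] = counts.get(k, 0) + 1
    return len(nn) / max(counts.values())


# ---------------------------------------------------------------------------


class TestSlidingWindows:
    def test_120s_series_has_six_windows(self):
        rr = RRSeries.from_intervals([1000.0] * 120)
        starts = [w.start_time for w in sliding_windows(rr)]
        assert starts == [0, 18, 36, 54, 72, 90]

    def test_zero_overlap_disjoint(self):
        rr = RRSeries.from_intervals([1000.0] * 120)
        wins = sliding_windows(rr, overlap=0.0)
        for a, b in zip(wins[:-1], wins[1:]):
            assert a.end_time == b.start_time
        # half-open [start, end) windows: the beat at exactly 120 s is out
        total = sum(len(w) for w in wins)
        assert total == 119

    def test_short_series_empty(self):
        rr = RRSeries.from_intervals([1000.0] * 29)
        assert sliding_windows(rr) == []

    def test_bad_overlap_rejected(self):
        rr = RRSeries.from_intervals([1000.0] * 40)
        with pytest.raises(ValueError):
            sliding_windows(rr, overlap=1.0)


class TestTimeDomain:
    def test_constant_window(self):
        f = time_domain([800.0] * 10)
        assert f["sdnn"] == f["rmssd"] == f["range_nni"] == 0
        assert f["mean_hr"] == pytest.approx(75.0)

    def test_rmssd_hand_value(self):
        f = time_domain([800, 810, 790, 805])
        assert f["rmssd"] == pytest.approx(math.sqrt((100 + 400 + 225) / 3), abs=1e-9)

    def test_nni20_strict_threshold(self):
        f = time_domain([700, 725, 750])
        assert f["nni_20"] == 2 and f["pnni_20"] == 100.0
        # exactly 20 ms does not count (strict inequality)
        assert time_domain([700, 720, 740])["nni_20"] == 0

    def test_window_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            time_domain([800.0])

    @given(st.lists(st.floats(500, 1200), min_size=4, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle(self, nn):
        f = time_domain(nn)
        o = oracle_time_domain(nn)
        for k, v in o.items():
            assert f[k] == pytest.approx(v, rel=1e-9, abs=1e-9), k

    @given(st.lists(st.floats(500, 1200), min_size=4, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_time_reversal_invariance(self, nn):
        fwd, rev = time_domain(nn), time_domain(nn[::-1])
        for k in ("sdnn", "rmssd", "range_nni", "mean_nni"):
            assert fwd[k] == pytest.approx(rev[k])

    def test_scale_equivariance(self):
        nn = [812.0, 745.5, 900.25, 788.0, 820.5]
        a, b = time_domain(nn), time_domain([3.0 * x for x in nn])
        for k in ("mean_nni", "sdnn", "rmssd", "range_nni"):
            assert b[k] == pytest.approx(3.0 * a[k])


def _sine_window(freq, amp=30.0, base=800.0, duration=30.0):
    t, times, intervals = 0.0, [], []
    while t < duration:
        rr = base + amp * math.sin(2 * math.pi * freq * t)
        t += rr / 1000.0
        if t >= duration:
            break
        times.append(t)
        intervals.append(rr)
    return RRWindow(0.0, duration, np.array(intervals), np.array(times))


class TestFrequencyDomain:
    def test_hf_modulation_concentrates_in_hf(self):
        f = frequency_domain(_sine_window(0.25))
        assert f["hf"] > 10 * f["lf"]
        assert f["hfnu"] > 90

    def test_lf_modulation_concentrates_in_lf(self):
        f = frequency_domain(_sine_window(0.10))
        assert f["lf"] > 10 * f["hf"]

    def test_normalized_powers_sum_to_100(self):
        for freq in (0.08, 0.2, 0.3):
            f = frequency_domain(_sine_window(freq))
            assert f["lfnu"] + f["hfnu"] == pytest.approx(100.0)

    def test_too_few_intervals_rejected(self):
        w = RRWindow(0, 30, np.array([800.0] * 3), np.array([0.8, 1.6, 2.4]))
        with pytest.raises(ValueError):
            frequency_domain(w)


class TestPoincare:
    def test_sd1_sdsd_identity(self):
        nn = [812.0, 745.5, 900.25, 788.0, 820.5, 799.0]
        assert poincare(nn)["sd1"] == pytest.approx(
            time_domain(nn)["sdsd"] / math.sqrt(2), rel=1e-9
        )

    def test_csi_equals_ratio(self):
        nn = [800.0, 850, 790, 830, 805, 820]
        f = poincare(nn)
        assert f["csi"] == f["ratio_sd2_sd1"]

    @given(st.lists(st.floats(500, 1200), min_size=4, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle(self, nn):
        o = oracle_poincare(nn)
        if "csi" not in o:  # degenerate window, ratio indices undefined
            return
        f = poincare(nn)
        for k, v in o.items():
            assert f[k] == pytest.approx(v, rel=1e-9, abs=1e-9), k

    def test_alternating_series(self):
        nn = [800.0, 900.0] * 6
        f = poincare(nn)
        assert f["sd1"] == pytest.approx(_sample_sd(
            [(b - a) / math.sqrt(2) for a, b in zip(nn[:-1], nn[1:])]
        ))
        assert f["sd1"] > f["sd2"]  # all variability is beat-to-beat


class TestTriangularIndex:
    def test_constant_series_is_one(self):
        assert triangular_index([800.0] * 50) == 1.0

    def test_uniform_spread_over_k_bins(self):
        bw = 1000.0 / 128
        nn = []
        for k in range(5):
            nn.extend([700.0 + (k + 0.5) * bw] * 4)  # 4 counts in each of 5 bins
        assert triangular_index(nn) == pytest.approx(5.0)

    @given(st.lists(st.floats(500, 1200), min_size=2, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_at_least_one_and_matches_oracle(self, nn):
        ti = triangular_index(nn)
        assert ti >= 1.0
        assert ti == pytest.approx(oracle_triangular_index(nn))


class TestExtractFeatures:
    def test_all_30_names_present(self, small_cohort):
        windows = extract_features(small_cohort[0].rr)
        assert len(windows) > 0
        for w in windows[:5]:
            assert set(w.features) == set(FEATURE_NAMES)
            assert len(w.features) == 30

    def test_oracle_agreement_on_random_windows(self, small_cohort):
        """Time-domain + Poincaré + triangular index agree with the
        independent oracle within 1% on 100 generator windows."""
        checked = 0
        for ds in small_cohort:
            for w in sliding_windows(ds.rr):
                if len(w) < 4 or checked >= 100:
                    continue
                nn = list(map(float, w.intervals))
                impl = {**time_domain(nn), **poincare(nn),
                        "triangular_index": triangular_index(nn)}
                orac = {**oracle_time_domain(nn), **oracle_poincare(nn),
                        "triangular_index": oracle_triangular_index(nn)}
                for k, v in orac.items():
                    if math.isfinite(v):
                        assert impl[k] == pytest.approx(v, rel=0.01, abs=1e-6), k
                checked += 1
        assert checked == 100

    def test_empty_series_gives_empty_list(self):
        rr = RRSeries.from_intervals([900.0] * 10)  # 9 s, shorter than a window
        assert extract_features(rr) == []
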
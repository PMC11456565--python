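"""Feature screening across the three turn-load classes.

Each of the 30 HRV features is first routed by a one-sample
Kolmogorov–Smirnov normality check (against a normal with estimated mean and
SD — note this estimated-parameter variant is anti-conservative, i.e. biased
toward *not* rejecting normality).  Normal features are compared across the
three classes with one-way ANOVA, non-normal ones with the Kruskal–Wallis
test; features with p below the significance level (0.05) are selected as
load indicators.  No multiple-testing correction is applied by default (a
Benjamini–Hochberg option exists); observations are pooled windows across
subjects, with per-subject means available as a sensitivity option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)


@dataclass
class ScreeningResult:
    feature_name: str
    normal: bool
    test_used: str  # "ANOVA" or "KW"
    p_value: float
    group_means: tuple[float, float, float]  # climbing, leveling, descending
    selected: bool


def ks_normal(values, alpha: float = 0.05) -> bool:
    """True when a KS test against N(mean, sd) does not reject at ``alpha``."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("constant feature treated as non-normal")
        return False
    p = stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue
    return bool(p >= alpha)


def normality_flags(features: pd.DataFrame, alpha: float = 0.05) -> dict[str, bool]:
    """Per-feature normality decision over all windows (classes pooled)."""
    return {name: ks_normal(features[name]) for name in FEATURE_NAMES if name in features}


def group_comparison(values, labels, normal: bool, alpha: float = 0.05) -> ScreeningResult:
    """Compare one feature across the three load classes.

    Routed to one-way ANOVA when ``normal`` else Kruskal–Wallis, exactly one
    of the two.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = []
    for cid in (1, 2, 3):
        g = values[labels == cid]
        g = g[np.isfinite(g)]
        if g.size < 2:
            raise ValueError("class absent")
        groups.append(g)
    means = tuple(float(g.mean()) for g in groups)
    if normal:
        p = float(stats.f_oneway(*groups).pvalue)
        test = "ANOVA"
    else:
        test = "KW"
        try:
            p = float(stats.kruskal(*groups).pvalue)
        except ValueError:  # all values identical → no ranks to compare
            logger.warning("degenerate Kruskal–Wallis input; reporting p = 1")
            p = 1.0
    if np.isnan(p):
        logger.warning("degenerate test statistic; reporting p = 1")
        p = 1.0
    return ScreeningResult(
        feature_name="",
        normal=normal,
        test_used=test,
        p_value=p,
        group_means=means,
        selected=bool(p < alpha),
    )


def screen_features(
    features: pd.DataFrame,
    alpha: float = 0.05,
    per_subject: bool = False,
    bh_correct: bool = False,
) -> list[ScreeningResult]:
    """Run the full screen over all feature columns present.

    ``per_subject`` aggregates windows to per-subject, per-class means before
    testing (unit-of-analysis sensitivity check); ``bh_correct`` applies
    Benjamini–Hochberg to the raw p-values before selection.
    """
    df = features
    if per_subject:
        df = (
            features.groupby(["subject", "class_id"], as_index=False)[
                [c for c in FEATURE_NAMES if c in features]
            ]
            .mean()
        )
    flags = normality_flags(df, alpha=alpha)
    results = []
    for name, normal in flags.items():
        res = group_comparison(df[name], df["class_id"], normal, alpha=alpha)
        res.feature_name = name
        results.append(res)
    if bh_correct:
        adj = stats.false_discovery_control([r.p_value for r in results], method="bh")
        for r, p in zip(results, adj):
            r.p_value = float(p)
            r.selected = bool(p < alpha)
    return results


def select_features(results: list[ScreeningResult], alpha: float = 0.05) -> list[str]:
    """Significant features, most significant first."""
    hits = [r for r in results if r.p_value < alpha]
    return [r.feature_name for r in sorted(hits, key=lambda r: r.p_value)]


def screening_table(results: list[ScreeningResult]) -> pd.DataFrame:
    """Tabular view mirroring the per-class mean / significance layout."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature_name,
                "test": r.test_used,
                "climbing_mean": r.group_means[0],
                "leveling_mean": r.group_means[1],
                "descending_mean": r.group_means[2],
                "p_value": r.p_value,
                "selected": r.selected,
            }
            for r in results
        ]
    ).sort_values("p_value").reset_index(drop=True)
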
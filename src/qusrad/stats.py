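"""Univariate group comparison of features between outcome classes.

Each feature is compared between the recurrence (R) and non-recurrence
(NR) groups with normality-routed tests: Shapiro-Wilk on each group; if
both are consistent with normality the unpaired two-sided t-test is used,
otherwise the two-sided Mann-Whitney U.  No multiple-testing correction is
applied across the catalog — each feature is reported at its raw p-value,
flagged at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "route_and_test", "comparison_table"]


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    test: str  # "t" or "mann-whitney"
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def route_and_test(
    values_a,
    values_b,
    alpha_normality: float = 0.05,
    feature: str = "",
) -> GroupComparison:
    """Normality-routed two-group comparison.

    Shapiro-Wilk is applied per group; the t-test is used only when neither
    group rejects normality at ``alpha_normality``.  Mann-Whitney uses the
    exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per group")
    normal = (
        sps.shapiro(a).pvalue >= alpha_normality
        and sps.shapiro(b).pvalue >= alpha_normality
    )
    if normal and (np.std(a) > 0 or np.std(b) > 0):
        stat = sps.ttest_ind(a, b)
        test, p = "t", float(stat.pvalue)
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
        stat = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test, p = "mann-whitney", float(stat.pvalue)
    if np.isnan(p):  # both groups constant and equal
        p = 1.0
    return GroupComparison(
        feature=feature,
        mean_a=float(a.mean()),
        sem_a=_sem(a),
        mean_b=float(b.mean()),
        sem_b=_sem(b),
        test=test,
        p_value=min(max(p, 0.0), 1.0),
    )


def comparison_table(
    features: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    positive_label: str = "R",
) -> pd.DataFrame:
    """Per-feature group comparison table (recurrence vs non-recurrence).

    Returns one row per feature column with per-group mean +/- SEM, the
    routed test, the raw p-value, and a significance flag at ``alpha``.
    """
    y = labels.loc[features.index] if labels.index.size else labels
    classes = pd.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    pos = features.loc[np.asarray(y) == positive_label]
    neg = features.loc[np.asarray(y) != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("one class is empty")
    rows = []
    for name in features.columns:
        gc = route_and_test(pos[name], neg[name], feature=name)
        rows.append(
            {
                "feature": name,
                "mean_R": gc.mean_a,
                "sem_R": gc.sem_a,
                "mean_NR": gc.mean_b,
                "sem_NR": gc.sem_b,
                "test": gc.test,
                "p": gc.p_value,
                "significant": gc.p_value < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
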
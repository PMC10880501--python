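"""Clinical validation statistics for a candidate marker gene.

Implements the validation layer: Pearson correlation between expression
markers, Welch group comparison with significance stars, Kaplan–Meier
survival with a two-group log-rank test after a median expression split,
the Pearson chi-square test on a 2x2 contingency table (no continuity
correction by default), and ROC/AUC by the Mann–Whitney concordance
formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .containers import InputError


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("pearson_r needs equal-length vectors of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("correlation of a constant vector is undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_compare(values: np.ndarray, labels: np.ndarray) -> tuple[float, float, str]:
    """Welch two-sided t-test between the two label groups.

    Returns ``(t, p, stars)``.  Two degenerate groups with equal means
    give ``t = 0, p = 1``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise InputError("group_compare needs exactly two groups")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, "ns"
        return float(np.inf), 0.0, "***"
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), significance_stars(float(p))


@dataclass
class SurvivalTestResult:
    endpoint: str
    group_sizes: tuple[int, int]  # (low, high)
    logrank_stat: float
    p: float
    split_value: float
    curves: dict[str, pd.DataFrame]


def km_logrank(
    ct: pd.DataFrame,
    endpoint: str = "OS",
    marker_col: str = "marker_expression",
) -> SurvivalTestResult:
    """Median-split Kaplan–Meier with a two-group log-rank test.

    Samples at or below the median marker value form the low group (ties
    go low).  ``endpoint`` selects the ``os_*`` or ``dfs_*`` columns.
    The log-rank statistic is the usual (O-E)^2 form with hypergeometric
    variance, referred to chi-square with 1 df.
    """
    cols = {"OS": ("os_time", "os_event"), "DFS": ("dfs_time", "dfs_event")}
    if endpoint not in cols:
        raise InputError(f"endpoint must be one of {sorted(cols)}")
    tcol, ecol = cols[endpoint]
    t = ct[tcol].to_numpy(dtype=float)
    e = ct[ecol].to_numpy(dtype=int)
    if e.sum() < 2:
        raise InputError("need at least 2 events for a survival comparison")
    marker = ct[marker_col].to_numpy(dtype=float)
    split = float(np.median(marker))
    high = marker > split
    if high.sum() == 0 or (~high).sum() == 0:
        raise InputError("median split produced an empty group")

    res = logrank_test(t[~high], t[high], event_observed_A=e[~high], event_observed_B=e[high])
    curves = {}
    for name, mask in (("low", ~high), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask], label=name)
        curves[name] = kmf.survival_function_.rename(columns={name: "S"})
    return SurvivalTestResult(
        endpoint=endpoint,
        group_sizes=(int((~high).sum()), int(high.sum())),
        logrank_stat=float(res.test_statistic),
        p=float(res.p_value),
        split_value=split,
        curves=curves,
    )


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi_square: float
    df: int
    p: float


def chisq_2x2(table, correction: bool = False) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table, df = 1.

    No Yates continuity correction by default (``correction=True``
    enables it).  All four margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InputError("table must be 2x2")
    if (t < 0).any():
        raise InputError("table entries must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise InputError("all margins must be positive")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=correction)
    return ContingencyResult(table=t.astype(int), chi_square=float(chi2), df=int(df), p=float(p))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, pd.DataFrame]:
    """AUC by the Mann–Whitney concordance formulation, plus the ROC curve.

    Ties between a positive and a negative score count 0.5.  Returns
    ``(auc, curve)`` where the curve holds (threshold, FPR, TPR) rows.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise InputError("both classes must be present")
    # Mann-Whitney concordance: P(score_pos > score_neg) + 0.5 P(tie)
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u / (pos.size * neg.size))
    fpr, tpr, thr = roc_curve(labels, scores)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return auc, curve


def stage_comparison(
    ct: pd.DataFrame, marker_col: str = "marker_expression", stage_col: str = "stage"
) -> pd.DataFrame:
    """Marker mean ± SD per stage plus Welch tests between adjacent stages."""
    stages = sorted(ct[stage_col].unique(), key=_stage_key)
    rows = []
    for i, s in enumerate(stages):
        v = ct.loc[ct[stage_col] == s, marker_col].to_numpy(dtype=float)
        row = {"stage": s, "n": v.size, "mean": v.mean(), "sd": v.std(ddof=1) if v.size > 1 else np.nan}
        if i > 0:
            prev = ct.loc[ct[stage_col] == stages[i - 1], marker_col].to_numpy(dtype=float)
            if v.size >= 2 and prev.size >= 2:
                _, p, star = group_compare(
                    np.concatenate([prev, v]),
                    np.concatenate([np.zeros(prev.size), np.ones(v.size)]),
                )
                row["p_vs_previous"], row["stars"] = p, star
        rows.append(row)
    return pd.DataFrame(rows)


_STAGE_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4}


def _stage_key(s: str) -> tuple:
    return (_STAGE_ORDER.get(s, 99), s)
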
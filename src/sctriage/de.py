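"""Two-group per-gene differential expression on log-normalized data.

The statistic is the two-sided Wilcoxon rank-sum test (exact for small
tie-free groups, normal approximation with tie correction otherwise —
the rank test's usual small-sample convention), the effect size is the natural-log
fold change of back-transformed group means with a pseudocount, and
detection fractions per group are reported alongside.  Genes enter the
test only if detected in more than ``min_pct`` of cells in at least one
group and if ``|avg_logFC|`` exceeds ``min_abs_logfc``; Bonferroni
adjustment is over the post-screen gene count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import InputError, NormalizedMatrix

DE_COLUMNS = ["gene", "p_val", "p_val_adj", "avg_logFC", "pct_1", "pct_2"]


def detection_fraction(values: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of cells in the masked group with expression > 0."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise InputError("detection fraction of an empty group is undefined")
    v = np.asarray(values)[mask]
    return float((v > 0).sum() / v.size)


def avg_logfc(
    values: np.ndarray,
    mask_1: np.ndarray,
    mask_2: np.ndarray,
    pseudocount: float = 1.0,
) -> float:
    """ln(mean(expm1(x)) + pc) in group 1 minus the same in group 2.

    Computed on log-normalized values; back-transforming with ``expm1``
    recovers normalized counts, so this is a log ratio of group mean
    expression with a pseudocount.
    """
    v = np.asarray(values, dtype=float)
    m1 = np.expm1(v[np.asarray(mask_1, dtype=bool)]).mean()
    m2 = np.expm1(v[np.asarray(mask_2, dtype=bool)]).mean()
    return float(np.log(m1 + pseudocount) - np.log(m2 + pseudocount))


def wilcoxon_de(
    nm: NormalizedMatrix,
    group_1: str = "tumor",
    group_2: str = "normal",
    min_pct: float = 0.25,
    min_abs_logfc: float = 0.25,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE table between two annotated groups.

    Returns a DataFrame with columns ``gene, p_val, p_val_adj, avg_logFC,
    pct_1, pct_2`` sorted by p-value then gene symbol.  A gene whose
    values are all tied across both groups gets ``p_val = 1``.
    """
    labels = nm.cell_meta["group"]
    mask_1 = (labels == group_1).to_numpy()
    mask_2 = (labels == group_2).to_numpy()
    if mask_1.sum() < 2 or mask_2.sum() < 2:
        raise InputError("both groups need at least 2 cells")

    x = nm.values
    v1 = x[:, mask_1]
    v2 = x[:, mask_2]
    pct_1 = (v1 > 0).mean(axis=1)
    pct_2 = (v2 > 0).mean(axis=1)
    m1 = np.expm1(v1).mean(axis=1)
    m2 = np.expm1(v2).mean(axis=1)
    lfc = np.log(m1 + pseudocount) - np.log(m2 + pseudocount)

    passes = (np.maximum(pct_1, pct_2) > min_pct) & (np.abs(lfc) > min_abs_logfc)
    idx = np.flatnonzero(passes)
    if idx.size == 0:
        return pd.DataFrame(columns=DE_COLUMNS)

    with np.errstate(invalid="ignore", divide="ignore"):
        if v1.shape[1] <= 8 and v2.shape[1] <= 8:
            # small groups: per-gene so tie-free genes get the exact p
            p = np.array(
                [
                    stats.mannwhitneyu(
                        v1[i], v2[i], alternative="two-sided", method="auto"
                    ).pvalue
                    for i in idx
                ],
                dtype=float,
            )
        else:
            res = stats.mannwhitneyu(
                v1[idx], v2[idx], axis=1, alternative="two-sided", method="asymptotic"
            )
            p = np.asarray(res.pvalue, dtype=float)
    # all-tied genes: the rank statistic is degenerate, report p = 1
    degenerate = np.array(
        [np.unique(np.concatenate([v1[i], v2[i]])).size == 1 for i in idx]
    )
    p[degenerate | ~np.isfinite(p)] = 1.0
    p = np.minimum(p, 1.0)

    out = pd.DataFrame(
        {
            "gene": [nm.genes[i] for i in idx],
            "p_val": p,
            "p_val_adj": np.minimum(p * idx.size, 1.0),
            "avg_logFC": lfc[idx],
            "pct_1": pct_1[idx],
            "pct_2": pct_2[idx],
        }
    )
    out = out.sort_values(["p_val", "gene"], kind="stable").reset_index(drop=True)
    return out
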
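"""Gene-set enrichment: over-representation and ranked permutation GSEA.

Pathway membership comes from GMT collections (synthetic or user
provided); no online pathway database is consulted.  ORA uses the
one-sided hypergeometric tail; GSEA uses the classical weighted
Kolmogorov–Smirnov running sum with a gene-label permutation null, a
sign-matched normalized enrichment score, and Benjamini–Hochberg
adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConfigurationError, InputError


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional universe, GMT-serializable."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise InputError(f"gene set {name!r} has duplicate members")

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, "na", *members]) + "\n")

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                name, _desc, *members = line.split("\t")
                sets[name] = members
        return cls(sets=sets)


def ora_hypergeometric(
    hits: set[str], universe: set[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each set.

    Population = universe, successes = set ∩ universe, draws = hits;
    p = P(X >= k_overlap), BH-adjusted across sets.
    """
    universe = set(universe)
    hits = set(hits)
    if not universe:
        raise InputError("empty universe")
    if not hits <= universe:
        raise InputError("hits must be a subset of the universe")
    rows = []
    for name, members in collection.sets.items():
        in_universe = set(members) & universe
        k = len(in_universe & hits)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(in_universe), len(hits)))
        rows.append({"set_name": name, "k_overlap": k, "set_size": len(in_universe), "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)


def gsea_es(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_set: set[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS running sum over a ranked gene list.

    In-set genes increment by ``|score|^weight_p`` normalized over the
    in-set total; out-of-set genes decrement by ``1/(N - n_set)``.  The
    enrichment score is the running sum's signed maximum deviation; the
    leading edge is the in-set genes up to (positive ES) or from
    (negative ES) the extremum.

    Returns ``(ES, running_sum, leading_edge)``.
    """
    genes = list(ranked_genes)
    if len(set(genes)) != len(genes):
        raise InputError("ranked gene list must be unique")
    mask = np.array([g in gene_set for g in genes])
    if not mask.any():
        raise InputError("gene set is disjoint from the ranked list")
    running = _running_sum(np.asarray(scores, dtype=float), mask, weight_p)
    i = int(np.argmax(np.abs(running)))
    es = float(running[i])
    if es >= 0:
        leading = [g for g, m in zip(genes[: i + 1], mask[: i + 1]) if m]
    else:
        leading = [g for g, m in zip(genes[i:], mask[i:]) if m]
    return es, running, leading


def _running_sum(scores: np.ndarray, mask: np.ndarray, weight_p: float) -> np.ndarray:
    n = mask.size
    n_hit = int(mask.sum())
    w = np.abs(scores) ** weight_p
    hit_w = w * mask
    total = hit_w.sum()
    if total == 0:  # all in-set scores are zero: fall back to uniform steps
        hit_w = mask.astype(float)
        total = float(n_hit)
    steps = hit_w / total
    if n > n_hit:
        steps = steps - (~mask) / (n - n_hit)
    return np.cumsum(steps)


def gsea(
    ranked_genes: list[str],
    scores: np.ndarray,
    collection: GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation GSEA of every set in the collection against one ranking.

    The null permutes gene labels: each permutation draws a random set of
    the same size from the ranked list.  ``NES = ES / mean(|null ES|)``
    over nulls of matching sign; the p-value is the two-sided empirical
    tail over the whole null with add-one smoothing; ``q`` is BH across
    sets.
    Sets disjoint from the ranking are reported as skipped (NaN
    statistics).  Fixed seed gives identical output.
    """
    if n_perm < 10:
        raise ConfigurationError("n_perm must be at least 10")
    rng = np.random.default_rng(seed)
    genes = list(ranked_genes)
    scores = np.asarray(scores, dtype=float)
    gene_index = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in collection.sets.items():
        positions = sorted(gene_index[g] for g in members if g in gene_index)
        if not positions:
            rows.append(
                {"set_name": name, "size": 0, "ES": np.nan, "NES": np.nan,
                 "p": np.nan, "leading_edge": "", "skipped": True}
            )
            continue
        mask = np.zeros(n, dtype=bool)
        mask[positions] = True
        running = _running_sum(scores, mask, weight_p)
        i = int(np.argmax(np.abs(running)))
        es = float(running[i])
        size = len(positions)
        if size not in null_cache:
            null = np.empty(n_perm)
            pm = np.zeros(n, dtype=bool)
            for b in range(n_perm):
                pm[:] = False
                pm[rng.choice(n, size=size, replace=False)] = True
                r = _running_sum(scores, pm, weight_p)
                null[b] = r[np.argmax(np.abs(r))]
            null_cache[size] = null
        null = null_cache[size]
        same = null >= 0 if es >= 0 else null < 0
        denom = np.abs(null[same]).mean() if same.any() else np.abs(null).mean()
        # two-sided empirical p over the whole null, add-one smoothed
        p = (1 + (np.abs(null) >= abs(es)).sum()) / (1 + n_perm)
        nes = es / denom if denom > 0 else np.nan
        if es >= 0:
            leading = [genes[j] for j in range(i + 1) if mask[j]]
        else:
            leading = [genes[j] for j in range(i, n) if mask[j]]
        rows.append(
            {"set_name": name, "size": size, "ES": es, "NES": nes, "p": float(p),
             "leading_edge": ",".join(leading), "skipped": False}
        )
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["q"] = q
    return out.sort_values(["p", "set_name"], kind="stable", na_position="last").reset_index(drop=True)
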
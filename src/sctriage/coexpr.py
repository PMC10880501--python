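"""Weighted co-expression network construction and module detection.

The network is unsigned: adjacency ``A_mn = |S_mn|^beta`` with ``S`` the
gene–gene Pearson correlation and ``beta`` chosen as the smallest power
whose connectivity distribution fits a scale-free law at a target signed
R².  Adjacency is transformed to the topological overlap matrix (TOM);
genes are clustered by average linkage on ``1 - TOM`` with a static tree
cut; clusters below the minimum size are left unassigned ("grey").
Module eigengenes (first principal components of the scaled module
expression) are correlated with pathway genes and traits to select the
module carrying the pathway signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .containers import InputError, NormalizedMatrix

GREY = "grey"


def select_variable_genes(nm: NormalizedMatrix, n: int = 5000) -> list[str]:
    """The ``n`` genes with greatest variance across cells, ties by symbol."""
    var = nm.values.var(axis=1, ddof=1)
    if n > len(nm.genes):
        warnings.warn(
            f"requested {n} genes but only {len(nm.genes)} available", stacklevel=2
        )
        n = len(nm.genes)
    order = sorted(range(len(nm.genes)), key=lambda i: (-var[i], nm.genes[i]))
    return [nm.genes[i] for i in order[:n]]


def correlation_matrix(nm: NormalizedMatrix, genes: list[str]) -> pd.DataFrame:
    """Gene x gene Pearson correlation of normalized expression."""
    idx = [nm.genes.index(g) for g in genes]
    x = nm.values[idx]
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise InputError("constant genes have undefined correlation; filter them first")
    s = np.corrcoef(x)
    return pd.DataFrame(s, index=genes, columns=genes)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit of a connectivity vector.

    Discretizes ``k`` into ``n_bins`` equal-width bins, takes each bin's
    mean connectivity and occupancy frequency, and fits
    ``log10(frequency) ~ log10(mean k)`` by least squares over non-empty
    bins.  Returns ``(signed_r2, slope)`` where
    ``signed_r2 = R^2 * sign(-slope)`` so a decreasing power-law tail
    scores positive.  Degenerate inputs — too few occupied bins, an
    all-equal connectivity vector, or connectivities spanning less than
    two decades (too short a range to assess a power law) — return
    ``(0.0, 0.0)``.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or k.min() == k.max():
        return 0.0, 0.0
    # a credible power law needs ~2 decades of dynamic range in k
    if np.log10(k.max() / k.min()) < 2.0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        inb = which == b
        if not inb.any():
            continue
        mk = k[inb].mean()
        freq = inb.mean()
        if mk > 0 and freq > 0:
            log_k.append(np.log10(mk))
            log_f.append(np.log10(freq))
    if len(log_k) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(log_k, log_f)
    return float(r**2 * np.sign(-slope)), float(slope)


def soft_threshold_scan(
    S: pd.DataFrame,
    powers: list[int] | None = None,
    target_r2: float = 0.85,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by scale-free topology fit.

    For each candidate power the connectivity ``k_m = sum_{n != m}
    |S_mn|^power`` is computed and its distribution scored with
    :func:`scale_free_fit`.  The chosen power is the smallest one whose
    signed R² reaches ``target_r2``; if none does, the power maximizing
    signed R² is returned with a warning.
    """
    if powers is None:
        powers = list(range(1, 21))
    a = np.abs(np.asarray(S, dtype=float))
    np.fill_diagonal(a, 0.0)
    rows = []
    for p in powers:
        k = (a**p).sum(axis=1)
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {"power": p, "signed_r2": r2, "slope": slope,
             "mean_k": float(k.mean()), "median_k": float(np.median(k))}
        )
    profile = pd.DataFrame(rows)
    ok = profile[profile["signed_r2"] >= target_r2]
    if len(ok):
        beta = int(ok["power"].iloc[0])
    else:
        beta = int(profile.loc[profile["signed_r2"].idxmax(), "power"])
        warnings.warn(
            f"no power reached signed R^2 >= {target_r2}; "
            f"falling back to the best fit (power {beta})",
            stacklevel=2,
        )
    return beta, profile


def adjacency(S: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency ``|S|^beta``."""
    if beta < 1:
        raise InputError("beta must be >= 1")
    return np.abs(S) ** beta


def tom(A: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency in [0, 1].

    ``TOM_mn = (sum_{u != m,n} A_mu A_un + A_mn) /
    (min(k_m, k_n) + 1 - A_mn)`` with ``k_m = sum_{u != m} A_mu``;
    the diagonal is 1.
    """
    a = np.asarray(A, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise InputError("adjacency must be square and symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    shared = a0 @ a0  # (m,n) entry sums over u != m,n exactly (zero diagonal)
    num = shared + a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(t, 1.0)
    if isinstance(A, pd.DataFrame):
        return pd.DataFrame(t, index=A.index, columns=A.columns)
    return t


def cluster_modules(
    diss_tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float | None = None,
    adapt_quantile: float = 0.99,
    adapt_fraction: float = 0.45,
) -> pd.Series:
    """Average-linkage modules from a TOM dissimilarity with a tree cut.

    With ``cut_height=None`` (the default) the cut adapts to the overlap
    scale of the network: the tree is cut at
    ``1 - adapt_fraction * q`` where ``q`` is the ``adapt_quantile``
    quantile of the off-diagonal topological overlap (1 - dissimilarity).
    Because the strong-overlap tail is dominated by within-module pairs,
    this places the cut a fixed fraction of the way into that tail
    whatever the soft-threshold power did to the absolute TOM scale.  A
    numeric ``cut_height`` applies a classical static cut instead.

    Clusters smaller than ``min_module_size`` are merged into ``grey``
    (unassigned); the rest are labeled ``M1, M2, ...`` in decreasing
    size order (ties by first gene symbol).
    """
    d = np.asarray(diss_tom, dtype=float)
    genes = list(diss_tom.index) if isinstance(diss_tom, pd.DataFrame) else [
        f"g{i}" for i in range(d.shape[0])
    ]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise InputError("dissimilarity must be square and symmetric")
    dd = (d + d.T) / 2.0
    np.fill_diagonal(dd, 0.0)
    condensed = squareform(dd, checks=False)
    if cut_height is None:
        overlap = 1.0 - condensed
        cut_height = float(1.0 - adapt_fraction * np.quantile(overlap, adapt_quantile))
    link = average(condensed)
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(index=genes, dtype=object, name="module")
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    kept = [
        members for members in clusters.values() if len(members) >= min_module_size
    ]
    kept.sort(key=lambda m: (-len(m), sorted(m)[0]))
    labels[:] = GREY
    for i, members in enumerate(kept, start=1):
        labels[members] = f"M{i}"
    return labels


def module_eigengenes(nm: NormalizedMatrix, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module over cells (unit norm).

    Each module's member genes are z-scored across cells; the eigengene
    is the leading left singular vector of the cell x gene matrix, with
    its sign aligned to the module's average scaled expression.
    """
    gene_index = {g: i for i, g in enumerate(nm.genes)}
    out = {}
    for module in sorted(set(labels) - {GREY}):
        members = [g for g in labels.index[labels == module] if g in gene_index]
        x = nm.values[[gene_index[g] for g in members]]
        sd = x.std(axis=1, ddof=1, keepdims=True)
        ok = sd[:, 0] > 0
        z = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok]
        u, s, vt = np.linalg.svd(z.T, full_matrices=False)
        eig = u[:, 0]
        if np.corrcoef(eig, z.mean(axis=0))[0, 1] < 0:
            eig = -eig
        out[module] = eig
    return pd.DataFrame(out, index=pd.Index(nm.cells, name="barcode"))


@dataclass
class ModulePathwayResult:
    """Module-by-(pathway gene + trait) correlation table and the best module."""

    correlations: pd.DataFrame  # MultiIndex columns: (kind, name) -> r
    pvalues: pd.DataFrame
    best_module: str
    pathway_hit_counts: pd.Series


def module_pathway_correlation(
    nm: NormalizedMatrix,
    labels: pd.Series,
    pathway_genes: list[str],
    traits: pd.DataFrame | None = None,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
) -> ModulePathwayResult:
    """Correlate module eigengenes with pathway-gene expression and traits.

    ``best_module`` is the module with the greatest number of pathway
    genes at ``|r| > r_threshold`` and ``p < p_threshold`` (ties broken
    by mean ``|r|`` over pathway genes).  Pathway genes absent from the
    matrix are skipped with a warning; constant traits yield NaN.
    """
    eig = module_eigengenes(nm, labels)
    if eig.shape[1] == 0:
        raise InputError("no non-grey modules to correlate")
    gene_index = {g: i for i, g in enumerate(nm.genes)}
    present = [g for g in pathway_genes if g in gene_index]
    missing = [g for g in pathway_genes if g not in gene_index]
    if missing:
        warnings.warn(
            f"{len(missing)} pathway genes absent from the matrix: {missing[:5]}...",
            stacklevel=2,
        )
    targets: dict[tuple[str, str], np.ndarray] = {
        ("pathway", g): nm.values[gene_index[g]] for g in present
    }
    if traits is not None:
        for c in traits.columns:
            targets[("trait", c)] = traits[c].to_numpy(dtype=float)

    cols = pd.MultiIndex.from_tuples(targets.keys()) if targets else pd.MultiIndex.from_tuples([], names=[None, None])
    r = pd.DataFrame(index=eig.columns, columns=cols, dtype=float)
    p = pd.DataFrame(index=eig.columns, columns=cols, dtype=float)
    for module in eig.columns:
        e = eig[module].to_numpy()
        for key, y in targets.items():
            if np.std(y) == 0 or np.std(e) == 0:
                r.loc[module, key] = np.nan
                p.loc[module, key] = np.nan
            else:
                rr, pp = stats.pearsonr(e, y)
                r.loc[module, key] = rr
                p.loc[module, key] = pp

    if present:
        path_r = r["pathway"].astype(float)
        path_p = p["pathway"].astype(float)
        hits = ((path_r.abs() > r_threshold) & (path_p < p_threshold)).sum(axis=1)
        mean_abs = path_r.abs().mean(axis=1)
        ranked = sorted(
            eig.columns, key=lambda m: (-hits[m], -mean_abs[m], m)
        )
        best = ranked[0]
    else:
        hits = pd.Series(0, index=eig.columns)
        best = sorted(eig.columns)[0]
    return ModulePathwayResult(
        correlations=r, pvalues=p, best_module=best, pathway_hit_counts=hits
    )
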
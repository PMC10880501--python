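"""Per-cell QC metrics, cell filtering, log-normalization and PCA.

Mirrors the standard single-cell preprocessing triplet: nCount (total UMI
per cell), nFeature (detected genes per cell), percent_mt (share of counts
from mitochondrial genes, identified by symbol prefix).  Cells are kept
when percent_mt is strictly below the threshold (default 20%).  Graph
clustering and UMAP are deliberately out of scope: group labels come from
the cell annotation table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, InputError, NormalizedMatrix


def compute_qc(m: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """QC metrics per cell: ``nCount``, ``nFeature``, ``percent_mt``.

    ``percent_mt`` of a cell with zero counts is defined as 0 (such cells
    can then be removed by an nFeature floor if desired).
    """
    if m.n_genes == 0 or m.n_cells == 0:
        raise InputError("cannot compute QC on an empty matrix")
    counts = m.counts
    n_count = counts.sum(axis=0)
    n_feature = (counts > 0).sum(axis=0)
    mito = np.array([g.startswith(mito_prefix) for g in m.genes])
    mito_counts = counts[mito].sum(axis=0) if mito.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_count > 0, 100.0 * mito_counts / np.maximum(n_count, 1), 0.0)
    return pd.DataFrame(
        {"nCount": n_count, "nFeature": n_feature, "percent_mt": pct},
        index=pd.Index(m.cells, name="barcode"),
    )


def filter_cells(m: CountMatrix, qc: pd.DataFrame, max_percent_mt: float = 20.0) -> CountMatrix:
    """Keep cells with ``percent_mt`` strictly below the threshold; order preserved."""
    if list(qc.index) != list(m.cells):
        raise InputError("QC table does not match the matrix cells")
    keep = (qc["percent_mt"] < max_percent_mt).to_numpy()
    if not keep.any():
        warnings.warn(
            "all cells removed by the mitochondrial filter", stacklevel=2
        )
    return m.subset_cells(keep)


def normalize(m: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Log-normalize: ``value = ln(1 + count * scale_factor / nCount)``.

    Cells with zero total counts come out all-zero.
    """
    n_count = m.counts.sum(axis=0).astype(float)
    denom = np.where(n_count > 0, n_count, 1.0)
    values = np.log1p(m.counts * (scale_factor / denom)[None, :])
    return NormalizedMatrix(values=values, scale_factor=scale_factor, source=m)


def scale_and_pca(
    nm: NormalizedMatrix, n_components: int = 30, clip: float = 10.0
) -> pd.DataFrame:
    """Z-score genes, clip at ±``clip``, and embed cells with PCA.

    Zero-variance genes are dropped before scaling.  The SVD sign is fixed
    so each component's largest-magnitude gene loading is positive, making
    the embedding reproducible bit-for-bit.  Returns a cell x component
    DataFrame (columns ``PC1..PCk``).
    """
    x = nm.values
    if x.shape[1] < 2:
        raise InputError("PCA needs at least 2 cells")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    nonzero = sd[:, 0] > 0
    z = (x[nonzero] - mean[nonzero]) / sd[nonzero]
    z = np.clip(z, -clip, clip)

    max_rank = min(z.shape)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} truncated to {max_rank}", stacklevel=2
        )
        n_components = max_rank

    # cells x genes for SVD; deterministic sign from gene loadings
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    emb = u * s
    return pd.DataFrame(
        emb,
        index=pd.Index(nm.cells, name="barcode"),
        columns=[f"PC{i + 1}" for i in range(emb.shape[1])],
    )
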
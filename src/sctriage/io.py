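"""Readers and writers for the pipeline's on-disk formats.

Counts travel as MatrixMarket (``matrix.mtx`` + ``genes.tsv`` +
``barcodes.tsv``) or as a dense TSV; gene sets as GMT; the interaction
graph as a two-column TSV edge list; clinical tables as CSV; ground
truth as JSON.  All formats are plain text.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix, GroundTruth, InputError


def write_counts_mtx(cm: CountMatrix, directory) -> None:
    """Write ``matrix.mtx`` (genes x cells), ``genes.tsv`` and ``barcodes.tsv``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(d / "matrix.mtx"), sparse.coo_matrix(cm.counts))
    pd.Series(cm.genes).to_csv(d / "genes.tsv", sep="\t", index=False, header=False)
    meta = cm.cell_meta.reset_index()
    meta.columns = ["barcode", *meta.columns[1:]]
    meta.to_csv(d / "barcodes.tsv", sep="\t", index=False)


def read_counts_mtx(directory) -> CountMatrix:
    d = Path(directory)
    counts = np.asarray(spio.mmread(str(d / "matrix.mtx")).todense())
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].tolist()
    meta = pd.read_csv(d / "barcodes.tsv", sep="\t").set_index("barcode")
    return CountMatrix(
        genes=genes, cells=meta.index.tolist(),
        counts=counts.astype(np.int64), cell_meta=meta,
    )


def write_counts_dense(cm: CountMatrix, counts_path, meta_path) -> None:
    """Dense TSV: genes as rows, barcodes as columns; meta as its own TSV."""
    df = pd.DataFrame(cm.counts, index=pd.Index(cm.genes, name="gene"), columns=cm.cells)
    df.to_csv(counts_path, sep="\t")
    meta = cm.cell_meta.reset_index()
    meta.columns = ["barcode", *meta.columns[1:]]
    meta.to_csv(meta_path, sep="\t", index=False)


def read_counts_dense(counts_path, meta_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t").set_index("barcode")
    return CountMatrix(
        genes=df.index.tolist(), cells=df.columns.tolist(),
        counts=df.to_numpy(), cell_meta=meta,
    )


def write_edges(g: nx.Graph, path) -> None:
    """Two-column tab-separated edge list with header ``gene_a\\tgene_b``."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")
        # isolated nodes round-trip as a==b rows (never read back as loops)
        isolated = sorted(n for n in g.nodes if g.degree(n) == 0)
        for n in isolated:
            fh.write(f"{n}\t{n}\n")


def read_edges(path, col_a: str = "gene_a", col_b: str = "gene_b") -> nx.Graph:
    """Read an edge-list TSV; tolerates extra columns by naming the pair.

    A row with identical endpoints records an isolated node (self-loops
    are never added to the graph).
    """
    df = pd.read_csv(path, sep="\t")
    if col_a not in df.columns or col_b not in df.columns:
        raise InputError(f"edge list lacks columns {col_a!r}/{col_b!r}")
    g = nx.Graph()
    for a, b in zip(df[col_a], df[col_b]):
        if a == b:
            g.add_node(a)
        else:
            g.add_edge(a, b)
    return g


def read_clinical(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Clinical CSV reader with optional file-column -> canonical renaming."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"marker_expression", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"clinical table lacks columns: {sorted(missing)}")
    return df


def write_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))
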
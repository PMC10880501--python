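"""Core in-memory containers shared across pipeline stages.

The pipeline's raw input is a gene x cell integer count matrix with a
per-cell annotation table (sample id and group label).  Downstream stages
operate either on the raw counts (:class:`CountMatrix`) or on the
log-normalized values (:class:`NormalizedMatrix`).  Ground truth about
planted signal in synthetic data travels separately in
:class:`GroundTruth` so that no analysis stage can peek at it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GROUPS = ("tumor", "normal", "border")


class InputError(ValueError):
    """Raised when an input violates a stage's preconditions."""


class ConfigurationError(ValueError):
    """Raised when a configuration object is internally inconsistent."""


@dataclass
class CountMatrix:
    """Gene x cell non-negative integer counts plus cell annotations.

    Parameters
    ----------
    genes : list of str
        Unique gene symbols, one per row.
    cells : list of str
        Unique cell barcodes, one per column.
    counts : ndarray of shape (n_genes, n_cells)
        Non-negative integer UMI counts.
    cell_meta : DataFrame indexed by barcode
        Must carry ``sample`` and ``group`` columns; every group label is
        one of ``tumor``, ``normal``, ``border``.
    """

    genes: list[str]
    cells: list[str]
    counts: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise InputError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise InputError("gene symbols must be unique")
        if len(set(self.cells)) != len(self.cells):
            raise InputError("cell barcodes must be unique")
        if self.counts.size and (self.counts < 0).any():
            raise InputError("counts must be non-negative")
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise InputError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        missing = set(self.cells) - set(self.cell_meta.index)
        if missing:
            raise InputError(f"{len(missing)} cells lack annotations")
        bad = set(self.cell_meta["group"]) - set(VALID_GROUPS)
        if bad:
            raise InputError(f"unknown group labels: {sorted(bad)}")
        # align meta to column order
        self.cell_meta = self.cell_meta.loc[self.cells]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean mask over columns selecting cells of one group."""
        return (self.cell_meta["group"] == group).to_numpy()

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        """New matrix restricted to the cells flagged in ``keep`` (order kept)."""
        keep = np.asarray(keep, dtype=bool)
        cells = [c for c, k in zip(self.cells, keep) if k]
        return CountMatrix(
            genes=list(self.genes),
            cells=cells,
            counts=self.counts[:, keep].copy(),
            cell_meta=self.cell_meta.loc[cells].copy(),
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ``ln(1 + count * scale_factor / nCount)``.

    Keeps a reference to the source :class:`CountMatrix` for provenance;
    ``values`` has the same gene x cell layout as the source counts.
    """

    values: np.ndarray
    scale_factor: float
    source: CountMatrix

    @property
    def genes(self) -> list[str]:
        return self.source.genes

    @property
    def cells(self) -> list[str]:
        return self.source.cells

    @property
    def cell_meta(self) -> pd.DataFrame:
        return self.source.cell_meta


@dataclass
class GroundTruth:
    """Planted signal of a synthetic dataset.

    ``latent_factor`` is the per-cell value of the shared factor that the
    planted co-expression module (and part of the pathway set) loads on.
    """

    de_gene_ids: set[str]
    module_gene_ids: set[str]
    pathway_gene_ids: set[str]
    planted_regulator_id: str
    latent_factor: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_dict(self) -> dict:
        return {
            "de_gene_ids": sorted(self.de_gene_ids),
            "module_gene_ids": sorted(self.module_gene_ids),
            "pathway_gene_ids": sorted(self.pathway_gene_ids),
            "planted_regulator_id": self.planted_regulator_id,
            "latent_factor": [float(x) for x in self.latent_factor],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            de_gene_ids=set(d["de_gene_ids"]),
            module_gene_ids=set(d["module_gene_ids"]),
            pathway_gene_ids=set(d["pathway_gene_ids"]),
            planted_regulator_id=d["planted_regulator_id"],
            latent_factor=np.asarray(d.get("latent_factor", []), dtype=float),
        )
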
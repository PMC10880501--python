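"""Synthetic-data generators with planted ground truth.

Every pipeline input — single-cell counts, gene-set collections, a binary
protein-interaction graph, and a clinical sample table — can be generated
from one :class:`SimulationConfig`.  Each generator plants a known signal:

* a set of differentially expressed genes, up-shifted in the tumor group
  on the mean scale by a fixed natural-log fold change;
* a co-expressed module whose genes (plus a share of the pathway genes)
  load on a single per-cell latent factor;
* one regulator gene, a member of the planted module, wired directly to
  several pathway genes on top of an Erdős–Rényi background graph;
* a clinical table with marker-dependent hazard and an exactly
  reproducible 2x2 marker-by-histology cross-tabulation.

One global seed drives four independent sub-streams (counts, sets, graph,
clinical) so each input can be regenerated independently and
deterministically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ConfigurationError, CountMatrix, GroundTruth

# Pathway gene symbols used for readability when n_pathway_genes <= 14;
# purely cosmetic — ground truth is carried by GroundTruth, not by names.
PATHWAY_SYMBOLS = [
    "COL1A1", "ITGB4", "COL1A2", "HSP90AA1", "COL6A1", "DDIT4", "SPP1",
    "RHEB", "ATF4", "LAMB3", "ITGA3", "EPHA2", "ITGB1", "HSP90AB1",
]
REGULATOR_SYMBOL = "MDFI"
N_MITO_GENES = 10
MITO_FRACTION = 0.08  # of total expression; keeps every cell well below 20%


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Sizes default to a desk-scale study: 1,000 genes x 400 cells
    (200 tumor + 200 normal), 50 planted DE genes at a natural-log fold
    change of 1.0, a 100-gene co-expressed module, 14 pathway genes, a
    ~500-node interaction graph and a 260-sample clinical table whose 2x2
    histology table is (66, 64, 45, 85).
    """

    n_cells_per_group: int = 200
    n_genes: int = 1000
    n_de_genes: int = 50
    de_logfc_mean: float = 1.0          # natural-log units, mean scale
    nb_dispersion: float = 0.3          # var = mu + a*mu^2
    library_size_mean: int = 5000
    n_module_genes: int = 100
    module_latent_sd: float = 0.8       # sd of the shared latent factor
    latent_group_shift: float = 1.5     # latent-factor mean offset in tumor cells
    n_pathway_genes: int = 14
    pathway_module_share: float = 0.7   # fraction of pathway genes on the factor
    ppi_n_background_genes: int = 400
    ppi_edge_prob: float = 0.001        # keeps chance 3-hop pathway reach realistic at desk scale
    regulator_direct_targets: int = 6
    n_decoy_sets: int = 20
    clinical_n: int = 260
    hazard_ratio_high_marker: float = 2.5
    contingency_counts: tuple[int, int, int, int] = (66, 64, 45, 85)
    exact_contingency: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_group <= 0:
            raise ConfigurationError("n_genes and n_cells_per_group must be positive")
        if self.n_de_genes < 0 or self.n_module_genes < 0 or self.n_pathway_genes < 0:
            raise ConfigurationError("gene-set sizes must be non-negative")
        if self.n_de_genes + self.n_module_genes > self.n_genes - N_MITO_GENES:
            raise ConfigurationError(
                "n_de_genes + n_module_genes exceeds the available gene count"
            )
        if self.n_pathway_genes > max(self.n_de_genes, 0) and self.n_de_genes > 0:
            # pathway genes are drawn from the DE set when DE genes exist
            if self.n_pathway_genes > self.n_de_genes:
                raise ConfigurationError(
                    "n_pathway_genes must not exceed n_de_genes when DE genes are planted"
                )
        if self.regulator_direct_targets > self.n_pathway_genes:
            raise ConfigurationError(
                "regulator_direct_targets must not exceed n_pathway_genes"
            )
        if not 0 <= self.pathway_module_share <= 1:
            raise ConfigurationError("pathway_module_share must lie in [0, 1]")
        if not 0 <= self.ppi_edge_prob <= 1:
            raise ConfigurationError("ppi_edge_prob must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.hazard_ratio_high_marker <= 0:
            raise ConfigurationError("hazard_ratio_high_marker must be positive")

    # one global seed -> four independent sub-streams
    def _rng(self, stream: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(stream,))
        return np.random.default_rng(ss)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _gene_symbols(config: SimulationConfig) -> tuple[list[str], GroundTruth]:
    """Lay out gene roles and symbols; ground truth minus the latent factor."""
    n_pwy = config.n_pathway_genes
    if n_pwy <= len(PATHWAY_SYMBOLS):
        pathway = PATHWAY_SYMBOLS[:n_pwy]
    else:
        pathway = [f"PWY{i:04d}" for i in range(n_pwy)]
    n_extra_de = max(config.n_de_genes - n_pwy, 0) if config.n_de_genes > 0 else 0
    extra_de = [f"DEG{i:04d}" for i in range(n_extra_de)]
    module = [REGULATOR_SYMBOL] + [f"MOD{i:04d}" for i in range(config.n_module_genes - 1)]
    module = module[: config.n_module_genes]
    mito = [f"MT-{i}" for i in range(1, N_MITO_GENES + 1)]
    n_bg = config.n_genes - n_pwy - len(extra_de) - len(module) - len(mito)
    if n_bg < 0:
        raise ConfigurationError("n_genes too small for the requested planted sets")
    background = [f"GENE{i:05d}" for i in range(n_bg)]
    genes = pathway + extra_de + module + mito + background
    de = set(pathway[: config.n_de_genes] + extra_de) if config.n_de_genes > 0 else set()
    truth = GroundTruth(
        de_gene_ids=de,
        module_gene_ids=set(module),
        pathway_gene_ids=set(pathway),
        planted_regulator_id=REGULATOR_SYMBOL if module else "",
    )
    return genes, truth


def gen_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial gene x cell counts with planted DE and module signal.

    Per-gene mean for cell ``c``:
    ``mu_gc = L_c * rel_g * exp(de_logfc_mean * [g in DE][c tumor]
    + loading_g * z_c)`` where ``L_c`` is a log-normal library size,
    ``rel_g`` a log-normal relative abundance, and ``z_c`` the shared
    latent factor (sd ``module_latent_sd``) that only module genes and a
    ``pathway_module_share`` fraction of pathway genes load on.  Counts
    are NB with ``var = mu + nb_dispersion * mu^2``.  Planted-signal genes
    are given moderate base abundance so they are detectably expressed,
    as biomarker genes are; mitochondrial genes carry ~8% of expression
    so default QC retains every cell.
    """
    config.validate()
    rng = config._rng(0)
    genes, truth = _gene_symbols(config)
    n_cells = 2 * config.n_cells_per_group
    cells = [f"CELL{i:05d}" for i in range(n_cells)]
    groups = ["tumor"] * config.n_cells_per_group + ["normal"] * config.n_cells_per_group
    meta = pd.DataFrame(
        {"sample": ["S1"] * n_cells, "group": groups}, index=pd.Index(cells, name="barcode")
    )

    special = truth.de_gene_ids | truth.module_gene_ids | truth.pathway_gene_ids
    is_mito = np.array([g.startswith("MT-") for g in genes])
    is_special = np.array([g in special for g in genes])

    # relative abundance weights: background heavy-tailed, planted genes moderate
    w = rng.lognormal(mean=0.0, sigma=1.5, size=len(genes))
    w[is_special] = rng.lognormal(mean=np.log(3.0), sigma=0.5, size=int(is_special.sum()))
    w[is_mito] = 0.0
    w[is_mito] = (MITO_FRACTION / (1 - MITO_FRACTION)) * w.sum() / max(N_MITO_GENES, 1)
    rel = w / w.sum()

    lib = rng.lognormal(np.log(config.library_size_mean) - 0.3**2 / 2, 0.3, size=n_cells)

    log_mu = np.log(rel)[:, None] + np.log(lib)[None, :]

    tumor = np.array([g == "tumor" for g in groups])
    de_rows = np.array([g in truth.de_gene_ids for g in genes])
    log_mu[np.ix_(de_rows, tumor)] += config.de_logfc_mean

    # the module's latent factor tracks tumor status (offset mean in tumor),
    # so the planted module is both internally co-expressed and
    # tumor-associated, like a disease-linked expression program
    z = rng.normal(0.0, 1.0, size=n_cells) + config.latent_group_shift * tumor
    n_pwy_on = int(np.floor(config.pathway_module_share * config.n_pathway_genes))
    pathway_ordered = [g for g in genes if g in truth.pathway_gene_ids]
    on_factor = truth.module_gene_ids | set(pathway_ordered[:n_pwy_on])
    factor_rows = np.array([g in on_factor for g in genes])
    if factor_rows.any():
        loadings = rng.uniform(0.7, 1.0, size=int(factor_rows.sum()))
        # the regulator is the program's hub: it carries the full loading
        factor_gene_names = [g for g, r in zip(genes, factor_rows) if r]
        if truth.planted_regulator_id in factor_gene_names:
            loadings[factor_gene_names.index(truth.planted_regulator_id)] = 1.0
        log_mu[factor_rows, :] += (
            config.module_latent_sd * loadings[:, None] * z[None, :]
        )

    mu = np.exp(log_mu)
    a = config.nb_dispersion
    n_param = 1.0 / a
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)

    truth.latent_factor = z
    cm = CountMatrix(genes=genes, cells=cells, counts=counts, cell_meta=meta)
    return cm, truth


def gen_gene_sets(config: SimulationConfig, truth: GroundTruth):
    """Pathway collection: ``PATHWAY_AKT`` = the planted pathway genes, plus decoys.

    Decoy sets are random draws (without replacement, within a set) from
    the full gene universe, sized like the pathway set; no decoy equals
    the pathway set.
    """
    from .enrich import GeneSetCollection

    rng = config._rng(1)
    genes, _ = _gene_symbols(config)
    pathway = sorted(truth.pathway_gene_ids)
    sets: dict[str, list[str]] = {"PATHWAY_AKT": pathway}
    size = max(len(pathway), 1)
    i = 0
    while len(sets) < config.n_decoy_sets + 1:
        draw = sorted(rng.choice(genes, size=size, replace=False).tolist())
        if set(draw) != set(pathway):
            sets[f"DECOY_{i:03d}"] = draw
            i += 1
    return GeneSetCollection(sets=sets, universe=list(genes))


def gen_ppi(config: SimulationConfig, truth: GroundTruth) -> nx.Graph:
    """Erdős–Rényi background plus planted regulator→pathway edges.

    Nodes are the module and pathway genes plus ``ppi_n_background_genes``
    other genes; edges are i.i.d. with ``ppi_edge_prob``; the planted
    regulator then gains direct edges to ``regulator_direct_targets``
    pathway genes.  The result is a simple undirected graph.
    """
    rng = config._rng(2)
    genes, _ = _gene_symbols(config)
    special = sorted(truth.module_gene_ids | truth.pathway_gene_ids)
    others = [g for g in genes if g not in set(special) and not g.startswith("MT-")]
    nodes = special + others[: config.ppi_n_background_genes]
    n = len(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if config.ppi_edge_prob > 0 and n > 1:
        iu, ju = np.triu_indices(n, k=1)
        pick = rng.random(iu.size) < config.ppi_edge_prob
        g.add_edges_from(
            (nodes[i], nodes[j]) for i, j in zip(iu[pick], ju[pick])
        )
    if truth.planted_regulator_id:
        pathway_ordered = [x for x in genes if x in truth.pathway_gene_ids]
        for target in pathway_ordered[: config.regulator_direct_targets]:
            if target != truth.planted_regulator_id:
                g.add_edge(truth.planted_regulator_id, target)
    return g


# stage probabilities for low / high marker samples (shifted toward late stage)
_STAGE_P_LOW = (0.24, 0.43, 0.25, 0.08)
_STAGE_P_HIGH = (0.12, 0.33, 0.35, 0.20)
_STAGES = ("I", "II", "III", "IV")


def gen_clinical(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Clinical sample table with marker-dependent hazard and 2x2 association.

    Survival times are exponential; samples above the marker cutoff have
    their hazard multiplied by ``hazard_ratio_high_marker`` (applied to
    both OS and DFS, with independent censoring).  In exact-contingency
    mode the cross-tab of (marker above cutoff) x histology equals
    ``contingency_counts = (a, b, c, d)`` exactly, with the marker cutoff
    at rank ``a + b`` from the top; otherwise histology is Bernoulli with
    the per-group positive rates implied by those counts.
    """
    if config.clinical_n <= 0:
        raise ConfigurationError("clinical_n must be positive")
    a, b, c, d = (int(x) for x in config.contingency_counts)
    if min(a, b, c, d) < 0:
        raise ConfigurationError("contingency_counts must be non-negative")
    if config.exact_contingency and a + b + c + d != config.clinical_n:
        raise ConfigurationError(
            f"contingency_counts sum to {a + b + c + d}, expected clinical_n={config.clinical_n}"
        )
    rng = config._rng(3)
    n = config.clinical_n
    marker = rng.lognormal(mean=1.0, sigma=0.5, size=n)

    # "high" = above the cutoff that the downstream median split reproduces
    n_high = a + b if config.exact_contingency else n // 2
    order = np.argsort(-marker, kind="stable")
    high = np.zeros(n, dtype=bool)
    high[order[:n_high]] = True

    hr = np.where(high, config.hazard_ratio_high_marker, 1.0)
    os_t = rng.exponential(1.0 / (0.01 * hr))
    os_c = rng.uniform(0, 120, size=n)
    dfs_t = rng.exponential(1.0 / (0.02 * hr))
    dfs_c = rng.uniform(0, 120, size=n)

    histology = np.zeros(n, dtype=int)
    hi_idx = np.flatnonzero(high)
    lo_idx = np.flatnonzero(~high)
    if config.exact_contingency:
        histology[rng.choice(hi_idx, size=a, replace=False)] = 1
        histology[rng.choice(lo_idx, size=c, replace=False)] = 1
    else:
        p_hi = a / max(a + b, 1)
        p_lo = c / max(c + d, 1)
        histology[hi_idx] = rng.random(hi_idx.size) < p_hi
        histology[lo_idx] = rng.random(lo_idx.size) < p_lo

    stage = np.empty(n, dtype=object)
    stage[hi_idx] = rng.choice(_STAGES, size=hi_idx.size, p=_STAGE_P_HIGH)
    stage[lo_idx] = rng.choice(_STAGES, size=lo_idx.size, p=_STAGE_P_LOW)

    return pd.DataFrame(
        {
            "sample_id": [f"PT{i:04d}" for i in range(n)],
            "marker_expression": marker,
            "os_time": np.minimum(os_t, os_c),
            "os_event": (os_t <= os_c).astype(int),
            "dfs_time": np.minimum(dfs_t, dfs_c),
            "dfs_event": (dfs_t <= dfs_c).astype(int),
            "stage": stage,
            "histology_positive": histology,
            "chemo": (rng.random(n) < 0.5).astype(int),
        }
    )
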
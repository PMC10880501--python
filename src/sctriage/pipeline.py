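"""End-to-end orchestration of the regulator-triage pipeline.

Stages run in order — QC → differential expression → enrichment →
co-expression modules → PPI level ranking → clinical validation — with
the DE ranking feeding enrichment, the selected module's genes becoming
the PPI candidate list, and the top enriched set becoming the PPI target
set.  A single :class:`PipelineConfig` (file paths or a simulation
config) plus its seeds fully determines the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from . import coexpr, de, enrich, io, ppi, qc
from .containers import ConfigurationError
from .simulate import SimulationConfig, gen_clinical, gen_counts, gen_gene_sets, gen_ppi

log = logging.getLogger("sctriage.pipeline")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for fail-fast diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    log.info("stage=%s start", name)
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as exc:  # surfaced with the stage name, fail fast
        raise PipelineStageError(name, str(exc)) from exc
    log.info("stage=%s done", name)


@dataclass
class PipelineConfig:
    """All inputs and stage parameters of one pipeline run.

    Exactly one of ``simulation`` or the file-path inputs must be given
    per data stream.  Every stochastic stage derives its seed from
    ``seed`` so identical configs give identical reports.
    """

    simulation: SimulationConfig | None = None
    counts_mtx_dir: str | None = None
    gmt_path: str | None = None
    edges_path: str | None = None
    clinical_path: str | None = None

    mito_prefix: str = "MT-"
    max_percent_mt: float = 20.0
    n_pcs: int = 30
    group_1: str = "tumor"
    group_2: str = "normal"
    min_pct: float = 0.25
    min_abs_logfc: float = 0.25
    gsea_weight_p: float = 1.0
    n_perm: int = 1000
    coexpr_top_n: int = 5000
    target_r2: float = 0.85
    min_module_size: int = 30
    cut_height: float | None = None  # None = overlap-scale adaptive cut
    target_set_name: str | None = None
    max_level: int = 3
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        file_inputs = [self.counts_mtx_dir, self.gmt_path, self.edges_path, self.clinical_path]
        if self.simulation is None and not all(file_inputs):
            raise ConfigurationError(
                "provide either a simulation config or all four file inputs"
            )
        if self.simulation is not None and any(file_inputs):
            raise ConfigurationError(
                "simulation config and file inputs are mutually exclusive"
            )

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class TriageReport:
    """Consolidated result of one pipeline run.

    Every reported number comes from a stage table held here; the
    provenance block records the config hash and seeds.
    """

    qc_summary: dict
    de_table: pd.DataFrame
    ora_table: pd.DataFrame
    gsea_table: pd.DataFrame
    target_set: str
    target_genes: list[str]
    beta: int
    scale_free_profile: pd.DataFrame
    best_scale_free_r2: float
    module_labels: pd.Series
    best_module: str
    module_hit_counts: pd.Series
    level_table: pd.DataFrame
    top_candidate: str
    clinical: dict
    provenance: dict
    truth_eval: dict | None = None

    def to_dict(self) -> dict:
        return {
            "qc_summary": self.qc_summary,
            "n_de_genes": int(len(self.de_table)),
            "target_set": self.target_set,
            "beta": self.beta,
            "best_scale_free_r2": self.best_scale_free_r2,
            "best_module": self.best_module,
            "module_sizes": self.module_labels.value_counts().to_dict(),
            "top_candidate": self.top_candidate,
            "level_table_head": self.level_table.head(10).to_dict(orient="records"),
            "clinical": self.clinical,
            "truth_eval": self.truth_eval,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, default=_jsonify)

    def to_markdown(self) -> str:
        lines = [
            "# Triage report",
            "",
            f"- config hash: `{self.provenance['config_hash']}`; seed: {self.provenance['seed']}",
            f"- cells analyzed: {self.qc_summary['n_cells_kept']} of {self.qc_summary['n_cells_in']}",
            f"- DE genes passing screen: {len(self.de_table)}",
            f"- top enriched set: **{self.target_set}**",
            f"- soft threshold beta = {self.beta} (signed scale-free R^2 = {self.best_scale_free_r2:.3f})",
            f"- selected module: **{self.best_module}** "
            f"({int((self.module_labels == self.best_module).sum())} genes)",
            f"- top-ranked candidate regulator: **{self.top_candidate}**",
            "",
            "## Level-count ranking (top 10)",
            "```",
            self.level_table.head(10).to_string(index=False),
            "```",
            "",
            "## Clinical validation",
        ]
        for k, v in self.clinical.items():
            lines.append(f"- {k}: {v}")
        if self.truth_eval is not None:
            lines += ["", "## Planted-truth evaluation"]
            for k, v in self.truth_eval.items():
                lines.append(f"- {k}: {v}")
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> None:
        d = Path(outdir)
        d.mkdir(parents=True, exist_ok=True)
        self.de_table.to_csv(d / "de_table.tsv", sep="\t", index=False)
        self.ora_table.to_csv(d / "ora_table.tsv", sep="\t", index=False)
        self.gsea_table.to_csv(d / "gsea_table.tsv", sep="\t", index=False)
        self.scale_free_profile.to_csv(d / "scale_free_profile.tsv", sep="\t", index=False)
        self.module_labels.rename("module").to_csv(d / "modules.tsv", sep="\t")
        self.level_table.to_csv(d / "level_counts.tsv", sep="\t", index=False)
        (d / "report.md").write_text(self.to_markdown())
        (d / "report.json").write_text(self.to_json())
        from . import plots

        plots.plot_scale_free_profile(
            self.scale_free_profile, 0.85, d / "scale_free_profile.png"
        )


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    return str(o)


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = config.simulation
        cm, truth = gen_counts(sim)
        sets = gen_gene_sets(sim, truth)
        graph = gen_ppi(sim, truth)
        table = gen_clinical(sim, truth)
        return cm, sets, graph, table, truth
    cm = io.read_counts_mtx(config.counts_mtx_dir)
    sets = enrich.GeneSetCollection.read_gmt(config.gmt_path)
    graph = io.read_edges(config.edges_path)
    table = io.read_clinical(config.clinical_path)
    return cm, sets, graph, table, None


def run_all(config: PipelineConfig) -> TriageReport:
    """Execute the whole triage and return the consolidated report."""
    config.validate()
    with _stage("inputs"):
        cm, sets, graph, clin_table, truth = _load_inputs(config)

    with _stage("qc"):
        metrics = qc.compute_qc(cm, mito_prefix=config.mito_prefix)
        kept = qc.filter_cells(cm, metrics, max_percent_mt=config.max_percent_mt)
        nm = qc.normalize(kept)
        embedding = qc.scale_and_pca(nm, n_components=min(config.n_pcs, kept.n_cells - 1))
        qc_summary = {
            "n_cells_in": cm.n_cells,
            "n_cells_kept": kept.n_cells,
            "median_nCount": float(metrics["nCount"].median()),
            "median_nFeature": float(metrics["nFeature"].median()),
            "max_percent_mt": float(metrics["percent_mt"].max()),
            "n_pcs": int(embedding.shape[1]),
        }

    with _stage("diff_expr"):
        de_full = de.wilcoxon_de(
            nm, config.group_1, config.group_2, min_pct=0.0, min_abs_logfc=0.0
        )
        de_table = de_full[
            (np.maximum(de_full["pct_1"], de_full["pct_2"]) > config.min_pct)
            & (de_full["avg_logFC"].abs() > config.min_abs_logfc)
        ].copy()
        n_tested = len(de_table)
        de_table["p_val_adj"] = np.minimum(de_table["p_val"] * n_tested, 1.0)
        de_table = de_table.sort_values(["p_val", "gene"], kind="stable").reset_index(drop=True)

    with _stage("enrichment"):
        ranked = de_full.assign(neg_log_p=-np.log10(de_full["p_val"].clip(lower=1e-300)))
        ranked = ranked.sort_values(
            ["avg_logFC", "neg_log_p", "gene"], ascending=[False, False, True], kind="stable"
        )
        universe = set(de_full["gene"])
        hits = set(de_table["gene"])
        ora_table = enrich.ora_hypergeometric(hits, universe, sets)
        gsea_seed = int(np.random.SeedSequence(config.seed, spawn_key=(10,)).generate_state(1)[0] % (2**31))
        gsea_table = enrich.gsea(
            ranked["gene"].tolist(),
            ranked["avg_logFC"].to_numpy(),
            sets,
            weight_p=config.gsea_weight_p,
            n_perm=config.n_perm,
            seed=gsea_seed,
        )
        if config.target_set_name is not None:
            target_set = config.target_set_name
        else:
            up = gsea_table[(~gsea_table["skipped"]) & (gsea_table["NES"] > 0)]
            if len(up) == 0:
                raise PipelineStageError("enrichment", "no positively enriched set found")
            target_set = up.sort_values(["q", "p", "set_name"]).iloc[0]["set_name"]
        target_genes = [g for g in sets.sets[target_set] if g in set(nm.genes)]

    with _stage("coexpr"):
        top_n = min(config.coexpr_top_n, len(nm.genes))
        selected = coexpr.select_variable_genes(nm, n=top_n)
        gi = {g: i for i, g in enumerate(nm.genes)}
        sd = nm.values.std(axis=1)
        selected = [g for g in selected if sd[gi[g]] > 0]
        S = coexpr.correlation_matrix(nm, selected)
        beta, profile = coexpr.soft_threshold_scan(S, target_r2=config.target_r2)
        A = coexpr.adjacency(S, beta)
        T = coexpr.tom(A)
        labels = coexpr.cluster_modules(
            1.0 - T, min_module_size=config.min_module_size, cut_height=config.cut_height
        )
        traits = pd.DataFrame(
            {"tumor": (nm.cell_meta["group"] == config.group_1).astype(float).to_numpy()},
            index=nm.cells,
        )
        if (labels != coexpr.GREY).any():
            mp = coexpr.module_pathway_correlation(nm, labels, target_genes, traits=traits)
            best_module = mp.best_module
            hit_counts = mp.pathway_hit_counts
            candidates = sorted(labels.index[labels == best_module])
        else:
            # no module survived the cut: fall back to all selected genes
            warnings.warn("no co-expression module detected; using all selected genes "
                          "as PPI candidates", stacklevel=2)
            best_module = coexpr.GREY
            hit_counts = pd.Series(dtype=int)
            candidates = sorted(labels.index)

    with _stage("ppi_levels"):
        level_table = ppi.rank_candidates(
            graph, candidates, set(target_genes), max_level=config.max_level
        )
        top_candidate = str(level_table.iloc[0]["gene"])

    with _stage("clinical"):
        marker = clin_table["marker_expression"].to_numpy(dtype=float)
        high = marker > np.median(marker)
        hist = clin_table["histology_positive"].to_numpy(dtype=int)
        table2 = [
            [int((high & (hist == 1)).sum()), int((high & (hist == 0)).sum())],
            [int((~high & (hist == 1)).sum()), int((~high & (hist == 0)).sum())],
        ]
        chi = clin.chisq_2x2(table2)
        km_os = clin.km_logrank(clin_table, endpoint="OS")
        km_dfs = clin.km_logrank(clin_table, endpoint="DFS")
        auc, _curve = clin.roc_auc(marker, hist)
        stage_tab = clin.stage_comparison(clin_table)
        clinical_summary = {
            "contingency_table": table2,
            "chi_square": round(chi.chi_square, 3),
            "chi_square_p": chi.p,
            "logrank_OS_stat": km_os.logrank_stat,
            "logrank_OS_p": km_os.p,
            "logrank_DFS_stat": km_dfs.logrank_stat,
            "logrank_DFS_p": km_dfs.p,
            "roc_auc_marker_vs_histology": auc,
            "stage_means": stage_tab.to_dict(orient="records"),
        }

    truth_eval = None
    if truth is not None:
        planted = truth.de_gene_ids
        recovered = set(de_table.loc[de_table["p_val_adj"] < 0.05, "gene"])
        module_genes = set(candidates)
        reg = truth.planted_regulator_id
        reg_rank = level_table.loc[level_table["gene"] == reg, "rank"]
        inter = len(module_genes & truth.module_gene_ids)
        union = len(module_genes | truth.module_gene_ids)
        truth_eval = {
            "de_recovery": (len(planted & recovered) / len(planted)) if planted else None,
            "module_jaccard": inter / union if union else None,
            "regulator_rank": int(reg_rank.iloc[0]) if len(reg_rank) else None,
            "regulator_is_top": bool(top_candidate == reg),
        }

    report = TriageReport(
        qc_summary=qc_summary,
        de_table=de_table,
        ora_table=ora_table,
        gsea_table=gsea_table,
        target_set=target_set,
        target_genes=target_genes,
        beta=beta,
        scale_free_profile=profile,
        best_scale_free_r2=float(profile["signed_r2"].max()),
        module_labels=labels,
        best_module=best_module,
        module_hit_counts=hit_counts,
        level_table=level_table,
        top_candidate=top_candidate,
        clinical=clinical_summary,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_perm": config.n_perm,
            "beta_powers_scanned": "1..20",
        },
        truth_eval=truth_eval,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report
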
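# sctriage

**Single-cell to network triage of candidate pathway regulators.**

Tumor biology often needs an answer to a very specific question: *which
gene, among the members of a disease-associated co-expression program, is
best placed to regulate a signaling pathway of interest?*  `sctriage`
implements a complete computational triage for that question, of the kind
used to nominate upstream regulators of the PI3K–AKT cascade in
colorectal cancer from single-cell RNA-seq, protein-interaction maps and
clinical cohorts:

1. **QC and normalization** of a gene × cell count matrix
   (nCount / nFeature / percent-mitochondrial metrics, strict `< 20%`
   mito filter, log-normalization, scaled PCA).
2. **Differential expression** between tumor and normal cells: two-sided
   Wilcoxon rank-sum per gene, natural-log fold change
   `ln(mean₁+1) − ln(mean₂+1)` of back-transformed expression, detection
   fractions per group, Bonferroni adjustment.
3. **Gene-set enrichment**: hypergeometric over-representation and
   ranked permutation GSEA (weighted Kolmogorov–Smirnov running sum,
   gene-label permutation null, sign-matched NES, BH q-values) against
   GMT collections.
4. **Weighted co-expression network**: Pearson correlation `S`,
   soft-thresholded adjacency `A_mn = |S_mn|^β` with β chosen by the
   scale-free topology criterion (signed fit R² ≥ 0.85), topological
   overlap matrix (TOM), average-linkage module detection, module
   eigengenes and module–pathway/trait correlation.
5. **PPI level scoring**: on an undirected interaction graph, each
   candidate's level-1/2/3 counts are the number of pathway genes at
   shortest-path distance exactly 1, 2, 3; candidates are ranked by the
   sum.  This is the score that puts the true regulator at rank 1.
6. **Clinical validation**: Kaplan–Meier with log-rank after a median
   expression split, Pearson chi-square on 2×2 tables (no continuity
   correction, reproducing the classical 6.933 on the 66/64/45/85
   table), Welch tests across stages, Pearson correlation, ROC/AUC.

A first-class **synthetic-data module** generates every input with
planted ground truth — negative-binomial counts with planted DE genes, a
latent-factor co-expression module, an Erdős–Rényi interaction graph
with a planted regulator wired to the pathway, and clinical tables with
a known hazard ratio and an exact 2×2 cross-tabulation — so the entire
pipeline is testable end-to-end without downloading anything.

## Worked example

```python
from sctriage import PipelineConfig, SimulationConfig, run_all

cfg = PipelineConfig(simulation=SimulationConfig(seed=7), seed=7)
report = run_all(cfg)
print(report.to_markdown())
```

prints (abridged):

```
# Triage report

- cells analyzed: 400 of 400
- DE genes passing screen: 366
- top enriched set: **PATHWAY_AKT**
- soft threshold beta = 6 (signed scale-free R^2 = 0.948)
- selected module: **M1** (109 genes)
- top-ranked candidate regulator: **MDFI**

## Level-count ranking (top 10)
    gene  level1  level2  level3  total  rank
    MDFI       6       1       0      7     1
HSP90AA1       1       5       0      6     2
    SPP1       1       0       5      6     3
...

## Clinical validation
- contingency_table: [[66, 64], [45, 85]]
- chi_square: 6.933
- chi_square_p: 0.00846...
- logrank_OS_p: 2.06e-07
```

Reading the output: 366 genes pass the DE screen; the planted AKT-like
pathway is the top enriched set; the co-expression scan settles on
β = 6 with a scale-free fit above the 0.85 criterion; the selected
109-gene module contains the planted regulator, and the level-count
ranking places it at rank 1 (6 direct pathway contacts).  The clinical
block reproduces the chi-square of 6.933 (p ≈ 0.008) on the planted
2×2 table and a strongly significant survival split.

The same stages are available from the shell:

```bash
sctriage simulate --seed 7 --out data/
sctriage qc --counts data/counts --max-mt 20 --out out/
sctriage de --counts data/counts --group1 tumor --group2 normal --out out/de.tsv
sctriage enrich --de-table out/de.tsv --gmt data/sets.gmt --nperm 1000 --seed 7 --out out/gsea.tsv
sctriage coexpr --counts data/counts --top-n 5000 --out out/
sctriage ppi-rank --edges data/edges.tsv --candidates cand.txt --targets targ.txt --out out/rank.tsv
sctriage clinical --table data/clinical.csv --out out/clinical.json
sctriage run-all --seed 7 --out out/report
```

## Layout

```
src/sctriage/
  simulate.py   # synthetic inputs with planted ground truth
  qc.py         # QC metrics, filtering, normalization, PCA
  de.py         # Wilcoxon differential expression
  enrich.py     # GMT collections, ORA, permutation GSEA
  coexpr.py     # soft threshold, TOM, modules, eigengenes
  ppi.py        # level-1/2/3 counts and candidate ranking
  clinical.py   # KM/log-rank, chi-square, ROC, stage stats
  pipeline.py   # run_all orchestration + TriageReport
  io.py         # MTX/TSV/GMT/CSV/JSON readers and writers
  cli.py        # click command-line interface
```

See `docs/methods.md` for the modeling assumptions, parameter defaults
and known limitations.
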
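"""Co-expression network tests: brute-force oracles, fixtures, recovery."""

import numpy as np
import pandas as pd
import pytest

from sctriage import SimulationConfig
from sctriage.coexpr import (
    GREY,
    adjacency,
    cluster_modules,
    correlation_matrix,
    module_eigengenes,
    module_pathway_correlation,
    scale_free_fit,
    select_variable_genes,
    soft_threshold_scan,
    tom,
)
from sctriage.qc import normalize
from sctriage.simulate import gen_counts

from conftest import make_count_matrix


def tom_triple_loop(a):
    """Independent elementwise oracle for the topological overlap matrix."""
    n = a.shape[0]
    out = np.eye(n)
    k = np.array([sum(a[m, u] for u in range(n) if u != m) for m in range(n)])
    for m in range(n):
        for q in range(n):
            if m == q:
                continue
            shared = sum(a[m, u] * a[u, q] for u in range(n) if u not in (m, q))
            out[m, q] = (shared + a[m, q]) / (min(k[m], k[q]) + 1 - a[m, q])
    return out


def random_adjacency(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


@pytest.mark.parametrize("seed", range(10))
def test_tom_matches_triple_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    a = random_adjacency(rng, 10)
    assert np.allclose(tom(a), tom_triple_loop(a), atol=1e-12)


def test_tom_bounds_on_many_random_matrices():
    rng = np.random.default_rng(99)
    for _ in range(100):
        t = np.asarray(tom(random_adjacency(rng, 10)))
        assert (t >= -1e-12).all() and (t <= 1 + 1e-12).all()
        assert np.allclose(t, t.T)


def test_tom_trivial_cases():
    # two genes connected only to each other with full weight
    a = np.array([[1.0, 1.0], [1.0, 1.0]])
    assert np.asarray(tom(a))[0, 1] == pytest.approx(1.0)
    # disconnected pair with no shared neighbors
    a = np.eye(4)
    assert np.asarray(tom(a))[0, 1] == pytest.approx(0.0)


def test_adjacency_elementwise():
    s = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
    assert adjacency(s, 2).loc["a", "b"] == pytest.approx(0.25)
    assert np.allclose(adjacency(s, 1), np.abs(s))
    rng = np.random.default_rng(0)
    m = rng.uniform(-1, 1, size=(6, 6))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    s = pd.DataFrame(m)
    assert np.allclose(adjacency(s, 7), np.abs(m) ** 7, atol=1e-15)


def test_variable_gene_selection_matches_variance_sort():
    rng = np.random.default_rng(1)
    counts = rng.poisson(3.0, size=(40, 30))
    counts[5] = 2  # constant gene ranks last
    cm = make_count_matrix(counts)
    nm = normalize(cm)
    sel = select_variable_genes(nm, n=10)
    var = nm.values.var(axis=1, ddof=1)
    oracle = [nm.genes[i] for i in sorted(range(40), key=lambda i: (-var[i], nm.genes[i]))][:10]
    assert sel == oracle
    assert "G5" not in sel
    assert select_variable_genes(nm, n=40) == [
        nm.genes[i] for i in sorted(range(40), key=lambda i: (-var[i], nm.genes[i]))
    ]


def test_scale_free_fit_on_exact_power_law():
    # log-uniform k has density ~ 1/k: slope -1 on the log-log histogram
    rng = np.random.default_rng(2)
    k = 10 ** rng.uniform(0, 3, size=5000)
    r2, slope = scale_free_fit(k)
    assert r2 > 0.97
    assert slope == pytest.approx(-1.0, abs=0.15)


def test_scale_free_fit_degenerate_inputs():
    assert scale_free_fit(np.ones(100)) == (0.0, 0.0)
    # less than two decades of range: no power-law claim
    assert scale_free_fit(np.linspace(10, 99, 100))[0] == 0.0


def test_soft_threshold_fallback_on_uncorrelated_data():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(30, 40))
    s = pd.DataFrame(np.corrcoef(x))
    with pytest.warns(UserWarning):
        beta, profile = soft_threshold_scan(s, powers=[1, 2], target_r2=0.99)
    assert beta in (1, 2)
    assert len(profile) == 2


def test_cluster_modules_recovers_planted_blocks():
    n = 80
    d = np.full((n, n), 0.95)
    d[:35, :35] = 0.2
    d[35:70, 35:70] = 0.25
    np.fill_diagonal(d, 0.0)
    labels = cluster_modules(pd.DataFrame(d), min_module_size=30)
    assert set(labels[:35]) == {"M1"}
    assert set(labels[35:70]) == {"M2"}
    assert set(labels[70:]) == {GREY}


def test_cluster_modules_all_equal_dissimilarity_single_module():
    n = 40
    d = np.full((n, n), 0.5)
    np.fill_diagonal(d, 0.0)
    labels = cluster_modules(pd.DataFrame(d), min_module_size=30)
    assert set(labels) == {"M1"}  # everything merges at one height


def test_gene_permutation_leaves_partition_invariant():
    rng = np.random.default_rng(4)
    n = 60
    d = np.full((n, n), 0.9) + rng.normal(0, 0.01, (n, n))
    d[:32, :32] = 0.2 + rng.normal(0, 0.01, (32, 32))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    genes = [f"g{i:02d}" for i in range(n)]
    df = pd.DataFrame(d, index=genes, columns=genes)
    labels = cluster_modules(df, min_module_size=20)
    perm = rng.permutation(n)
    df_p = df.iloc[perm, perm]
    labels_p = cluster_modules(df_p, min_module_size=20)
    groups = lambda lab: {
        frozenset(lab.index[lab == m]) for m in set(lab) if m != GREY
    }
    assert groups(labels) == groups(labels_p)


def test_eigengene_correlates_with_members(default_normalized):
    nm, truth = default_normalized
    genes = sorted(truth.module_gene_ids)
    labels = pd.Series("M1", index=genes)
    eig = module_eigengenes(nm, labels)
    assert np.linalg.norm(eig["M1"]) == pytest.approx(1.0)
    gi = {g: i for i, g in enumerate(nm.genes)}
    rs = [np.corrcoef(eig["M1"], nm.values[gi[g]])[0, 1] for g in genes[:20]]
    assert np.mean(rs) > 0.3
    assert all(abs(r) > 0 for r in rs)


def test_module_pathway_correlation_selects_planted_module():
    hits = 0
    for seed in range(5):
        cm, truth = gen_counts(SimulationConfig(seed=seed))
        nm = normalize(cm)
        sel = select_variable_genes(nm, n=1000)
        sd = nm.values.std(axis=1)
        gi = {g: i for i, g in enumerate(nm.genes)}
        sel = [g for g in sel if sd[gi[g]] > 0]
        s = correlation_matrix(nm, sel)
        beta, _ = soft_threshold_scan(s)
        labels = cluster_modules(1.0 - tom(adjacency(s, beta)))
        res = module_pathway_correlation(
            nm, labels, sorted(truth.pathway_gene_ids)
        )
        members = set(labels.index[labels == res.best_module])
        inter = len(members & truth.module_gene_ids)
        union = len(members | truth.module_gene_ids)
        assert inter / union >= 0.8, f"seed {seed}: Jaccard {inter / union:.2f}"
        hits += truth.planted_regulator_id in members
    assert hits == 5


def test_constant_trait_reported_as_missing(default_normalized):
    nm, truth = default_normalized
    genes = sorted(truth.module_gene_ids)
    labels = pd.Series("M1", index=genes)
    traits = pd.DataFrame({"flat": np.ones(len(nm.cells))}, index=nm.cells)
    res = module_pathway_correlation(nm, labels, genes[:3], traits=traits)
    assert np.isnan(res.correlations[("trait", "flat")]).all()
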
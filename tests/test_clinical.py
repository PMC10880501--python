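"""Clinical statistics tests: closed-form oracles, hand ledgers, calibration."""

import numpy as np
import pandas as pd
import pytest

from sctriage import InputError, SimulationConfig
from sctriage.clinical import (
    chisq_2x2,
    group_compare,
    km_logrank,
    pearson_r,
    roc_auc,
    stage_comparison,
)
from sctriage.simulate import gen_clinical


def test_pearson_perfect_and_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_r(x, x)[0] == pytest.approx(1.0)
    assert pearson_r(x, -x)[0] == pytest.approx(-1.0)
    y = np.array([2.0, 1.0, 4.0, 3.0])
    r_oracle = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
    assert pearson_r(x, y)[0] == pytest.approx(r_oracle, abs=1e-12)
    with pytest.raises(InputError):
        pearson_r(x, np.ones(4))


def test_pearson_invariant_to_positive_affine_transform():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=50), rng.normal(size=50)
    r0 = pearson_r(x, y)[0]
    assert pearson_r(3 * x + 7, y)[0] == pytest.approx(r0, abs=1e-12)
    assert pearson_r(x, 0.1 * y - 2)[0] == pytest.approx(r0, abs=1e-12)


def test_welch_hand_computed_3v3():
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([2.0, 4.0, 9.0])
    va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
    t_oracle = (a.mean() - b.mean()) / np.sqrt(va + vb)
    t, p, stars = group_compare(
        np.concatenate([a, b]), np.array([0, 0, 0, 1, 1, 1])
    )
    assert t == pytest.approx(t_oracle, abs=1e-12)
    assert stars in {"ns", "*", "**", "***"}


def test_welch_degenerate_identical_groups():
    t, p, stars = group_compare(np.array([5.0] * 6), np.array([0, 0, 0, 1, 1, 1]))
    assert t == 0.0 and p == 1.0 and stars == "ns"


def test_welch_power_on_shifted_normals():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        _, p, _ = group_compare(np.concatenate([a, b]), np.repeat([0, 1], 50))
        hits += p < 0.01
    assert hits >= 19


def _hand_logrank(times, events, groups):
    """Explicit O/E/V ledger over distinct event times (group 1 as test group)."""
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_km_logrank_matches_hand_ledger():
    ct = pd.DataFrame(
        {
            "marker_expression": [1, 1, 1, 10, 10, 10],
            "os_time": [5.0, 8.0, 12.0, 3.0, 6.0, 9.0],
            "os_event": [1, 1, 0, 1, 1, 1],
            "dfs_time": [5.0, 8.0, 12.0, 3.0, 6.0, 9.0],
            "dfs_event": [1, 1, 0, 1, 1, 1],
        }
    )
    res = km_logrank(ct, endpoint="OS")
    oracle = _hand_logrank(
        ct["os_time"].to_numpy(),
        ct["os_event"].to_numpy(),
        (ct["marker_expression"] > ct["marker_expression"].median()).astype(int).to_numpy(),
    )
    assert res.logrank_stat == pytest.approx(oracle, rel=1e-6)
    assert res.group_sizes == (3, 3)
    assert set(res.curves) == {"low", "high"}


def test_km_logrank_zero_for_identical_groups():
    times = [2.0, 4.0, 6.0, 8.0]
    events = [1, 1, 1, 0]
    ct = pd.DataFrame(
        {
            "marker_expression": [1, 1, 1, 1, 9, 9, 9, 9],
            "os_time": times + times,
            "os_event": events + events,
        }
    )
    res = km_logrank(ct, endpoint="OS")
    assert res.logrank_stat == pytest.approx(0.0, abs=1e-12)


def test_km_logrank_invariant_to_monotone_time_transform():
    rng = np.random.default_rng(1)
    ct = pd.DataFrame(
        {
            "marker_expression": rng.normal(size=60),
            "os_time": rng.exponential(10, 60),
            "os_event": rng.integers(0, 2, 60),
        }
    )
    if ct["os_event"].sum() < 2:
        ct.loc[:1, "os_event"] = 1
    r1 = km_logrank(ct, "OS")
    ct2 = ct.assign(os_time=np.log1p(ct["os_time"]))
    r2 = km_logrank(ct2, "OS")
    assert r1.logrank_stat == pytest.approx(r2.logrank_stat, rel=1e-9)


def test_km_power_under_generated_hazard_ratio():
    hits = 0
    for seed in range(20):
        cfg = SimulationConfig(clinical_n=300, hazard_ratio_high_marker=2.5,
                               exact_contingency=False, seed=300 + seed)
        ct = gen_clinical(cfg, None)
        hits += km_logrank(ct, "OS").p < 0.05
    assert hits >= 18


def test_chisq_printed_value_and_dual_formula():
    res = chisq_2x2([[66, 64], [45, 85]])
    assert res.chi_square == pytest.approx(6.933, abs=5e-4)
    assert res.df == 1
    assert res.p == pytest.approx(0.008, abs=5e-4)
    # independence
    assert chisq_2x2([[10, 10], [10, 10]]).chi_square == 0.0
    rng = np.random.default_rng(2)
    for _ in range(200):
        t = rng.integers(1, 60, size=(2, 2)).astype(float)
        a, b, c, d = t.ravel()
        n = t.sum()
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        exp = np.outer(t.sum(1), t.sum(0)) / n
        cellwise = ((t - exp) ** 2 / exp).sum()
        got = chisq_2x2(t).chi_square
        assert got == pytest.approx(closed, abs=1e-10)
        assert got == pytest.approx(cellwise, abs=1e-10)


def test_chisq_yates_flag_and_margin_errors():
    assert chisq_2x2([[66, 64], [45, 85]], correction=True).chi_square == pytest.approx(
        6.28, abs=0.01
    )
    with pytest.raises(InputError):
        chisq_2x2([[0, 0], [5, 5]])


def test_roc_auc_trivial_and_concordance_oracle():
    assert roc_auc(np.array([1, 2, 3, 10, 11, 12]), np.array([0, 0, 0, 1, 1, 1]))[0] == 1.0
    assert roc_auc(np.ones(10), np.repeat([0, 1], 5))[0] == 0.5
    rng = np.random.default_rng(3)
    scores = rng.normal(size=60)
    labels = rng.integers(0, 2, 60)
    if labels.sum() in (0, 60):
        labels[0] = 1 - labels[0]
    auc, curve = roc_auc(scores, labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    conc = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
    assert auc == pytest.approx(conc, abs=1e-12)
    assert {"fpr", "tpr"} <= set(curve.columns)


def test_roc_auc_complement_identity_and_errors():
    rng = np.random.default_rng(4)
    scores = rng.normal(size=40)  # continuous: tie-free
    labels = np.repeat([0, 1], 20)
    a1, _ = roc_auc(scores, labels)
    a2, _ = roc_auc(-scores, labels)
    assert a1 + a2 == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(InputError):
        roc_auc(scores, np.zeros(40, dtype=int))


def test_roc_auc_null_near_half():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=4000)
    labels = rng.integers(0, 2, 4000)
    assert roc_auc(scores, labels)[0] == pytest.approx(0.5, abs=0.03)


def test_stage_comparison_reports_means_and_adjacent_tests():
    cfg = SimulationConfig(seed=8)
    ct = gen_clinical(cfg, None)
    tab = stage_comparison(ct)
    assert tab["stage"].tolist() == ["I", "II", "III", "IV"]
    assert tab["n"].sum() == len(ct)
    assert tab["p_vs_previous"].notna().sum() == 3
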
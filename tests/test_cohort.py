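"""Cohort statistics: exact tests vs brute-force oracles, collapsing rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, rankdata

from fieldclone.cohort import (burden_model, ccf_vs_epithelial,
                               classify_expansion, collapse_per_patient,
                               correlate, fisher_exact_2x2, group_compare,
                               max_retained_ccf)
from fieldclone.dp import ClusterResult


# --- brute-force oracles --------------------------------------------------

def fisher_brute_force(table):
    """Sum hypergeometric probabilities <= that of the observed table."""
    (a, b), (c, d) = table
    r1, c1 = a + b, a + c
    N = a + b + c + d
    p_obs = hypergeom.pmf(a, N, r1, c1)
    total = 0.0
    for aa in range(max(0, c1 - (N - r1)), min(r1, c1) + 1):
        p = hypergeom.pmf(aa, N, r1, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def ranksum_brute_force(x, y):
    """Two-sided exact Mann-Whitney p over all group assignments."""
    n1, n = len(x), len(x) + len(y)
    ranks = rankdata(np.concatenate([x, y]))
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array([ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
                   for idx in itertools.combinations(range(n), n1)])
    p = 2 * min((us <= obs_u).mean(), (us >= obs_u).mean())
    return min(p, 1.0)


# --- Fisher ---------------------------------------------------------------

def test_fisher_reproduces_expansion_contrast():
    # 23/37 expansions in cancer normals vs 1/7 in non-cancer normals
    assert fisher_exact_2x2([[23, 14], [1, 6]]) == pytest.approx(0.035, abs=5e-4)


def test_fisher_zero_margin_is_one():
    assert fisher_exact_2x2([[0, 0], [3, 5]]) == pytest.approx(1.0)
    assert fisher_exact_2x2([[2, 0], [5, 0]]) == pytest.approx(1.0)


def test_fisher_rejects_bad_tables():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        fisher_exact_2x2([[-1, 2], [3, 4]])


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(11)
    for _ in range(40):
        t = rng.integers(0, 7, size=(2, 2))
        if t.sum() > 20:
            continue
        assert fisher_exact_2x2(t) == pytest.approx(
            fisher_brute_force(t.tolist()), abs=1e-9)


# --- rank tests -----------------------------------------------------------

def _df(groups_values):
    rows = []
    i = 0
    for g, values in groups_values.items():
        for v in values:
            rows.append({"patient_id": f"p{i}", "group": g, "value": v})
            i += 1
    return pd.DataFrame(rows)


def test_patient_median_collapsing():
    df = pd.DataFrame([
        {"patient_id": "p1", "group": "a", "value": 3},
        {"patient_id": "p1", "group": "a", "value": 5},
        {"patient_id": "p1", "group": "a", "value": 9},
        {"patient_id": "p2", "group": "a", "value": 7},
    ])
    out = collapse_per_patient(df)
    assert out[out.patient_id == "p1"].value.iloc[0] == 5


def test_collapsing_idempotent_and_order_invariant():
    df = _df({"a": [1, 2, 3, 4]})
    once = collapse_per_patient(df)
    twice = collapse_per_patient(once)
    pd.testing.assert_frame_equal(
        once.sort_values("patient_id").reset_index(drop=True),
        twice.sort_values("patient_id").reset_index(drop=True))
    shuffled = collapse_per_patient(df.sample(frac=1, random_state=0))
    assert sorted(shuffled.value) == sorted(once.value)


def test_identical_groups_p_one():
    df = _df({"a": [1.5, 2.5, 3.5, 4.5], "b": [1.5, 2.5, 3.5, 4.5]})
    res = group_compare(df)
    assert res["p_value"] == pytest.approx(1.0)


def test_exact_ranksum_matches_brute_force():
    rng = np.random.default_rng(12)
    for _ in range(10):
        x = rng.normal(size=6)
        y = rng.normal(loc=rng.uniform(0, 2), size=6)
        df = _df({"a": x, "b": y})
        res = group_compare(df)
        assert res["p_value"] == pytest.approx(ranksum_brute_force(x, y),
                                               abs=1e-9)


def test_paired_comparison_drops_incomplete_pairs():
    rows = []
    for i in range(6):
        rows.append({"patient_id": f"p{i}", "group": "n", "value": 10 + i})
        rows.append({"patient_id": f"p{i}", "group": "t", "value": 30 + 2 * i})
    rows.append({"patient_id": "p_lone", "group": "n", "value": 5})
    res = group_compare(pd.DataFrame(rows), paired=True)
    assert res["n"] == 6
    assert res["p_value"] < 0.05  # consistent direction across all pairs


# --- correlation ----------------------------------------------------------

def test_spearman_perfect_monotone():
    rho, _ = correlate([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
    assert rho == pytest.approx(1.0)
    rho, _ = correlate([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
    assert rho == pytest.approx(-1.0)


def test_spearman_constant_vector_undefined():
    rho, p = correlate([1, 1, 1, 1], [1, 2, 3, 4])
    assert np.isnan(rho) and np.isnan(p)


def test_spearman_exact_permutation_matches_brute_force():
    rng = np.random.default_rng(13)
    x = rng.normal(size=6)
    y = rng.normal(size=6)
    rho, p = correlate(x, y)
    rx, ry = rankdata(x), rankdata(y)

    def pear(u, v):
        u = u - u.mean()
        v = v - v.mean()
        return (u @ v) / np.sqrt((u @ u) * (v @ v))

    obs = abs(pear(rx, ry))
    perms = [abs(pear(rx, ry[list(pi)]))
             for pi in itertools.permutations(range(6))]
    expected = np.mean([r >= obs - 1e-12 for r in perms])
    assert p == pytest.approx(expected, abs=1e-12)


# --- burden model ---------------------------------------------------------

def test_burden_model_null_effect_exact_zero():
    age = np.array([50, 55, 60, 65, 70, 75], float)
    status = np.array([0, 1, 0, 1, 0, 1], float)
    y = 2 * age + 10  # burden depends only on age
    res = burden_model(y, status, age)
    assert res["coefficient"] == pytest.approx(0.0, abs=1e-9)


def test_burden_model_recovers_injected_status_effect():
    rng = np.random.default_rng(14)
    n = 37
    status = (np.arange(n) < 30).astype(float)
    age = rng.uniform(45, 80, n)
    y = 100 + 362 * status + 1.5 * age + rng.normal(0, 50, n)
    res = burden_model(y, status, age)
    assert abs(res["coefficient"] - 362) < 3 * res["se"]
    assert res["p_value"] < 0.05


def test_burden_model_collinear_design_raises():
    age = np.array([50, 50, 60, 60], float)
    status = np.array([1, 1, 1, 1], float)
    with pytest.raises(np.linalg.LinAlgError):
        burden_model([1, 2, 3, 4], status, age)


# --- expansions -----------------------------------------------------------

def _cluster(retained, reason, ccf=0.5):
    return ClusterResult(cluster_id=1, ccf={"S": ccf}, n_snvs=50,
                         fraction_of_total=0.5, retained=retained,
                         removal_reason=reason)


def test_classify_expansion():
    assert classify_expansion([_cluster(True, "none")])
    assert not classify_expansion([_cluster(False, "support"),
                                   _cluster(False, "neutrality")])
    assert not classify_expansion([])
    # present-in-sample requirement
    assert not classify_expansion([_cluster(True, "none", ccf=0.0)], "S")


def test_max_retained_ccf():
    clusters = [_cluster(True, "none", 0.4), _cluster(False, "support", 0.9)]
    assert max_retained_ccf(clusters, "S") == pytest.approx(0.4)
    assert np.isnan(max_retained_ccf([], "S"))


def test_ccf_vs_epithelial_violations_and_p():
    df = pd.DataFrame({
        "max_ccf": np.linspace(0.5, 0.9, 12),
        "epithelial_pct": np.linspace(20, 40, 12),
    })
    res = ccf_vs_epithelial(df)
    assert res["violations"] == 0
    assert res["p_value"] < 0.05


def test_ccf_vs_epithelial_single_pair():
    df = pd.DataFrame({"max_ccf": [0.8], "epithelial_pct": [30.0]})
    res = ccf_vs_epithelial(df)
    assert res["n_pairs"] == 1
    assert np.isnan(res["p_value"])
    assert res["median_difference"] == pytest.approx(50.0)
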
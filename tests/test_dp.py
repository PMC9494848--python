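"""Dirichlet-process clustering and the retention filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_clone_variants, make_metas
from fieldclone.dp import ClusterResult, ConfigurationError, GibbsSettings
from fieldclone.dp import assign_indels, filter_support, fit_dirichlet_process
from fieldclone.dp import test_background as background_binomial_test

FAST = GibbsSettings(iterations=800, burn_in=400, seed=1)


def retained_clusters(clusters):
    return [c for c in clusters if c.retained]


def test_single_clone_recovery():
    recs = make_clone_variants([((1.0,), 200)], depth=100, seed=2)
    clusters = fit_dirichlet_process(recs, make_metas(["S0"]), FAST)
    occupied = [c for c in clusters if c.n_snvs / 200 >= 0.01]
    assert len(occupied) == 1
    assert occupied[0].ccf["S0"] == pytest.approx(1.0, abs=0.05)


def test_two_clone_recovery_two_samples():
    recs = make_clone_variants(
        [((1.0, 1.0), 150), ((0.3, 0.6), 150)],
        depth=100, samples=("S0", "S1"), seed=3)
    clusters = fit_dirichlet_process(
        recs, make_metas(["S0", "S1"]), FAST)
    big = sorted((c for c in clusters if c.n_snvs >= 30),
                 key=lambda c: c.ccf["S0"])
    assert len(big) == 2
    assert big[0].ccf["S0"] == pytest.approx(0.3, abs=0.05)
    assert big[0].ccf["S1"] == pytest.approx(0.6, abs=0.05)
    assert big[1].ccf["S0"] == pytest.approx(1.0, abs=0.05)


def test_no_snvs_gives_empty_result():
    assert fit_dirichlet_process([], make_metas(["S0"]), FAST) == []


def test_zero_depth_mutation_excluded():
    recs = make_clone_variants([((1.0,), 50)], depth=60, seed=4)
    recs[0].counts["S0"] = (0, 0)
    clusters = fit_dirichlet_process(recs, make_metas(["S0"]), FAST)
    assert sum(c.n_snvs for c in clusters) == 49


def test_assignment_exhaustive_and_exclusive():
    recs = make_clone_variants([((1.0,), 100), ((0.4,), 100)], depth=80, seed=5)
    clusters = fit_dirichlet_process(recs, make_metas(["S0"]), FAST)
    assigned = [m for c in clusters for m in c.members]
    assert len(assigned) == len(set(assigned)) == 200
    for c in clusters:
        assert all(0 <= p <= 1 for p in c.members.values())


def test_determinism_same_seed():
    recs = make_clone_variants([((0.8,), 120)], depth=70, seed=6)
    metas = make_metas(["S0"])
    a = fit_dirichlet_process(recs, metas, FAST)
    b = fit_dirichlet_process(recs, metas, FAST)
    assert [(c.cluster_id, c.n_snvs, c.ccf) for c in a] == \
           [(c.cluster_id, c.n_snvs, c.ccf) for c in b]


def test_single_sample_agrees_with_multi_sample_path():
    """The one-dimensional case is the n-dimensional sampler at S=1."""
    recs2 = make_clone_variants([((0.6, 0.6), 200)], depth=100,
                                samples=("S0", "S1"), seed=7)
    recs1 = []
    for r in recs2:
        r1 = type(r)(r.chrom, r.pos, r.ref, r.alt, r.vclass,
                     {"S0": r.counts["S0"]}, r.context)
        recs1.append(r1)
    c1 = fit_dirichlet_process(recs1, make_metas(["S0"]), FAST)
    c2 = fit_dirichlet_process(recs2, make_metas(["S0", "S1"]), FAST)
    top1 = max(c1, key=lambda c: c.n_snvs)
    top2 = max(c2, key=lambda c: c.n_snvs)
    assert top1.ccf["S0"] == pytest.approx(top2.ccf["S0"], abs=0.02)


# --- support filter -------------------------------------------------------

def _cluster(n, ccf=0.5, cid=1):
    return ClusterResult(cluster_id=cid, ccf={"S0": ccf}, n_snvs=n,
                         fraction_of_total=0.0,
                         members={f"m{cid}_{i}": 1.0 for i in range(n)})


def test_support_filter_boundary_inclusive():
    clusters = [_cluster(3, cid=1), _cluster(10, cid=2), _cluster(500, cid=3)]
    filter_support(clusters, total_snvs=1000)
    assert [c.retained for c in clusters] == [False, True, True]
    assert clusters[0].removal_reason == "support"


def test_support_filter_all_below_threshold():
    clusters = [_cluster(2, cid=1), _cluster(4, cid=2)]
    filter_support(clusters, total_snvs=1000)
    assert not any(c.retained for c in clusters)


# --- background test ------------------------------------------------------

def _background_setup(n_sites, alt_per_site, depth_per_site, seed=0):
    recs = []
    cluster = ClusterResult(cluster_id=1, ccf={"S0": 0.5}, n_snvs=n_sites,
                            fraction_of_total=1.0)
    for i in range(n_sites):
        rec_counts = {"S0": (depth_per_site, alt_per_site)}
        from fieldclone.io_formats import VariantRecord
        rec = VariantRecord("1", 10 + i, "C", "T", "SNV", rec_counts)
        recs.append(rec)
        cluster.members[rec.mutation_id] = 1.0
    return cluster, recs


def test_background_strongly_supported_cluster_retained():
    cluster, recs = _background_setup(100, 5, 50)  # 500 alt / 5000 reads
    pvals = background_binomial_test(cluster, recs, error_rate=0.001)
    assert pvals["S0"] < 1e-10
    assert cluster.retained


def test_background_weak_cluster_removed():
    cluster, recs = _background_setup(100, 0, 50)
    # put 5 alt reads total across the cluster
    for rec in recs[:5]:
        rec.counts["S0"] = (50, 1)
    pvals = background_binomial_test(cluster, recs, error_rate=0.001)
    expected = stats.binomtest(5, 5000, 0.001, alternative="greater").pvalue
    assert pvals["S0"] == pytest.approx(expected)
    assert pvals["S0"] > 0.5
    assert not cluster.retained
    assert cluster.removal_reason == "background"


def test_background_zero_alt_p_is_one():
    cluster, recs = _background_setup(50, 0, 40)
    pvals = background_binomial_test(cluster, recs, error_rate=0.001)
    assert pvals["S0"] == pytest.approx(1.0)
    assert not cluster.retained


def test_background_control_derived_rate():
    cluster, recs = _background_setup(50, 20, 40)
    control = {r.mutation_id: (40, 0) for r in recs}
    pvals = background_binomial_test(cluster, recs, control_counts=control)
    assert pvals["S0"] < 1e-10  # rate floored at 1e-4, cluster clearly above


def test_background_requires_control_or_rate():
    cluster, recs = _background_setup(10, 5, 40)
    with pytest.raises(ConfigurationError):
        background_binomial_test(cluster, recs)


# --- indel assignment -----------------------------------------------------

def _indel_table(rows):
    return pd.DataFrame(rows, columns=["mutation_id", "sample_id", "ccf"])


def test_indel_assigned_to_exact_centroid():
    clusters = [_cluster(100, ccf=0.4, cid=1), _cluster(100, ccf=0.9, cid=2)]
    table = _indel_table([("i1", "S0", 0.4)])
    counts = assign_indels(clusters, table)
    assert counts == {1: 1, 2: 0}
    assert clusters[0].n_indels == 1


def test_indel_tie_goes_to_larger_cluster():
    clusters = [_cluster(50, ccf=0.4, cid=1), _cluster(200, ccf=0.6, cid=2)]
    table = _indel_table([("i1", "S0", 0.5)])
    counts = assign_indels(clusters, table)
    assert counts == {1: 0, 2: 1}


def test_indel_outside_radius_unassigned():
    clusters = [_cluster(100, ccf=0.9, cid=1)]
    table = _indel_table([("i1", "S0", 0.3)])
    counts = assign_indels(clusters, table)
    assert counts == {1: 0}
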
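"""Synthetic-cohort generator: determinism, sum rule, neutral tail."""

import numpy as np
import pytest

from fieldclone.io_formats import ValidationError
from fieldclone.synthetic import (SimConfig, channel_to_mutation,
                                  count_sample_burdens, sample_neutral_vafs,
                                  simulate_cohort, synthetic_signature_catalog,
                                  write_cohort)


def small_config(seed=0, **kw):
    kw.setdefault("n_cancer_patients", 3)
    kw.setdefault("n_noncancer_patients", 2)
    return SimConfig(seed=seed, **kw)


def test_seed_determinism_byte_identical(tmp_path):
    for d in ("a", "b"):
        write_cohort(simulate_cohort(small_config(seed=9)), tmp_path / d)
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_adding_patient_preserves_existing():
    c1 = simulate_cohort(small_config(seed=3))
    c2 = simulate_cohort(small_config(seed=3, n_noncancer_patients=3))
    for pid in c1.variants:
        assert c1.variants[pid] == c2.variants[pid]


def test_no_expansions_leaves_root_and_tail():
    cfg = small_config(seed=1, expansion_probability={
        g: 0.0 for g in ("cancer_normal", "noncancer_normal", "bph",
                         "tumour", "fibroblast")})
    cohort = simulate_cohort(cfg)
    for pid, truth in cohort.truth.patients.items():
        # with expansion probability zero everywhere only the (zero-SNV)
        # clonal root survives; every sample is pure neutral tail
        assert set(truth.clone_ccfs) == {"clonal_root"}
        assert truth.clone_snvs["clonal_root"] == 0
        for s, muts in truth.tail_mutations.items():
            assert len(muts) > 0


def test_ground_truth_sum_rule():
    cohort = simulate_cohort(small_config(seed=7))
    for truth in cohort.truth.patients.values():
        samples = next(iter(truth.clone_ccfs.values())).keys()
        for s in samples:
            for parent in truth.clone_ccfs:
                kids = [c for c, p in truth.parent.items() if p == parent]
                total = sum(truth.clone_ccfs[c][s] for c in kids)
                assert total <= truth.clone_ccfs[parent][s] + 1e-9


def test_clone_vaf_matches_ccf_within_binomial_error():
    cohort = simulate_cohort(small_config(seed=13))
    pid = sorted(cohort.variants)[0]
    truth = cohort.truth.patients[pid]
    subs = {c: v for c, v in truth.clone_ccfs.items()
            if c != "clonal_root" and truth.clone_snvs.get(c, 0) >= 100}
    if not subs:
        pytest.skip("no large clone drawn for this patient")
    # tail mutations are private; everything else belongs to clones.  Check
    # the pooled VAF of the largest normal-sample clone against CCF/2.
    tails = {m for ms in truth.tail_mutations.values() for m in ms}
    for c, ccfs in subs.items():
        home = max(ccfs, key=ccfs.get)
        if "T" in home.split("_")[-1]:
            continue
        expected = ccfs[home] / 2
        vafs = []
        for rec in cohort.variants[pid]:
            if rec.mutation_id in tails or rec.vclass != "SNV":
                continue
            d, a = rec.counts[home]
            if d and abs(a / d - expected) < 0.12:
                vafs.append(a / d)
        if len(vafs) >= 50:
            assert np.mean(vafs) == pytest.approx(expected, abs=0.05)


def test_burden_medians_recover_configured_means():
    """Monte-Carlo check across seeds at the configured group means."""
    cfg0 = SimConfig()
    groups = {"cancer_normal": [], "noncancer_normal": [], "tumour": []}
    for seed in range(10):
        cohort = simulate_cohort(SimConfig(
            seed=seed, n_cancer_patients=6, n_noncancer_patients=3))
        snv, _ = count_sample_burdens(cohort)
        for m in cohort.sample_sheet:
            if m.group in groups:
                groups[m.group].append(snv.get(m.sample_id, 0))
    for g, values in groups.items():
        med = np.median(values)
        assert abs(med - cfg0.snv_burden_mean[g]) / cfg0.snv_burden_mean[g] < 0.2


def test_tumour_exceeds_normal_and_has_cna():
    cohort = simulate_cohort(small_config(seed=2))
    snv, _ = count_sample_burdens(cohort)
    tumours = [m.sample_id for m in cohort.sample_sheet if m.group == "tumour"]
    normals = [m.sample_id for m in cohort.sample_sheet
               if m.group == "cancer_normal"]
    assert min(snv[t] for t in tumours) > max(snv[n] for n in normals)
    seg_samples = {s.sample_id for s in cohort.segments}
    assert seg_samples and seg_samples.issubset(set(tumours))
    assert all(cohort.rearrangements[t] > 5 for t in tumours)
    assert all(cohort.rearrangements[n] <= 3 for n in normals)


def test_invalid_config_rejected():
    with pytest.raises(ValidationError):
        SimConfig(expansion_probability={"cancer_normal": 1.5}).validate()
    with pytest.raises(ValidationError):
        SimConfig(snv_burden_mean={"cancer_normal": -5}).validate()
    with pytest.raises(ValidationError):
        SimConfig(tail_fmin=0.3, tail_fmax=0.2).validate()


# --- neutral tail sampler -------------------------------------------------

def test_neutral_vafs_empty_and_bounds():
    assert len(sample_neutral_vafs(0, 0.1, 0.25, 0)) == 0
    v = sample_neutral_vafs(5000, 0.1, 0.25, 1)
    assert v.min() >= 0.1 and v.max() <= 0.25


def test_neutral_vafs_inverse_cdf_endpoints():
    # u = 0 -> fmax; u -> 1 -> fmin
    fmin, fmax = 0.1, 0.25
    assert 1 / (1 / fmax + 0.0 * (1 / fmin - 1 / fmax)) == pytest.approx(fmax)
    assert 1 / (1 / fmax + 1.0 * (1 / fmin - 1 / fmax)) == pytest.approx(fmin)


def test_neutral_vafs_domain_error():
    with pytest.raises(ValueError):
        sample_neutral_vafs(10, 0.25, 0.1, 0)


def test_neutral_cumulative_is_linear_in_inverse_f():
    """M(f) regressed on (1/f - 1/fmax) is linear with R^2 > 0.999."""
    v = np.sort(sample_neutral_vafs(100_000, 0.1, 0.25, 12))
    f = np.linspace(0.25, 0.1, 200)
    M = len(v) - np.searchsorted(v, f)
    x = 1 / f - 1 / 0.25
    slope = x @ M / (x @ x)
    r2 = 1 - np.sum((M - slope * x) ** 2) / np.sum((M - M.mean()) ** 2)
    assert r2 > 0.999


# --- helpers --------------------------------------------------------------

def test_channel_to_mutation_round_trip():
    ref, alt, ctx = channel_to_mutation("T[C>A]G")
    assert (ref, alt, ctx) == ("C", "A", "TCG")
    with pytest.raises(ValueError):
        channel_to_mutation("T[G>A]G")  # purine-centred labels are invalid


def test_synthetic_catalog_is_valid():
    cat = synthetic_signature_catalog(4, seed=5)
    assert len(cat) == 4
    np.testing.assert_allclose(cat.matrix.sum(axis=0), 1.0, atol=1e-9)
    assert (cat.matrix >= 0).all()
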
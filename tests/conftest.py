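import numpy as np
import pytest

from fieldclone.io_formats import SampleMeta, VariantRecord


def make_clone_variants(clone_specs, depth=100, samples=("S0",), seed=0,
                        start_pos=0):
    """Variant records simulating clones at given per-sample CCFs.

    ``clone_specs`` is a list of (ccf_tuple, n_snvs); expected VAF in a pure
    copy-neutral sample is CCF/2.
    """
    rng = np.random.default_rng(seed)
    records = []
    pos = start_pos
    for ccfs, n in clone_specs:
        for _ in range(n):
            pos += 10
            counts = {}
            for j, s in enumerate(samples):
                d = max(int(rng.poisson(depth)), 1)
                a = int(rng.binomial(d, ccfs[j] / 2))
                counts[s] = (d, a)
            records.append(VariantRecord("1", pos, "C", "T", "SNV", counts,
                                         context="ACA"))
    return records


def make_metas(samples, patient="P1", tissue="normal", cancer=True):
    return [SampleMeta(patient_id=patient, sample_id=s, tissue_class=tissue,
                       donor_has_cancer=cancer) for s in samples]


@pytest.fixture(scope="session")
def toy_cohort(tmp_path_factory):
    """A small simulated cohort written to disk, shared across tests."""
    from fieldclone.synthetic import SimConfig, simulate_cohort, write_cohort

    cfg = SimConfig(seed=11, n_cancer_patients=2, n_noncancer_patients=2)
    cohort = simulate_cohort(cfg)
    outdir = tmp_path_factory.mktemp("toy_cohort")
    write_cohort(cohort, outdir)
    return cohort, outdir
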
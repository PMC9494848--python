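"""Cohort-level burden tables, expansion calls and statistical comparisons.

Samples are summarised into a per-sample table (SNV/indel burdens,
rearrangement and copy-number counts, expansion flag, maximum retained-
clone CCF) joined to the sample metadata.  Group comparisons follow the
study conventions: where a patient contributes several samples to a group
its median value is used; rank tests are exact (enumeration) below 25 per
group and normal-approximated with tie correction above; Fisher tests are
exact two-sided by the "probability at most that of the observed table"
rule.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dp import ClusterResult
from .io_formats import SampleMeta

log = logging.getLogger(__name__)

EXACT_N = 25  # exact rank-test enumeration below this per-group size


def classify_expansion(clusters: Sequence[ClusterResult],
                       sample_id: str | None = None) -> bool:
    """True iff the sample carries a clonal expansion under selection:
    at least one cluster retained after all filters (removal_reason none).

    With ``sample_id`` given, the cluster must also be present there
    (CCF >= 0.05) rather than only in a sibling sample of the patient.
    """
    for c in clusters:
        if not (c.retained and c.removal_reason == "none"):
            continue
        if sample_id is None or c.ccf.get(sample_id, 0.0) >= 0.05:
            return True
    return False


def max_retained_ccf(clusters: Sequence[ClusterResult],
                     sample_id: str) -> float:
    """Largest CCF among retained clusters in one sample (NaN if none)."""
    vals = [c.ccf.get(sample_id, np.nan) for c in clusters
            if c.retained and c.removal_reason == "none"
            and c.ccf.get(sample_id, 0.0) >= 0.05]
    return float(max(vals)) if vals else float("nan")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def collapse_per_patient(df: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Median of each patient's samples within a group (study convention)."""
    return (df.groupby(["patient_id", "group"], as_index=False)[value]
              .median())


def group_compare(df: pd.DataFrame, paired: bool = False,
                  alternative: str = "two-sided") -> dict:
    """Rank test between two groups of per-sample values.

    ``df`` needs columns patient_id, group (two labels), value.  Samples of
    one patient in the same group are collapsed to their median first.
    Unpaired data get a Wilcoxon rank-sum (Mann-Whitney) test; ``paired``
    uses the signed-rank test on per-patient pairs, dropping patients
    missing either member with a warning.
    """
    d = collapse_per_patient(df)
    labels = sorted(d["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"group_compare needs exactly 2 groups, got {labels}")
    a = d.loc[d["group"] == labels[0], ["patient_id", "value"]]
    b = d.loc[d["group"] == labels[1], ["patient_id", "value"]]
    medians = {labels[0]: float(a["value"].median()),
               labels[1]: float(b["value"].median())}

    if paired:
        merged = a.merge(b, on="patient_id", suffixes=("_a", "_b"))
        dropped = (len(a) + len(b) - 2 * len(merged))
        if dropped:
            log.warning("paired comparison dropped %d unpaired samples", dropped)
        if len(merged) < 2:
            return {"groups": labels, "medians": medians, "n": len(merged),
                    "statistic": np.nan, "p_value": np.nan,
                    "test": "wilcoxon_signed_rank"}
        x = merged["value_a"].to_numpy(float)
        y = merged["value_b"].to_numpy(float)
        diffs = x - y
        nz = diffs[diffs != 0]
        exact = len(nz) < EXACT_N and len(np.unique(np.abs(nz))) == len(nz)
        res = stats.wilcoxon(x, y, alternative=alternative,
                             method="exact" if exact else "approx")
        return {"groups": labels, "medians": medians, "n": len(merged),
                "statistic": float(res.statistic), "p_value": float(res.pvalue),
                "test": "wilcoxon_signed_rank"}

    va = a["value"].to_numpy(float)
    vb = b["value"].to_numpy(float)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("need >= 2 values per group after collapsing")
    no_ties = len(np.unique(np.concatenate([va, vb]))) == len(va) + len(vb)
    exact = max(len(va), len(vb)) < EXACT_N and no_ties
    res = stats.mannwhitneyu(va, vb, alternative=alternative,
                             method="exact" if exact else "asymptotic")
    return {"groups": labels, "medians": medians,
            "n": (len(va), len(vb)),
            "statistic": float(res.statistic), "p_value": float(res.pvalue),
            "test": "wilcoxon_rank_sum"}


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman rank correlation with exact permutation p at small n.

    Uses the t-approximation above n = 10 and exact permutation enumeration
    otherwise.  A constant vector leaves rho undefined (NaN, NaN).
    """
    if method != "spearman":
        raise ValueError("only spearman correlation is supported")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired observations with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p_approx = stats.spearmanr(x, y)
    n = len(x)
    if n > 10:
        return float(rho), float(p_approx)
    # exact permutation distribution of |rho|
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(_pearson(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(_pearson(rx, ry[list(perm)]))
        count += r >= obs - 1e-12
        total += 1
    return float(rho), count / total


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = math.sqrt(float(u @ u) * float(v @ v))
    return float(u @ v) / denom if denom else 0.0


def burden_model(n_snvs, cancer_status, age) -> dict:
    """OLS of SNV burden on cancer status with age as covariate.

    Returns the status coefficient with its t statistic and p-value.
    Raises on a rank-deficient design (e.g. constant status or age
    perfectly collinear with status).
    """
    y = np.asarray(n_snvs, float)
    status = np.asarray(cancer_status, float)
    age = np.asarray(age, float)
    X = np.column_stack([np.ones_like(y), status, age])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    dof = len(y) - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations for the model")
    sigma2 = float(np.sum((y - fitted) ** 2)) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = math.sqrt(cov[1, 1])
    tstat = beta[1] / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(tstat), dof)
    return {"coefficient": float(beta[1]), "se": float(se),
            "t": float(tstat), "p_value": float(p),
            "intercept": float(beta[0]), "age_coefficient": float(beta[2])}


def ccf_vs_epithelial(table: pd.DataFrame) -> dict:
    """Paired comparison of expansion CCF (x100) against epithelial %.

    Uses samples with both a retained-clone CCF and an epithelial estimate.
    Reports the count of pairs where the CCF does NOT exceed the epithelial
    fraction, and a one-sided paired signed-rank p (CCF greater).  A single
    pair yields a missing p but still reports the difference.
    """
    d = table.dropna(subset=["max_ccf", "epithelial_pct"])
    ccf_pct = d["max_ccf"].to_numpy(float) * 100
    epi = d["epithelial_pct"].to_numpy(float)
    n = len(d)
    violations = int(np.sum(ccf_pct <= epi))
    out = {"n_pairs": n, "violations": violations,
           "median_difference": float(np.median(ccf_pct - epi)) if n else np.nan,
           "p_value": np.nan}
    if n >= 2 and np.any(ccf_pct != epi):
        diffs = ccf_pct - epi
        nz = diffs[diffs != 0]
        exact = len(nz) < EXACT_N and len(np.unique(np.abs(nz))) == len(nz)
        res = stats.wilcoxon(ccf_pct, epi, alternative="greater",
                             method="exact" if exact else "approx")
        out["p_value"] = float(res.pvalue)
    return out


def build_cohort_table(metas: Sequence[SampleMeta],
                       snv_counts: Mapping[str, int],
                       indel_counts: Mapping[str, int],
                       clusters_by_patient: Mapping[str, Sequence[ClusterResult]],
                       rearrangement_counts: Mapping[str, int] | None = None,
                       cna_counts: Mapping[str, int] | None = None
                       ) -> pd.DataFrame:
    """Assemble the per-sample cohort table used by every comparison."""
    rows = []
    for m in metas:
        if m.tissue_class == "control":
            continue
        clusters = clusters_by_patient.get(m.patient_id, [])
        rows.append({
            "patient_id": m.patient_id, "sample_id": m.sample_id,
            "tissue_class": m.tissue_class, "group": m.group,
            "donor_has_cancer": m.donor_has_cancer,
            "n_snvs": int(snv_counts.get(m.sample_id, 0)),
            "n_indels": int(indel_counts.get(m.sample_id, 0)),
            "n_rearrangements": int((rearrangement_counts or {}).get(m.sample_id, 0)),
            "n_cna_segments": int((cna_counts or {}).get(m.sample_id, 0)),
            "has_expansion": classify_expansion(clusters, m.sample_id),
            "max_ccf": max_retained_ccf(clusters, m.sample_id),
            "purity": m.purity, "epithelial_pct": m.epithelial_pct,
            "stromal_pct": m.stromal_pct,
            "distance_to_tumour_mm": m.distance_to_tumour_mm,
            "age": m.age, "multifocal": m.multifocal,
        })
    return pd.DataFrame(rows)


def expansion_contingency(table: pd.DataFrame,
                          groups: tuple[str, str] = ("cancer_normal",
                                                     "noncancer_normal")
                          ) -> tuple[list[list[int]], float]:
    """2x2 expansion-vs-group counts and their Fisher exact p."""
    t = []
    for g in groups:
        sub = table[table["group"] == g]
        pos = int(sub["has_expansion"].sum())
        t.append([pos, len(sub) - pos])
    return t, fisher_exact_2x2(t)
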
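"""Multi-sample Dirichlet-process clustering of somatic SNVs.

SNVs of one patient are clustered across its n samples with a truncated
stick-breaking Dirichlet-process binomial mixture.  Each cluster k carries a
per-sample clonal cell fraction (CCF) vector; the expected allele fraction
of a mutation in cluster k in sample s is

    xi_s = ccf_ks * rho_s * m / (rho_s * cn_t + (1 - rho_s) * 2)

and observed alt counts are Binomial(depth, xi).  Cluster CCFs live on a
discrete grid (step 0.01 on [0, 1.2]) so position updates are exact
categorical draws; cluster weights follow the usual Beta(1, alpha) sticks
with a Gamma prior on the concentration alpha.

After sampling, each mutation is assigned to its modal cluster over the
post-burn-in draws and cluster centroids are posterior medians — a summary
that is robust to label switching.  Retention filters follow the study
design: clusters need >= 1% of the patient's SNVs, allele counts
significantly above the control (blood) background rate, and survival of
the per-sample neutrality filter applied downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ccf import estimate_multiplicity
from .io_formats import SampleMeta, VariantRecord

log = logging.getLogger(__name__)

#: clusters below this CCF in every sample are noise at ~50X depth
NOISE_CCF = 0.05
#: floor for the control-derived background error rate
BACKGROUND_FLOOR = 1e-4


class ConfigurationError(RuntimeError):
    pass


@dataclass
class GibbsSettings:
    """Sampler settings for the truncated stick-breaking DP."""

    truncation: int = 30        # K, far above any plausible clone count
    iterations: int = 2000
    burn_in: int = 1000
    alpha_shape: float = 1.0    # Gamma prior on the DP concentration
    alpha_rate: float = 1.0
    seed: int = 0
    grid_max: float = 1.2
    grid_step: float = 0.01

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.truncation < 2:
            raise ValueError("truncation must be >= 2")


@dataclass
class ClusterResult:
    """One mutation cluster with per-sample CCF centroid and filter state."""

    cluster_id: int
    ccf: dict[str, float]                     # sample_id -> centroid CCF
    n_snvs: int
    fraction_of_total: float
    members: dict[str, float] = field(default_factory=dict)  # mut_id -> posterior prob
    n_indels: int = 0
    background_p: dict[str, float] = field(default_factory=dict)
    retained: bool = True
    removal_reason: str = "none"   # none | support | background | neutrality

    def ccf_vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.ccf[s] for s in sample_ids], float)


def _vaf_conversion(variants: Sequence[VariantRecord],
                    metas: Sequence[SampleMeta],
                    cn_map: Mapping[tuple[str, str], int] | None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Alt counts, depths and the CCF->VAF conversion factor per mutation/sample."""
    samples = [m.sample_id for m in metas if m.tissue_class != "control"]
    purity = {m.sample_id: m.purity for m in metas}
    N, S = len(variants), len(samples)
    a = np.zeros((N, S))
    d = np.zeros((N, S))
    conv = np.full((N, S), 0.5)
    for i, rec in enumerate(variants):
        for j, sid in enumerate(samples):
            if sid not in rec.counts:
                continue
            depth, alt = rec.counts[sid]
            a[i, j], d[i, j] = alt, depth
            rho = purity[sid]
            cn_t = cn_map.get((rec.mutation_id, sid), 2) if cn_map else 2
            denom = rho * cn_t + (1 - rho) * 2
            if depth > 0:
                m = estimate_multiplicity(alt / depth, rho, cn_t)
            else:
                m = 1
            conv[i, j] = rho * m / denom
    return a, d, conv, samples


def fit_dirichlet_process(variants: Sequence[VariantRecord],
                          sample_metas: Sequence[SampleMeta],
                          settings: GibbsSettings | None = None,
                          cn_map: Mapping[tuple[str, str], int] | None = None,
                          ) -> list[ClusterResult]:
    """Cluster one patient's SNVs across samples; returns occupied clusters.

    Mutations with zero depth in every sample are excluded with a warning.
    The single-sample case is the same model in one dimension.  Identical
    settings (including seed) give identical results.
    """
    settings = settings or GibbsSettings()
    snvs = [v for v in variants if v.vclass == "SNV"]
    usable, dropped = [], 0
    for v in snvs:
        if any(depth > 0 for depth, _ in v.counts.values()):
            usable.append(v)
        else:
            dropped += 1
    if dropped:
        log.warning("excluded %d mutations with zero depth in all samples", dropped)
    if not usable:
        return []

    a, d, conv, samples = _vaf_conversion(usable, sample_metas, cn_map)
    N, S = a.shape
    K = settings.truncation
    grid = np.arange(0.0, settings.grid_max + settings.grid_step / 2,
                     settings.grid_step)
    G = len(grid)
    rng = np.random.default_rng(settings.seed)

    # per-sample (N, G) log-likelihood of each mutation at each grid CCF
    Lg = []
    for j in range(S):
        xi = np.clip(grid[None, :] * conv[:, j, None], 1e-6, 1 - 1e-6)
        lg = a[:, j, None] * np.log(xi) + (d[:, j] - a[:, j])[:, None] * np.log1p(-xi)
        lg[d[:, j] == 0, :] = 0.0  # unobserved: no likelihood contribution
        Lg.append(lg)

    # init positions at the observed CCFs of K random mutations
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_ccf = np.where(d > 0, a / np.maximum(d, 1) / conv, 0.0)
    obs_idx = np.clip(np.round(obs_ccf / settings.grid_step), 0, G - 1).astype(int)
    pick = rng.integers(0, N, size=K)
    Pidx = obs_idx[pick, :].copy()

    alpha = 1.0
    log_w = np.full(K, -np.log(K))
    kept = settings.iterations - settings.burn_in
    assign_counts = np.zeros((N, K), dtype=np.int32)
    pos_history = np.empty((kept, K, S), dtype=np.float32)
    occ_history = np.zeros((kept, K), dtype=bool)

    for it in range(settings.iterations):
        # --- assignments (Gumbel-max categorical) ---
        L = np.zeros((N, K))
        for j in range(S):
            L += Lg[j][:, Pidx[:, j]]
        z = np.argmax(L + log_w[None, :] + rng.gumbel(size=(N, K)), axis=1)

        # --- sticks and concentration ---
        n_k = np.bincount(z, minlength=K)
        tail = n_k[::-1].cumsum()[::-1] - n_k
        V = rng.beta(1 + n_k, alpha + tail)
        V = np.clip(V, 1e-12, 1 - 1e-12)
        V[K - 1] = 1.0 - 1e-12
        log1mV = np.log1p(-V)
        log_w = np.log(V) + np.concatenate(([0.0], np.cumsum(log1mV[:-1])))
        alpha = rng.gamma(settings.alpha_shape + K - 1,
                          1.0 / (settings.alpha_rate - log1mV[:-1].sum()))

        # --- cluster positions: exact categorical draw on the grid ---
        for j in range(S):
            score = np.zeros((K, G))
            np.add.at(score, z, Lg[j])
            Pidx[:, j] = np.argmax(score + rng.gumbel(size=(K, G)), axis=1)

        if it >= settings.burn_in:
            t = it - settings.burn_in
            assign_counts[np.arange(N), z] += 1
            pos_history[t] = grid[Pidx]
            occ_history[t, np.unique(z)] = True

    modal = np.argmax(assign_counts, axis=1)
    probs = assign_counts[np.arange(N), modal] / kept
    total = len(usable)

    centroids: dict[int, np.ndarray] = {}
    for k in np.unique(modal):
        occ = occ_history[:, k]
        if occ.any():
            centroids[k] = np.median(pos_history[occ, k, :], axis=0)
        else:  # pragma: no cover - a modal cluster is occupied by construction
            centroids[k] = pos_history[:, k, :].mean(axis=0)
    modal, centroids = _bic_merge(modal, centroids, Lg, grid,
                                  settings.grid_step)

    clusters: list[ClusterResult] = []
    for new_id, k in enumerate(sorted(centroids), start=1):
        centroid = centroids[k]
        member_idx = np.flatnonzero(modal == k)
        cluster = ClusterResult(
            cluster_id=new_id,
            ccf={s: float(centroid[j]) for j, s in enumerate(samples)},
            n_snvs=len(member_idx),
            fraction_of_total=len(member_idx) / total,
            members={usable[i].mutation_id: float(probs[i]) for i in member_idx},
        )
        if max(cluster.ccf.values()) < NOISE_CCF:
            cluster.retained = False
            cluster.removal_reason = "support"
        clusters.append(cluster)
    return clusters


#: clusters farther apart than this (max per-sample CCF difference) are
#: never merge candidates: unambiguously distinct at ~50X
MERGE_CANDIDATE_DIST = 0.25


def _mixture_gain(L_members: list[np.ndarray], gi: np.ndarray,
                  gj: np.ndarray, iters: int = 25) -> float:
    """2*(LL_2-component - LL_1-component) for pooled members of two clusters.

    ``L_members`` holds one (N, G) grid log-likelihood per sample for the
    pooled members; ``gi``/``gj`` are per-sample grid indices initialising
    the two components.  EM over (positions, weight) with exact per-sample
    grid M-steps.
    """
    S = len(L_members)
    N = L_members[0].shape[0]
    w = 0.5
    gi, gj = gi.copy(), gj.copy()
    for _ in range(iters):
        li = sum(L_members[s][:, gi[s]] for s in range(S)) + np.log(w)
        lj = sum(L_members[s][:, gj[s]] for s in range(S)) + np.log(1 - w)
        m = np.maximum(li, lj)
        ri = np.exp(li - m) / (np.exp(li - m) + np.exp(lj - m))
        w = float(np.clip(ri.mean(), 0.01, 0.99))
        for s in range(S):
            gi[s] = int(np.argmax(ri @ L_members[s]))
            gj[s] = int(np.argmax((1 - ri) @ L_members[s]))
    li = sum(L_members[s][:, gi[s]] for s in range(S)) + np.log(w)
    lj = sum(L_members[s][:, gj[s]] for s in range(S)) + np.log(1 - w)
    m = np.maximum(li, lj)
    ll2 = float(np.sum(m + np.log(np.exp(li - m) + np.exp(lj - m))))
    ll1 = float(sum(L_members[s].sum(axis=0).max() for s in range(S)))
    return 2 * (ll2 - ll1)


def _bic_merge(modal: np.ndarray, centroids: dict[int, np.ndarray],
               Lg: list[np.ndarray], grid: np.ndarray, grid_step: float
               ) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Merge modal clusters that a single binomial component explains.

    Single-site Gibbs moves can leave one clone split into two persistent
    clusters.  For nearby cluster pairs a two-component binomial mixture is
    refitted on the pooled members; when its log-likelihood gain over one
    component fails the BIC penalty (S + 1 parameters x ln n), the pair is
    merged and the merged centroid set to the pooled maximum-likelihood
    position.
    """
    S = len(Lg)
    changed = True
    while changed and len(centroids) > 1:
        changed = False
        labels = sorted(centroids)
        pairs = []
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                dist = float(np.max(np.abs(centroids[a] - centroids[b])))
                if dist <= MERGE_CANDIDATE_DIST:
                    pairs.append((dist, a, b))
        for _, a, b in sorted(pairs):
            idx = np.flatnonzero((modal == a) | (modal == b))
            if len(idx) == 0:
                continue
            Lm = [Lg[s][idx] for s in range(S)]
            gi = np.clip(np.round(centroids[a] / grid_step), 0,
                         len(grid) - 1).astype(int)
            gj = np.clip(np.round(centroids[b] / grid_step), 0,
                         len(grid) - 1).astype(int)
            gain = _mixture_gain(Lm, gi, gj)
            penalty = (S + 1) * np.log(len(idx))
            if gain < penalty:
                modal[modal == b] = a
                centroids[a] = np.array([
                    grid[int(np.argmax(Lm[s].sum(axis=0)))] for s in range(S)])
                del centroids[b]
                changed = True
                break
    return modal, centroids


# ---------------------------------------------------------------------------
# retention filters
# ---------------------------------------------------------------------------

def filter_support(clusters: Sequence[ClusterResult], total_snvs: int,
                   min_fraction: float = 0.01) -> list[ClusterResult]:
    """Remove clusters supported by fewer than ``min_fraction`` of the
    patient's SNVs (boundary inclusive: exactly 1% is retained)."""
    if total_snvs <= 0:
        raise ValueError("total_snvs must be positive")
    for c in clusters:
        if c.retained and c.n_snvs / total_snvs < min_fraction:
            c.retained = False
            c.removal_reason = "support"
    return list(clusters)


def test_background(cluster: ClusterResult,
                    variants: Sequence[VariantRecord],
                    control_counts: Mapping[str, tuple[int, int]] | None = None,
                    error_rate: float | None = None,
                    alpha: float = 0.05,
                    sample_ids: Sequence[str] | None = None) -> dict[str, float]:
    """One-sided binomial test of a cluster's allele counts against the
    background rate.

    The background rate is the pooled alt/depth of the control (blood)
    sample at the cluster's sites, floored at 1e-4; a configured
    ``error_rate`` is used when no control is available.  The cluster is
    retained only if some sample rejects the background at ``alpha``.
    """
    by_id = {v.mutation_id: v for v in variants}
    members = [by_id[m] for m in cluster.members if m in by_id]
    if control_counts is not None:
        cd = sum(control_counts[m.mutation_id][0] for m in members
                 if m.mutation_id in control_counts)
        ca = sum(control_counts[m.mutation_id][1] for m in members
                 if m.mutation_id in control_counts)
        e = max(ca / cd if cd > 0 else 0.0, BACKGROUND_FLOOR)
    elif error_rate is not None:
        e = max(error_rate, BACKGROUND_FLOOR)
    else:
        raise ConfigurationError(
            "background test needs control read counts or a configured error rate"
        )
    if sample_ids is None:
        sample_ids = list(cluster.ccf)
    pvals: dict[str, float] = {}
    for sid in sample_ids:
        depth = sum(v.counts[sid][0] for v in members if sid in v.counts)
        alt = sum(v.counts[sid][1] for v in members if sid in v.counts)
        if depth == 0:
            pvals[sid] = 1.0
        else:
            pvals[sid] = float(stats.binomtest(alt, depth, e,
                                               alternative="greater").pvalue)
    cluster.background_p = pvals
    if cluster.retained and not any(p < alpha for p in pvals.values()):
        cluster.retained = False
        cluster.removal_reason = "background"
    return pvals


def filter_background(clusters: Sequence[ClusterResult],
                      variants: Sequence[VariantRecord],
                      control_counts: Mapping[str, tuple[int, int]] | None = None,
                      error_rate: float | None = None,
                      alpha: float = 0.05) -> list[ClusterResult]:
    for c in clusters:
        test_background(c, variants, control_counts, error_rate, alpha)
    return list(clusters)


def assign_indels(clusters: Sequence[ClusterResult],
                  indel_ccfs: pd.DataFrame,
                  radius: float = 0.15) -> dict[int, int]:
    """Attach indels to the nearest retained cluster centroid.

    ``indel_ccfs`` is a long table (mutation_id, sample_id, ccf) as produced
    by :func:`fieldclone.ccf.compute_ccf_table`.  An indel joins the cluster
    whose per-sample CCF vector is nearest in Euclidean distance, if within
    ``radius``; ties go to the larger cluster.  Returns per-cluster counts
    and updates ``n_indels`` in place.
    """
    retained = [c for c in clusters if c.retained]
    counts = {c.cluster_id: 0 for c in clusters}
    if not retained or indel_ccfs.empty:
        return counts
    wide = indel_ccfs.pivot_table(index="mutation_id", columns="sample_id",
                                  values="ccf")
    samples = [s for s in retained[0].ccf if s in wide.columns]
    cent = np.array([[c.ccf[s] for s in samples] for c in retained])
    for _, row in wide.iterrows():
        vec = row.reindex(samples).to_numpy(float)
        ok = ~np.isnan(vec)
        if not ok.any():
            continue
        dist = np.sqrt(((cent[:, ok] - vec[ok]) ** 2).sum(axis=1))
        best = np.min(dist)
        if best > radius:
            continue
        tied = np.flatnonzero(np.isclose(dist, best))
        winner = max(tied, key=lambda i: retained[i].n_snvs)
        counts[retained[winner].cluster_id] += 1
    for c in clusters:
        c.n_indels = counts[c.cluster_id]
    return counts
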
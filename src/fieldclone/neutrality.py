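"""Test of neutral 1/f mutation accumulation in the subclonal VAF range.

Under neutral growth the cumulative number of subclonal mutations with
allele frequency at least f grows linearly in (1/f - 1/fmax):

    M(f) = (mu/beta) * (1/f - 1/fmax)

Deviation from this power law indicates clones under positive selection.
A sample's subclonal spectrum (fmin < VAF < fmax, defaults 0.1 and 0.25)
is fitted through the origin and compared to the theoretical cumulative
with three distances: area between the normalised cumulatives, Kolmogorov
(max pointwise) distance, and Euclidean (RMS) distance.  P-values come from
an empirical null regenerated by simulation at the observed depth and
mutation count; a sample is called neutral only when all three distances
are compatible with the null (every p > 0.05), which makes cluster removal
deliberately conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

FMIN_DEFAULT = 0.1
FMAX_DEFAULT = 0.25
MIN_MUTATIONS = 12
#: the 1/f model describes mutations with VAF < fmax, i.e. clones below
#: CCF = 2*fmax in a copy-neutral pure sample; clusters above this ceiling
#: were never assessed by the test and are exempt from removal
NEUTRAL_CCF_CEILING = 2 * FMAX_DEFAULT
P_THRESHOLD = 0.05

METRIC_NAMES = ("area", "kolmogorov", "euclidean")


@dataclass
class NeutralityReport:
    sample_id: str
    n_subclonal_mutations: int
    mu_over_beta: float = float("nan")
    r_squared: float = float("nan")
    area: float = float("nan")
    kolmogorov: float = float("nan")
    euclidean: float = float("nan")
    p_area: float = float("nan")
    p_ks: float = float("nan")
    p_euclid: float = float("nan")
    verdict: str = "not_evaluable"  # neutral | selected | not_evaluable


def neutrality_metrics(vafs, fmin: float = FMIN_DEFAULT,
                       fmax: float = FMAX_DEFAULT,
                       grid_points: int = 100) -> dict[str, float]:
    """Fit the 1/f model and compute the three goodness-of-fit distances.

    Only VAFs strictly inside (fmin, fmax) contribute.  Returns the fitted
    slope mu/beta, its R^2, the three distances and the number of
    contributing mutations.
    """
    if fmin >= fmax:
        raise ValueError("fmin must be < fmax")
    v = np.asarray(vafs, float)
    v = np.sort(v[(v > fmin) & (v < fmax)])
    n = len(v)
    out = {"n": n, "mu_over_beta": np.nan, "r_squared": np.nan,
           "area": np.nan, "kolmogorov": np.nan, "euclidean": np.nan}
    if n == 0:
        return out
    f = np.linspace(fmax, fmin, grid_points)  # descending
    # M(f) = #{v >= f}
    M = n - np.searchsorted(v, f, side="left")
    x = 1.0 / f - 1.0 / fmax
    slope = float(np.dot(x, M) / np.dot(x, x))
    resid = M - slope * x
    ss_tot = float(np.sum((M - M.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0

    emp = M / n
    theo = x / (1.0 / fmin - 1.0 / fmax)
    diff = emp - theo
    # integrate |diff| over f (grid is descending, so flip)
    area = float(np.trapezoid(np.abs(diff)[::-1], f[::-1]))
    out.update(
        mu_over_beta=slope, r_squared=r2, area=area,
        kolmogorov=float(np.max(np.abs(diff))),
        euclidean=float(np.sqrt(np.mean(diff ** 2))),
    )
    return out


class NullDistribution:
    """Empirical null of the three neutrality distances.

    Regenerated by simulating neutral samples (1/f^2 VAF draws plus binomial
    read resampling at the observed depth) rather than shipped as a
    precomputed table.  Empirical p-values use the plain k/n_sims estimator
    floored at 1/n_sims.
    """

    def __init__(self, metrics: dict[str, np.ndarray], depth: float,
                 n_mutations: int, fmin: float, fmax: float, seed: int) -> None:
        self.metrics = metrics
        self.depth = depth
        self.n_mutations = n_mutations
        self.fmin, self.fmax = fmin, fmax
        self.seed = seed
        self.n_sims = len(next(iter(metrics.values())))

    def p_value(self, name: str, observed: float) -> float:
        null = self.metrics[name]
        k = int(np.sum(null >= observed))
        return max(k, 1) / self.n_sims


def calibrate_null(depth: float, n_mutations: int, n_sims: int = 1000,
                   fmin: float = FMIN_DEFAULT, fmax: float = FMAX_DEFAULT,
                   seed: int = 0) -> NullDistribution:
    """Simulate the null distribution of the three distances.

    Each replicate draws ``n_mutations`` true frequencies from the neutral
    1/f^2 density on [fmin, fmax], resamples read counts binomially at
    ``depth``, and recomputes the distances on the surviving subclonal-range
    mutations.
    """
    from .synthetic import sample_neutral_vafs

    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for usable p-values")
    rng = np.random.default_rng(seed)
    store: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for _ in range(n_sims):
        true_v = sample_neutral_vafs(n_mutations, fmin, fmax, rng)
        depths = rng.poisson(depth, size=n_mutations)
        depths = np.maximum(depths, 1)
        obs = rng.binomial(depths, true_v) / depths
        m = neutrality_metrics(obs, fmin, fmax)
        for name in METRIC_NAMES:
            store[name].append(m[name] if np.isfinite(m[name]) else 0.0)
    return NullDistribution({k: np.array(v) for k, v in store.items()},
                            depth, n_mutations, fmin, fmax, seed)


def fit_neutral_model(vafs, null: NullDistribution | None = None,
                      fmin: float = FMIN_DEFAULT, fmax: float = FMAX_DEFAULT,
                      min_mutations: int = MIN_MUTATIONS,
                      sample_id: str = "",
                      p_threshold: float = P_THRESHOLD) -> NeutralityReport:
    """Full neutrality assessment of one sample's VAF spectrum.

    Fewer than ``min_mutations`` in the subclonal window yields
    ``not_evaluable`` (cumulative fits on a handful of points carry no
    signal).  Otherwise the verdict is ``neutral`` iff every distance has an
    empirical p above ``p_threshold``.
    """
    m = neutrality_metrics(vafs, fmin, fmax)
    report = NeutralityReport(
        sample_id=sample_id, n_subclonal_mutations=m["n"],
        mu_over_beta=m["mu_over_beta"], r_squared=m["r_squared"],
        area=m["area"], kolmogorov=m["kolmogorov"], euclidean=m["euclidean"],
    )
    if m["n"] < min_mutations:
        report.verdict = "not_evaluable"
        return report
    if null is None:
        raise ValueError("an evaluable sample needs a calibrated null "
                         "(see calibrate_null)")
    report.p_area = null.p_value("area", m["area"])
    report.p_ks = null.p_value("kolmogorov", m["kolmogorov"])
    report.p_euclid = null.p_value("euclidean", m["euclidean"])
    ps = (report.p_area, report.p_ks, report.p_euclid)
    report.verdict = "neutral" if all(p > p_threshold for p in ps) else "selected"
    return report


def apply_neutrality_filter(clusters, reports: dict[str, NeutralityReport],
                            clonal_threshold: float = NEUTRAL_CCF_CEILING,
                            presence_ccf: float = 0.05):
    """Remove subclonal clusters that are explainable by neutral drift.

    A retained cluster is removed (reason ``neutrality``) when every sample
    in which it is present (CCF >= ``presence_ccf``) has a neutral verdict
    and the cluster sits inside the tested frequency range
    (CCF < ``clonal_threshold``, default 2*fmax) there.  Clusters above the
    ceiling lie outside the 1/f window and a neutral verdict carries no
    information about them.  Samples with verdict ``not_evaluable`` never
    trigger removal and are logged as untested.
    """
    for sid, rep in reports.items():
        if rep.verdict == "not_evaluable":
            log.info("sample %s: neutrality not evaluable (n=%d)",
                     sid, rep.n_subclonal_mutations)
    for c in clusters:
        if not c.retained:
            continue
        present = [s for s, v in c.ccf.items() if v >= presence_ccf]
        if not present:
            continue
        removable = all(
            s in reports
            and reports[s].verdict == "neutral"
            and c.ccf[s] < clonal_threshold
            for s in present
        )
        if removable:
            c.retained = False
            c.removal_reason = "neutrality"
    return list(clusters)
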
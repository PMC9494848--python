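# Methods

This note documents the models behind each stage, the defaults that
matter, and the choices made where the design was genuinely open.

## Clonal cell fractions

For a mutation with variant allele fraction `v` in a sample of purity `ρ`,
local total copy number `cn_t` (normal compartment `cn_n = 2`) and
multiplicity `m`,

    CCF = v · (ρ·cn_t + (1−ρ)·cn_n) / (ρ·m).

Normal, BPH and fibroblast samples are treated as pure (`ρ = 1`) and
copy-number neutral (`cn_t = 2`), where `CCF = 2v` for heterozygous
mutations. Multiplicity is the rounded implied mutant copy number
`round(v·(ρ·cn_t + (1−ρ)·2)/ρ)` clipped to `[1, cn_t]` — the standard
convention when subclonal copy-number genotyping is unavailable. CCFs are
capped at 1.2 (binomial noise pushes clonal mutations above 1) and clipped
to 1 for reporting. A sample with zero depth at a site gets a *missing*
CCF, not zero: absence of reads is not evidence of absence of the clone.
Copy-number segments (1-based, inclusive ends) apply to tumour samples
only; normal-class samples always use `cn_t = 2`, reflecting the absence
of copy-number alterations in this tissue.

## Dirichlet-process clustering

SNVs of one patient are clustered jointly across its samples with a
truncated stick-breaking Dirichlet-process mixture: weights from
Beta(1, α) sticks at truncation K = 30 (far above any plausible clone
count), a Gamma(1, 1) prior on α, and binomial emissions
`alt ~ Bin(depth, CCF·ρ·m/(ρ·cn_t + (1−ρ)·2))` per sample. Cluster
positions live on a per-sample CCF grid of step 0.01 on [0, 1.2], so
position updates are exact categorical draws; assignments use Gumbel-max
categorical sampling. Defaults: 2,000 iterations, 1,000 burn-in; all
randomness flows from a single integer seed, and identical seeds give
identical results. Mutations missing depth in some samples contribute
likelihood only where observed; mutations with no reads anywhere are
excluded with a warning.

After sampling, each mutation goes to its modal cluster over the kept
draws and centroids are posterior medians of the cluster's position chain
— a summary robust to label switching. Single-site Gibbs moves can leave
one clone persistently split into two clusters, so occupied clusters whose
centroids lie within 0.25 of each other are tested with a two-component
binomial-mixture refit (EM on the pooled members): if the two-component
log-likelihood gain fails a BIC penalty of `(S+1)·ln n` (S samples, one
weight), the pair is merged and the merged centroid set to the pooled
maximum-likelihood position. The penalty is parameter counting, not a
tuned constant; measured gains are ≈0–4 for a split clone and ≳30 for
clones separated by 0.15 CCF in two samples at 50X.

Retention filters, in order: clusters below CCF 0.05 in every sample are
noise at ~50X and never retained; clusters with < 1% of the patient's SNVs
are removed (boundary inclusive — exactly 1% is kept); clusters whose
pooled allele counts are not significantly above the background rate are
removed (one-sided binomial test at α = 0.05 per sample, background
estimated as pooled alt/depth in the matched blood at the cluster's sites,
floored at 1e-4, or a configured error rate when no control exists).
Indels do not enter the clustering; each is attached afterwards to the
nearest retained centroid (Euclidean over shared samples) within radius
0.15, ties to the larger cluster.

## Neutrality test

Under neutral growth the cumulative count of subclonal mutations with
frequency at least `f` satisfies `M(f) = (μ/β)(1/f − 1/fmax)`. Each
sample's VAFs inside (fmin, fmax) = (0.1, 0.25) are fitted through the
origin on a 100-point descending grid, giving μ/β and R², and compared to
the theoretical cumulative with three distances between the normalised
curves: integrated absolute difference (area), maximum pointwise
difference (Kolmogorov) and RMS difference (Euclidean). P-values are
empirical, from ≥ 1,000 simulated neutral samples at the observed depth
and mutation count (1/f² draws plus binomial read resampling), using the
k/n estimator floored at 1/n. Nulls are cached by (depth band, mutation
band, fmin, fmax). Fewer than 12 in-window mutations yields
`not_evaluable` — cumulative fits on a handful of points carry no signal.

A sample is `neutral` only when **all three** p-values exceed 0.05; this
makes cluster removal conservative (a cluster is only discarded when no
metric rejects). In neutral-verdict samples, retained clusters are removed
when their CCF is below 2·fmax = 0.5 in every sample where they are
present. The ceiling is deliberate: the test only assesses frequencies
below fmax, i.e. clones below CCF 0.5 in a pure diploid sample, so a
neutral verdict carries no information about larger clusters — removing
them would delete exactly the large expansions the analysis is meant to
find. A conventional "clonal" threshold (e.g. 0.9) is available as a
parameter but is not the default.

Measured operating characteristics (seeded simulations): fresh neutral
samples at 55X are called neutral ~94% of the time (the three distances
are strongly correlated, so the joint rate stays near the nominal 95%);
a half-neutral/half-subclone sample (peak at VAF 0.18, depth 100, n=500)
is called selected in ~100% of replicates. At ~55X a clone near VAF 0.15
mixed with a dense tail is genuinely hard to distinguish from drift — the
binomial smear closely mimics the 1/f cumulative — which is a property of
the method at that depth, not of this implementation.

## Clone trees

Two constraints order retained clusters into a rooted tree: the sum
(pigeonhole) rule — a parent's CCF covers the sum of its children's CCFs
in every sample — and the crossing rule — clusters whose CCF ordering
reverses between samples must be siblings. `build_tree` attaches clusters
in decreasing total CCF to the deepest compatible parent (maximally nested
parsimony convention) with backtracking, so it finds a consistent tree
whenever one exists at the tolerance; `enumerate_consistent_trees` is the
exhaustive oracle (≤ 7 clusters). The tolerance defaults to two binomial
standard errors of the least-supported cluster's CCF, floored at 0.02
(twice the grid step); on failure it escalates once to twice its value
with a warning before raising. The root is the germline (all cells); its
per-sample CCF absorbs cap overshoot above 1. Branch lengths in the
emitted Newick are raw assigned SNV counts (no weighting — any weighting
scheme would be arbitrary here). Ambiguity is real: clusters with equal
CCFs admit multiple consistent trees; the oracle's multiplicity is the
only ambiguity report, and recovery is only claimed where the constraints
identify the topology uniquely.

## Mutational signatures

SNVs map to the 96 pyrimidine-centred trinucleotide channels (purine
references strand-flipped). Exposures are refitted by forward selection:
starting from the best single-cosine signature, the signature whose
inclusion (non-negative least-squares refit of the selected set) most
increases the cosine similarity is added while the gain exceeds 0.01;
afterwards any exposure ≤ 0.06 is dropped with refit. Reported fractions
are normalised to sum to 1; samples with < 100 SNVs are excluded. This is
a documented stand-in for published single-sample refitting tools,
validated by mixture recovery (mean absolute exposure error ≈ 0.004, no
false signature above the cutoff in 100/100 simulated spectra) rather than
by bit-compatibility. Catalog-level exclusions (e.g. artefact signatures)
are a load-time option, not hard-coded.

## Cohort statistics

When a patient contributes several samples to a group, their median is
used. Rank tests are exact (scipy enumeration, matching brute-force
permutation oracles) below 25 per group without ties, else
normal-approximated with tie correction — the study's group sizes straddle
that boundary. Fisher tests are exact two-sided by the "probability at
most that of the observed table" rule. Spearman correlations use exact
permutation below n = 11 and the t-approximation above. The burden model
is OLS `n_snvs ~ status + age` with a t-test on the status coefficient. A
sample's expansion flag is true iff ≥ 1 cluster survives all filters *and*
is present in that sample (CCF ≥ 0.05); its CCF summary is the maximum
retained-cluster CCF, taken as the expansion's size. CCF is multiplied by
100 when compared against epithelial percentages (one-sided paired
signed-rank: stromal-origin clones should exceed the epithelial fraction).

## Synthetic cohorts

The generator emulates ~55X WGS somatic calls. Defaults are the study
conditions: 30 cancer patients (one normal + one tumour sample each) and 7
non-cancer donors (one normal each), detected-SNV burden means 436
(cancer-patient normal), 141 (non-cancer normal), 952 (BPH), 2,560.5
(tumour) and 1,116 (fibroblast); indel means 455/62/455/265/455;
expansion probabilities 23/37 (cancer normals), 1/7 (non-cancer), 1
(tumours), 0.8 (fibroblasts); depth Poisson(55); tumour purity
Uniform(0.5, 0.9).

Per patient, a clone tree grows by sequential attachment with uniform
parent choice; per-sample CCFs are drawn top-down, children splitting a
uniform fraction of the parent's residual, which guarantees the sum rule.
The root is the germline lineage: its truncal (developmental) mutations
are shared with the matched blood and removed by somatic calling, so the
root carries **no callable SNVs** and normal samples contain only
subclonal structure, as observed in this tissue. Subclone CCFs have a 0.1
floor (detectability at ~55X). Each sample carries a private neutral 1/f²
passenger tail on VAF (0.05, 0.25) — 35% of the burden in normals, 20% in
tumours — and clone SNV counts are negative-binomial (dispersion 8) around
the configured means, a modelling convenience the analysis does not
assume. Burden means refer to *detected* calls (≥ 2 alt reads), so
emission counts are inflated by the analytic detection probability; group
medians recover the configured means within ~5% over 10 seeds.
Trinucleotide channels are drawn from per-tissue mixtures over a synthetic
sparse signature catalog (Dirichlet(0.1) columns — a labelled stand-in for
a reference catalog, not a copy of one). Tumour samples also receive
copy-number segment lists and rearrangement counts (means 42 and 40;
normals ~0); segments are placed outside the variant coordinate span, so
they contribute burden without altering SNV genotypes. Epithelial
percentages of expansion-bearing normal samples are drawn below the
largest clone's CCF, emulating stromal-origin expansions. Randomness flows
through per-patient `SeedSequence` substreams, so adding a patient leaves
the others byte-identical.

What the synthetic cohorts do **not** emulate: real genome coordinates
and mutation hotspots, indel sequence realism, subclonal copy number,
sample contamination and mapping artefacts, or inter-patient burden
covariates beyond group and age ranges. Passing recovery tests therefore
demonstrates correctness of the inference under the stated statistical
model, not performance on real sequencing data.

## Problem sizes and numerical choices

The test suite and the acceptance script run reduced-but-adequate problem
sizes chosen for a single CPU: Gibbs chains of 800–900 iterations (half
burn-in) for recovery checks — the merge step makes results insensitive
to chain length beyond this — and an end-to-end cohort of 10 + 7 patients
with 600–1,000 neutrality null simulations. Likelihoods are computed on
the CCF grid once per patient and sample; ξ is clipped to
[1e-6, 1 − 1e-6]; empty clusters redraw positions from the uniform grid
prior. Ties in indel assignment go to the larger cluster; equal-depth
candidate parents in tree building are ordered deterministically by node
id. An unresolvable phylogeny for one patient is reported as a
machine-parsable warning and skipped rather than aborting the cohort run;
every other stage error aborts with the stage name and patient id.
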
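"""Synthetic multi-patient read-count cohorts with known ground truth.

The generator emulates the statistical structure of ~55X whole-genome
somatic calls from prostate tissue: per-patient clone trees whose
per-sample clonal cell fractions obey the pigeonhole sum rule, a neutral
1/f^2 tail of passenger mutations, binomial read sampling at
Poisson-distributed depth, trinucleotide channels drawn from per-tissue
signature mixtures, and the cohort contrasts of the study design —
higher SNV/indel burden and more frequent selected expansions in the
morphologically normal tissue of cancer patients than of non-cancer
donors, and tumour samples with far more SNVs, rearrangements and
copy-number changes than normals.

The clone-tree root is the germline lineage: its truncal (developmental)
mutations are shared with the matched blood control and therefore never
appear in the somatic call set, so the root carries no callable SNVs and
morphologically normal samples contain only subclonal structure, as
observed in this tissue.

Randomness flows from a single seed through per-patient substreams
(``numpy`` ``SeedSequence.spawn``), so regenerating with one more patient
leaves the others untouched.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io_formats import (BASES, SUBSTITUTIONS, CHANNELS_96, CopyNumberSegment,
                         SampleMeta, SignatureCatalog, ValidationError,
                         VariantRecord, revcomp, write_copy_number,
                         write_sample_sheet, write_signature_catalog,
                         write_vcf)

#: a variant is counted in a sample's burden when at least this many reads
#: support it (caller filter standing in for a somatic caller's evidence
#: threshold at ~55X)
MIN_ALT_READS = 2
SEQ_ERROR_RATE = 1e-4


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_burden() -> dict[str, float]:
    # group medians reported for this cohort design
    return {"cancer_normal": 436.0, "noncancer_normal": 141.0,
            "bph": 952.0, "tumour": 2560.5, "fibroblast": 1116.0}


def _default_indel_burden() -> dict[str, float]:
    return {"cancer_normal": 455.0, "noncancer_normal": 62.0,
            "bph": 455.0, "tumour": 265.0, "fibroblast": 455.0}


def _default_expansion_prob() -> dict[str, float]:
    # 23/37 cancer normals vs 1/7 non-cancer normals; tumours are clonal
    # expansions by definition; 4/5 fibroblast cultures
    return {"cancer_normal": 23 / 37, "noncancer_normal": 1 / 7,
            "bph": 23 / 37, "tumour": 1.0, "fibroblast": 0.8}


def _default_mixtures() -> dict[str, dict[str, float]]:
    return {
        "normal": {"S1": 0.6, "S2": 0.4},
        "bph": {"S1": 0.6, "S2": 0.4},
        "tumour": {"S1": 0.45, "S2": 0.2, "S3": 0.35},
        "fibroblast": {"S1": 0.5, "S4": 0.5},
    }


@dataclass
class SimConfig:
    """Study conditions for the simulated cohort."""

    seed: int = 0
    n_cancer_patients: int = 30
    n_noncancer_patients: int = 7
    cancer_samples: tuple[str, ...] = ("normal", "tumour")
    noncancer_samples: tuple[str, ...] = ("normal",)
    depth_mean: float = 55.0
    snv_burden_mean: dict[str, float] = field(default_factory=_default_burden)
    indel_burden_mean: dict[str, float] = field(default_factory=_default_indel_burden)
    burden_dispersion: float = 8.0          # negative-binomial size
    expansion_probability: dict[str, float] = field(
        default_factory=_default_expansion_prob)
    max_subclones: int = 3
    subclone_share_probability: float = 0.3  # share into sibling normal samples
    neutral_tail_fraction: float = 0.35
    tumour_tail_fraction: float = 0.2
    tail_fmin: float = 0.05
    tail_fmax: float = 0.25
    signature_mixtures: dict[str, dict[str, float]] = field(
        default_factory=_default_mixtures)
    tumour_purity_range: tuple[float, float] = (0.5, 0.9)
    tumour_cna_mean: float = 42.0
    tumour_rearrangement_mean: float = 40.0
    normal_rearrangement_mean: float = 0.25

    def validate(self) -> None:
        for g, p in self.expansion_probability.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"expansion probability for {g} outside [0,1]")
        for g, m in self.snv_burden_mean.items():
            if m <= 0:
                raise ValidationError(f"burden mean for {g} must be > 0")
        for tc, mix in self.signature_mixtures.items():
            if abs(sum(mix.values()) - 1) > 1e-6:
                raise ValidationError(f"signature mixture for {tc} must sum to 1")
        if not 0 < self.tail_fmin < self.tail_fmax <= 0.5:
            raise ValidationError("need 0 < tail_fmin < tail_fmax <= 0.5")
        if not 0 <= self.neutral_tail_fraction <= 1:
            raise ValidationError("neutral_tail_fraction outside [0,1]")


def load_config(path: str | Path) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("cancer_samples", "noncancer_samples", "tumour_purity_range"):
        if key in data:
            data[key] = tuple(data[key])
    cfg = SimConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class PatientTruth:
    parent: dict[str, str]                       # clone -> parent clone
    clone_ccfs: dict[str, dict[str, float]]      # clone -> sample -> CCF
    clone_snvs: dict[str, int]
    selected: dict[str, bool]
    tail_mutations: dict[str, list[str]]         # sample -> mutation ids
    exposures: dict[str, dict[str, float]]       # sample -> signature mix


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth]
    has_expansion: dict[str, bool]               # sample -> truth flag

    def to_json(self, path: str | Path) -> None:
        payload = {
            "patients": {p: asdict(t) for p, t in self.patients.items()},
            "has_expansion": self.has_expansion,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            patients={p: PatientTruth(**t) for p, t in payload["patients"].items()},
            has_expansion=payload["has_expansion"],
        )


@dataclass
class SimulatedCohort:
    variants: dict[str, list[VariantRecord]]     # patient -> records
    sample_sheet: list[SampleMeta]
    segments: list[CopyNumberSegment]
    rearrangements: dict[str, int]               # sample -> count
    truth: GroundTruth
    catalog: SignatureCatalog

    def control_counts(self, patient_id: str) -> dict[str, tuple[int, int]]:
        """Blood-control (depth, alt) per mutation for one patient."""
        ctrl = next(m.sample_id for m in self.sample_sheet
                    if m.patient_id == patient_id and m.tissue_class == "control")
        return {v.mutation_id: v.counts[ctrl]
                for v in self.variants[patient_id] if ctrl in v.counts}


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def sample_neutral_vafs(n: int, fmin: float, fmax: float,
                        rng: np.random.Generator | int = 0) -> np.ndarray:
    """Draw allele frequencies from the neutral 1/f^2 density on [fmin, fmax].

    Inverse-CDF: v = 1 / (1/fmax + u * (1/fmin - 1/fmax)), u ~ Uniform(0,1);
    u = 0 maps to fmax and u -> 1 to fmin.  The implied cumulative count
    above f is linear in (1/f - 1/fmax), the defining neutral power law.
    """
    if not 0 < fmin < fmax <= 0.5:
        raise ValueError("need 0 < fmin < fmax <= 0.5")
    if n == 0:
        return np.array([])
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    u = rng.random(n)
    return 1.0 / (1.0 / fmax + u * (1.0 / fmin - 1.0 / fmax))


def synthetic_signature_catalog(n_signatures: int = 5, seed: int = 17,
                                concentration: float = 0.1) -> SignatureCatalog:
    """A synthetic catalog of sparse, well-separated 96-channel signatures.

    Stand-in for a reference SBS catalog: columns are Dirichlet draws with a
    small concentration so each signature loads on a distinct subset of
    channels.  Names are S1..Sn.
    """
    rng = np.random.default_rng(seed)
    matrix = {}
    for i in range(n_signatures):
        matrix[f"S{i + 1}"] = rng.dirichlet(np.full(96, concentration))
    return SignatureCatalog(matrix)


_CHANNEL_RE = re.compile(r"^([ACGT])\[([CT])>([ACGT])\]([ACGT])$")


def channel_to_mutation(channel: str) -> tuple[str, str, str]:
    """(ref, alt, context) for a 96-channel label."""
    m = _CHANNEL_RE.match(channel)
    if not m:
        raise ValueError(f"bad channel label {channel!r}")
    five, ref, alt, three = m.groups()
    return ref, alt, five + ref + three


def _negbin(rng: np.random.Generator, mean: float, size_param: float) -> int:
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _group_of(tissue_class: str, donor_has_cancer: bool) -> str:
    if tissue_class == "normal":
        return "cancer_normal" if donor_has_cancer else "noncancer_normal"
    return tissue_class


class _PatientBuilder:
    def __init__(self, pid: str, tissue_classes: Sequence[str],
                 donor_has_cancer: bool, cfg: SimConfig,
                 catalog: SignatureCatalog, rng: np.random.Generator) -> None:
        self.pid = pid
        self.cfg = cfg
        self.catalog = catalog
        self.rng = rng
        self.donor_has_cancer = donor_has_cancer
        self.sample_ids = [f"{pid}_{tc[0].upper()}{i + 1}"
                           for i, tc in enumerate(tissue_classes)]
        self.classes = dict(zip(self.sample_ids, tissue_classes))
        self.control_id = f"{pid}_BL"
        self.purity = {
            s: (float(rng.uniform(*cfg.tumour_purity_range))
                if tc == "tumour" else 1.0)
            for s, tc in self.classes.items()
        }
        self._pos = 0
        self.records: list[VariantRecord] = []
        self.tail_ids: dict[str, list[str]] = {s: [] for s in self.sample_ids}

    # -- clone structure ----------------------------------------------------

    def build_clones(self) -> tuple[dict, dict, dict]:
        """Draw the clone tree and per-sample CCFs (sum rule by residuals)."""
        cfg, rng = self.cfg, self.rng
        parent = {"clonal_root": "germline"}
        ccfs: dict[str, dict[str, float]] = {
            "clonal_root": {s: 1.0 for s in self.sample_ids}}
        residual: dict[str, dict[str, float]] = {
            "clonal_root": {s: 1.0 for s in self.sample_ids}}
        home: dict[str, str] = {}
        self.sample_has_expansion: dict[str, bool] = {}
        n_clone = 0

        normals = [s for s in self.sample_ids if self.classes[s] != "tumour"]
        tumours = [s for s in self.sample_ids if self.classes[s] == "tumour"]

        for s in tumours:
            # the tumour trunk is itself a clonal expansion
            has_exp = bool(rng.random() < cfg.expansion_probability["tumour"])
            self.sample_has_expansion[s] = has_exp
            if not has_exp:
                continue
            trunk = f"tumour_trunk_{s}"
            parent[trunk] = "clonal_root"
            ccfs[trunk] = {t: (1.0 if t == s else 0.0) for t in self.sample_ids}
            residual["clonal_root"][s] = 0.0
            residual[trunk] = {t: (1.0 if t == s else 0.0) for t in self.sample_ids}
            home[trunk] = s
            for _ in range(int(rng.integers(1, cfg.max_subclones + 1))):
                n_clone += 1
                self._attach_subclone(f"sub{n_clone}", s, parent, ccfs,
                                      residual, home, anchor=trunk)

        for s in normals:
            group = _group_of(self.classes[s], self.donor_has_cancer)
            has_exp = bool(rng.random() < cfg.expansion_probability[group])
            self.sample_has_expansion[s] = has_exp
            if not has_exp:
                continue
            for _ in range(int(rng.integers(1, cfg.max_subclones + 1))):
                n_clone += 1
                name = f"sub{n_clone}"
                ok = self._attach_subclone(name, s, parent, ccfs, residual,
                                           home, anchor="clonal_root")
                if ok and len(normals) > 1:
                    self._share_clone(name, s, normals, parent, ccfs, residual)
        self.home = home
        return parent, ccfs, residual

    def _attach_subclone(self, name: str, s: str, parent, ccfs, residual,
                         home, anchor: str) -> bool:
        rng = self.rng
        cands = [c for c in residual
                 if residual[c].get(s, 0.0) >= 0.3
                 and (c == anchor or home.get(c) == s)]
        if not cands:
            return False
        par = str(rng.choice(sorted(cands)))
        # detectability floor ~0.1 CCF at ~55X
        ccf = max(0.1, float(rng.uniform(0.25, 0.75)) * residual[par][s])
        ccf = min(ccf, residual[par][s])
        parent[name] = par
        ccfs[name] = {t: (ccf if t == s else 0.0) for t in self.sample_ids}
        residual[par][s] -= ccf
        residual[name] = {t: (ccf if t == s else 0.0) for t in self.sample_ids}
        home[name] = s
        return True

    def _share_clone(self, name: str, s: str, normals, parent, ccfs, residual):
        """Optionally extend a clone into sibling normal samples."""
        rng, cfg = self.rng, self.cfg
        par = parent[name]
        for other in normals:
            if other == s or rng.random() >= cfg.subclone_share_probability:
                continue
            avail = residual[par].get(other, 0.0)
            if avail < 0.15:
                continue
            ccf = float(rng.uniform(0.25, 0.75)) * avail
            ccfs[name][other] = ccf
            residual[par][other] -= ccf
            residual[name][other] = ccf
            self.sample_has_expansion[other] = True

    # -- mutation drawing ---------------------------------------------------

    def _detect_prob(self, vaf: float) -> float:
        """Chance a variant at this VAF clears the read-support threshold.

        Alt reads are ~Poisson(depth * vaf) at Poisson depth, so the
        two-read detection probability is 1 - e^-lam (1 + lam).  Burden
        targets refer to detected calls, so emission counts are inflated by
        the inverse of this.
        """
        lam = self.cfg.depth_mean * vaf
        return float(1 - np.exp(-lam) * (1 + lam))

    def _tail_detect_prob(self) -> float:
        """Detection probability averaged over the 1/f^2 tail density."""
        cfg = self.cfg
        v = np.linspace(cfg.tail_fmin, cfg.tail_fmax, 200)
        w = 1.0 / v ** 2
        w /= w.sum()
        lam = cfg.depth_mean * v
        return float(np.sum(w * (1 - np.exp(-lam) * (1 + lam))))

    def _mixture_for(self, sample_id: str) -> dict[str, float]:
        return self.cfg.signature_mixtures[self.classes[sample_id]]

    def _draw_channels(self, n: int, mixture: Mapping[str, float]) -> list[str]:
        rng = self.rng
        names = list(mixture)
        sig_idx = rng.choice(len(names), size=n, p=[mixture[k] for k in names])
        out = []
        for i in sig_idx:
            probs = self.catalog[names[i]]
            out.append(CHANNELS_96[int(rng.choice(96, p=probs))])
        return out

    def _next_pos(self) -> int:
        self._pos += 1
        return self._pos * 1000

    def _emit(self, expected_vaf: dict[str, float], channel: str | None,
              vclass: str, cn_map=None) -> VariantRecord | None:
        """One variant with binomial read counts in every sample + control."""
        rng, cfg = self.rng, self.cfg
        pos = self._next_pos()
        if vclass == "SNV":
            ref, alt, ctx = channel_to_mutation(channel)
            # half the catalog's pyrimidine-centred channels are observed on
            # the opposite strand in real calls
            if rng.random() < 0.5:
                ctx_w = revcomp(ctx)
                ref_w, alt_w = ctx_w[1], revcomp(alt)
            else:
                ctx_w, ref_w, alt_w = ctx, ref, alt
        else:
            ref_w, alt_w, ctx_w = "A", "AT", None
        counts = {}
        detected = False
        for s in self.sample_ids:
            depth = int(rng.poisson(cfg.depth_mean))
            v = expected_vaf.get(s, 0.0)
            v = max(v, SEQ_ERROR_RATE)
            a = int(rng.binomial(depth, min(v, 1.0))) if depth else 0
            counts[s] = (depth, a)
            if a >= MIN_ALT_READS:
                detected = True
        depth = int(rng.poisson(cfg.depth_mean))
        counts[self.control_id] = (
            depth, int(rng.binomial(depth, SEQ_ERROR_RATE)) if depth else 0)
        if not detected:
            return None
        rec = VariantRecord(chrom="1", pos=pos, ref=ref_w, alt=alt_w,
                            vclass=vclass, counts=counts, context=ctx_w)
        self.records.append(rec)
        return rec

    def expected_vaf(self, ccf_by_sample: Mapping[str, float]) -> dict[str, float]:
        out = {}
        for s, ccf in ccf_by_sample.items():
            rho = self.purity[s]
            out[s] = ccf * rho / (rho * 2 + (1 - rho) * 2)  # m=1, cn_t=2
        return out

    def build_mutations(self, parent, ccfs) -> PatientTruth:
        cfg, rng = self.cfg, self.rng
        clone_snvs: dict[str, int] = {"clonal_root": 0}
        # the root's truncal mutations are germline-shared and not callable
        budgets = {}
        for s in self.sample_ids:
            group = _group_of(self.classes[s], self.donor_has_cancer)
            budgets[s] = max(_negbin(rng, cfg.snv_burden_mean[group],
                                     cfg.burden_dispersion), 20)

        clones_by_home: dict[str, list[str]] = {s: [] for s in self.sample_ids}
        for c in ccfs:
            if c == "clonal_root":
                continue
            clones_by_home[self.home[c]].append(c)

        tail_n: dict[str, int] = {}
        for s in self.sample_ids:
            tumour = self.classes[s] == "tumour"
            tail_frac = cfg.tumour_tail_fraction if tumour else cfg.neutral_tail_fraction
            clones = sorted(clones_by_home[s])
            if clones:
                tail_n[s] = int(round(tail_frac * budgets[s]))
                clone_budget = budgets[s] - tail_n[s]
                weights = np.array([3.0 if c.startswith("tumour_trunk") else 1.0
                                    for c in clones])
                shares = rng.dirichlet(weights * 2)
                raw = np.maximum((shares * clone_budget).astype(int), 5)
                for c, n in zip(clones, raw):
                    clone_snvs[c] = int(n)
            else:
                tail_n[s] = budgets[s]

        exposures = {s: dict(self._mixture_for(s)) for s in self.sample_ids}

        # clone mutations (emission inflated for detection losses)
        for c in sorted(clone_snvs):
            n = clone_snvs[c]
            if n == 0:
                continue
            mix = self._mixture_for(self.home[c])
            vafs = self.expected_vaf(ccfs[c])
            n_emit = int(round(n / max(self._detect_prob(vafs[self.home[c]]), 0.2)))
            for ch in self._draw_channels(n_emit, mix):
                self._emit(vafs, ch, "SNV")

        # neutral tail, private per sample
        p_tail = self._tail_detect_prob()
        for s in self.sample_ids:
            n = int(round(tail_n[s] / p_tail))
            true_v = sample_neutral_vafs(n, cfg.tail_fmin, cfg.tail_fmax, rng)
            chans = self._draw_channels(n, self._mixture_for(s))
            for v, ch in zip(true_v, chans):
                # the tail is defined on the VAF scale directly
                rec = self._emit({s: float(v)}, ch, "SNV")
                if rec is not None:
                    self.tail_ids[s].append(rec.mutation_id)

        # indels: mostly private, some attached to clones
        for s in self.sample_ids:
            group = _group_of(self.classes[s], self.donor_has_cancer)
            n_ind = _negbin(rng, cfg.indel_burden_mean[group],
                            cfg.burden_dispersion)
            clones = sorted(clones_by_home[s])
            n_clone_ind = int(0.3 * n_ind) if clones else 0
            for _ in range(n_clone_ind):
                c = str(rng.choice(clones))
                self._emit(self.expected_vaf(ccfs[c]), None, "indel")
            priv = sample_neutral_vafs(int(round((n_ind - n_clone_ind) / p_tail)),
                                       cfg.tail_fmin, cfg.tail_fmax, rng)
            for v in priv:
                self._emit({s: float(v)}, None, "indel")

        selected = {c: c != "clonal_root" for c in ccfs}
        return PatientTruth(
            parent=parent,
            clone_ccfs={c: dict(v) for c, v in ccfs.items()},
            clone_snvs=clone_snvs,
            selected=selected,
            tail_mutations=self.tail_ids,
            exposures=exposures,
        )


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Generate the full cohort: variants per patient, sample sheet,
    copy-number segments, rearrangement counts and ground truth.

    Identical config (including seed) gives identical output.
    """
    cfg = config or SimConfig()
    cfg.validate()
    catalog = synthetic_signature_catalog(
        n_signatures=max(5, len({n for mix in cfg.signature_mixtures.values()
                                 for n in mix})))
    root_ss = np.random.SeedSequence(cfg.seed)
    n_total = cfg.n_cancer_patients + cfg.n_noncancer_patients
    streams = root_ss.spawn(n_total)

    variants: dict[str, list[VariantRecord]] = {}
    metas: list[SampleMeta] = []
    segments: list[CopyNumberSegment] = []
    rearrangements: dict[str, int] = {}
    patients: dict[str, PatientTruth] = {}
    has_expansion: dict[str, bool] = {}

    plan = ([("C", True, cfg.cancer_samples)] * cfg.n_cancer_patients
            + [("H", False, cfg.noncancer_samples)] * cfg.n_noncancer_patients)

    for idx, ((tag, cancer, tissue_classes), ss) in enumerate(zip(plan, streams)):
        pid = f"P{tag}{idx + 1:03d}"
        rng = np.random.default_rng(ss)
        builder = _PatientBuilder(pid, tissue_classes, cancer, cfg, catalog, rng)
        parent, ccfs, _ = builder.build_clones()
        truth = builder.build_mutations(parent, ccfs)
        patients[pid] = truth
        variants[pid] = sorted(builder.records,
                               key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
        has_expansion.update(builder.sample_has_expansion)

        for s in builder.sample_ids:
            tc = builder.classes[s]
            tumour = tc == "tumour"
            if tumour:
                rearrangements[s] = int(rng.poisson(cfg.tumour_rearrangement_mean))
                n_seg = int(rng.poisson(cfg.tumour_cna_mean))
                # placed beyond the variant coordinate span: copy-number
                # burden without altering SNV genotypes
                base = 100_000_000
                for k in range(n_seg):
                    start = base + k * 200_000
                    major = int(rng.integers(1, 4))
                    minor = int(rng.integers(0, major + 1))
                    segments.append(CopyNumberSegment(
                        sample_id=s, chrom="1", start=start,
                        end=start + 100_000, major_cn=major, minor_cn=minor))
            else:
                rearrangements[s] = int(rng.poisson(cfg.normal_rearrangement_mean))

            max_sub_ccf = max(
                (truth.clone_ccfs[c].get(s, 0.0) for c in truth.clone_ccfs
                 if c != "clonal_root"), default=0.0)
            if tc in ("normal", "bph") and max_sub_ccf > 0:
                # stromal-origin expansions: the epithelial proportion sits
                # below the largest clone's CCF
                epi = float(rng.uniform(0.2, 0.8)) * max_sub_ccf * 100
            elif tc in ("normal", "bph"):
                epi = float(rng.uniform(20, 60))
            else:
                epi = None
            stromal = None if epi is None else min(100 - epi,
                                                   float(rng.uniform(30, 70)))
            metas.append(SampleMeta(
                patient_id=pid, sample_id=s, tissue_class=tc,
                donor_has_cancer=cancer, purity=builder.purity[s],
                epithelial_pct=epi, stromal_pct=stromal,
                distance_to_tumour_mm=(float(rng.uniform(2, 20))
                                       if cancer and not tumour else None),
                age=float(rng.integers(55, 76) if cancer
                          else rng.integers(40, 81)),
                multifocal=bool(rng.random() < 0.8) if cancer else None,
            ))
        metas.append(SampleMeta(
            patient_id=pid, sample_id=builder.control_id,
            tissue_class="control", donor_has_cancer=cancer, purity=1.0))

    return SimulatedCohort(
        variants=variants, sample_sheet=metas, segments=segments,
        rearrangements=rearrangements,
        truth=GroundTruth(patients=patients, has_expansion=has_expansion),
        catalog=catalog,
    )


def count_sample_burdens(cohort: SimulatedCohort
                         ) -> tuple[dict[str, int], dict[str, int]]:
    """Detected SNV and indel counts per sample (alt reads >= 2)."""
    snvs: dict[str, int] = {}
    indels: dict[str, int] = {}
    controls = {m.sample_id for m in cohort.sample_sheet
                if m.tissue_class == "control"}
    for recs in cohort.variants.values():
        for rec in recs:
            store = snvs if rec.vclass == "SNV" else indels
            for sid, (_, alt) in rec.counts.items():
                if sid in controls:
                    continue
                if alt >= MIN_ALT_READS:
                    store[sid] = store.get(sid, 0) + 1
    return snvs, indels


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Serialise a simulated cohort with the io_formats writers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for pid, recs in sorted(cohort.variants.items()):
        sample_ids = sorted({s for r in recs for s in r.counts})
        p = outdir / f"{pid}.vcf"
        write_vcf(p, recs, sample_ids)
        paths[f"vcf_{pid}"] = p
    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    write_sample_sheet(paths["sample_sheet"], cohort.sample_sheet)
    paths["segments"] = outdir / "copy_number.tsv"
    write_copy_number(paths["segments"], cohort.segments)
    paths["catalog"] = outdir / "signature_catalog.tsv"
    write_signature_catalog(paths["catalog"], cohort.catalog)
    paths["truth"] = outdir / "ground_truth.json"
    cohort.truth.to_json(paths["truth"])
    paths["rearrangements"] = outdir / "rearrangements.tsv"
    with open(paths["rearrangements"], "w") as fh:
        fh.write("sample_id\tn_rearrangements\n")
        for sid, n in sorted(cohort.rearrangements.items()):
            fh.write(f"{sid}\t{n}\n")
    return paths
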
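"""Readers and writers for the external formats the pipeline touches.

Variant calls travel as VCF 4.2 with per-sample AD (ref,alt) FORMAT fields
and an optional INFO/CTX key carrying the reference trinucleotide context.
Sample metadata, copy-number segments and signature catalogs are
tab-separated tables with fixed header names.

Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The 96 single-base-substitution channels in fixed COSMIC order:
#: six pyrimidine-centred substitutions x 16 flanking-base combinations.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

TISSUE_CLASSES = ("normal", "bph", "tumour", "fibroblast", "control")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One somatic variant with per-sample read support.

    ``counts`` maps sample id to ``(depth, alt_count)``.  ``context`` is the
    reference trinucleotide centred on ``pos`` and is only meaningful for
    SNVs, where its middle base must equal ``ref``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str  # "SNV" | "indel"
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    context: str | None = None

    def __post_init__(self) -> None:
        if self.vclass not in ("SNV", "indel"):
            raise ValidationError(f"unknown vclass {self.vclass!r}")
        if self.vclass == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValidationError(
                    f"SNV at {self.chrom}:{self.pos} must have single-base alleles"
                )
            if self.ref == self.alt:
                raise ValidationError(f"SNV ref == alt at {self.chrom}:{self.pos}")
            if self.context is not None:
                if len(self.context) != 3 or self.context[1] != self.ref:
                    raise ValidationError(
                        f"context {self.context!r} does not centre on ref "
                        f"{self.ref!r} at {self.chrom}:{self.pos}"
                    )
        for sid, (depth, alt_count) in self.counts.items():
            if alt_count > depth:
                raise ValidationError(
                    f"alt_count {alt_count} > depth {depth} for sample {sid} "
                    f"at {self.chrom}:{self.pos}"
                )

    @property
    def mutation_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def vaf(self, sample_id: str) -> float:
        """Variant allele fraction in one sample; NaN when depth is zero."""
        depth, alt = self.counts[sample_id]
        return alt / depth if depth > 0 else float("nan")


@dataclass
class SampleMeta:
    patient_id: str
    sample_id: str
    tissue_class: str
    donor_has_cancer: bool
    purity: float = 1.0
    epithelial_pct: float | None = None
    stromal_pct: float | None = None
    distance_to_tumour_mm: float | None = None
    age: float | None = None
    multifocal: bool | None = None

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValidationError(f"unknown tissue_class {self.tissue_class!r}")
        if not 0 < self.purity <= 1:
            raise ValidationError(f"purity {self.purity} outside (0, 1]")
        if self.epithelial_pct is not None and self.stromal_pct is not None:
            if self.epithelial_pct + self.stromal_pct > 100 + 1e-9:
                raise ValidationError(
                    f"epithelial {self.epithelial_pct} + stromal "
                    f"{self.stromal_pct} > 100 for {self.sample_id}"
                )

    @property
    def group(self) -> str:
        """Cohort group used for burden and expansion contrasts."""
        if self.tissue_class == "normal":
            return "cancer_normal" if self.donor_has_cancer else "noncancer_normal"
        return self.tissue_class


@dataclass
class CopyNumberSegment:
    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"segment start {self.start} > end {self.end}")
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValidationError(
                f"invalid copy numbers {self.major_cn}+{self.minor_cn}"
            )

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn


class SignatureCatalog:
    """A matrix of 96-channel mutational signatures.

    Each signature is a probability vector over the fixed COSMIC channel
    order; columns sum to one.
    """

    def __init__(self, matrix: Mapping[str, Sequence[float]],
                 channels: Sequence[str] = CHANNELS_96) -> None:
        if tuple(channels) != CHANNELS_96:
            raise FormatError("channel labels must follow the fixed 96-channel order")
        self.names: list[str] = list(matrix)
        self._matrix = np.column_stack([np.asarray(matrix[n], float) for n in self.names])
        if self._matrix.shape[0] != 96:
            raise FormatError(
                f"expected 96 channels, got {self._matrix.shape[0]}"
            )
        if (self._matrix < 0).any():
            raise ValidationError("signature catalog contains negative entries")
        sums = self._matrix.sum(axis=0)
        if np.any(np.abs(sums - 1) > 1e-3 + 1e-12):  # within 1e-3: renormalise
            i = int(np.argmax(np.abs(sums - 1)))
            raise ValidationError(
                f"signature {self.names[i]} does not sum to 1 (got {sums[i]:.4f})")
        self._matrix = self._matrix / sums

    @property
    def matrix(self) -> np.ndarray:
        """(96, n_signatures) column-stochastic array."""
        return self._matrix

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        return self._matrix[:, self.names.index(name)]

    def subset(self, names: Iterable[str]) -> "SignatureCatalog":
        names = list(names)
        return SignatureCatalog({n: self[n] for n in names})

    def drop(self, names: Iterable[str]) -> "SignatureCatalog":
        dropped = set(names)
        return self.subset(n for n in self.names if n not in dropped)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(path: str | Path, records: Iterable[VariantRecord],
              sample_ids: Sequence[str]) -> None:
    """Write records as a minimal VCF 4.2 with AD/DP FORMAT and INFO/CTX."""
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    chroms = sorted({r.chrom for r in records})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##INFO=<ID=CTX,Number=1,Type=String,Description="Reference trinucleotide context">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
        + "FORMAT\t" + "\t".join(sample_ids),
    ]
    for rec in records:
        info = f"CTX={rec.context}" if rec.context else "."
        cells = []
        for sid in sample_ids:
            depth, alt = rec.counts.get(sid, (0, 0))
            cells.append(f"./.:{depth - alt},{alt}:{depth}")
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}\t"
            "GT:AD:DP\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, sample_ids: Sequence[str] | None = None
             ) -> list[VariantRecord]:
    """Read biallelic variant records from a VCF 4.2 file.

    Multi-allelic rows are decomposed into one record per alternate allele;
    star alleles are dropped with a warning.  Records are returned sorted by
    (chrom, pos).
    """
    path = str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pysam warns on missing index
        vf = pysam.VariantFile(path)
    header_samples = list(vf.header.samples)
    if sample_ids is None:
        sample_ids = header_samples
    missing = [s for s in sample_ids if s not in header_samples]
    if missing:
        raise LookupError(f"samples absent from VCF header: {missing}")
    if "AD" not in vf.header.formats:
        raise FormatError("VCF lacks the FORMAT/AD field required for read counts")

    records: list[VariantRecord] = []
    for row in vf:
        alts = row.alts or ()
        for ai, alt in enumerate(alts):
            if alt in ("*", "<*>"):
                log.warning("dropping star allele at %s:%s", row.chrom, row.pos)
                continue
            counts: dict[str, tuple[int, int]] = {}
            for sid in sample_ids:
                fmt = row.samples[sid]
                ad = fmt.get("AD")
                if ad is None or all(v is None for v in ad):
                    raise FormatError(
                        f"missing AD for sample {sid} at {row.chrom}:{row.pos}"
                    )
                ad = [0 if v is None else int(v) for v in ad]
                alt_count = ad[ai + 1] if len(ad) > ai + 1 else 0
                depth = fmt.get("DP")
                depth = int(depth) if depth is not None else int(sum(ad))
                counts[sid] = (depth, alt_count)
            vclass = "SNV" if len(row.ref) == 1 and len(alt) == 1 else "indel"
            ctx = row.info.get("CTX") if "CTX" in row.info else None
            records.append(VariantRecord(
                chrom=row.chrom, pos=row.pos, ref=row.ref, alt=alt,
                vclass=vclass, counts=counts,
                context=ctx if vclass == "SNV" else None,
            ))
    vf.close()
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return records


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

_SHEET_OPTIONAL = ("purity", "epithelial_pct", "stromal_pct",
                   "distance_to_tumour_mm", "age", "multifocal")


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("1", "true", "yes", "y")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the tab-separated sample sheet.

    Purity defaults to 1 for non-tumour tissue classes; a tumour row without
    purity is an error.  Unknown extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "sample_id": str})
    required = {"patient_id", "sample_id", "tissue_class", "donor_has_cancer"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet missing columns {required - set(df.columns)}")
    metas = []
    for _, row in df.iterrows():
        kw = {}
        for col in _SHEET_OPTIONAL:
            if col in df.columns and pd.notna(row[col]):
                kw[col] = _parse_bool(row[col]) if col == "multifocal" else float(row[col])
        tissue = str(row["tissue_class"])
        if "purity" not in kw:
            if tissue == "tumour":
                raise ValidationError(
                    f"tumour sample {row['sample_id']} requires an explicit purity"
                )
            kw["purity"] = 1.0
        metas.append(SampleMeta(
            patient_id=str(row["patient_id"]),
            sample_id=str(row["sample_id"]),
            tissue_class=tissue,
            donor_has_cancer=_parse_bool(row["donor_has_cancer"]),
            **kw,
        ))
    return metas


def write_sample_sheet(path: str | Path, metas: Sequence[SampleMeta]) -> None:
    rows = []
    for m in metas:
        rows.append({
            "patient_id": m.patient_id, "sample_id": m.sample_id,
            "tissue_class": m.tissue_class,
            "donor_has_cancer": m.donor_has_cancer, "purity": m.purity,
            "epithelial_pct": m.epithelial_pct, "stromal_pct": m.stromal_pct,
            "distance_to_tumour_mm": m.distance_to_tumour_mm,
            "age": m.age, "multifocal": m.multifocal,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

def read_copy_number(path: str | Path) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    required = {"sample_id", "chrom", "start", "end", "major_cn", "minor_cn"}
    if not required.issubset(df.columns):
        raise FormatError(f"copy-number table missing {required - set(df.columns)}")
    return [
        CopyNumberSegment(
            sample_id=r.sample_id, chrom=r.chrom, start=int(r.start),
            end=int(r.end), major_cn=int(r.major_cn), minor_cn=int(r.minor_cn),
        )
        for r in df.itertuples()
    ]


def write_copy_number(path: str | Path, segments: Sequence[CopyNumberSegment]) -> None:
    pd.DataFrame([{
        "sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
        "end": s.end, "major_cn": s.major_cn, "minor_cn": s.minor_cn,
    } for s in segments]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signature catalog
# ---------------------------------------------------------------------------

def read_signature_catalog(path: str | Path,
                           exclude: Iterable[str] = ()) -> SignatureCatalog:
    """Read a COSMIC-layout catalog: first column channel labels, one column
    per signature.  Columns are renormalised when within 1e-3 of summing to 1.

    ``exclude`` drops named signatures at load time (e.g. artefactual ones).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise FormatError(f"expected 96 channel rows, got {df.shape[0]}")
    if set(df.index) != set(CHANNELS_96):
        raise FormatError("channel labels do not match the 96-channel convention")
    df = df.loc[list(CHANNELS_96)]
    catalog = SignatureCatalog({name: df[name].to_numpy() for name in df.columns})
    if exclude:
        catalog = catalog.drop(exclude)
    return catalog


def write_signature_catalog(path: str | Path, catalog: SignatureCatalog) -> None:
    df = pd.DataFrame(catalog.matrix, index=list(CHANNELS_96), columns=catalog.names)
    df.index.name = "channel"
    df.to_csv(path, sep="\t")
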
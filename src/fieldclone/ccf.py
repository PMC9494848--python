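"""Clonal cell fraction (CCF) estimation from allele fractions.

The fraction of cells in a sample carrying a mutation is estimated from the
variant allele fraction (VAF), the tumour purity rho, the local total copy
number and the mutation multiplicity m:

    CCF = VAF * (rho * cn_t + (1 - rho) * cn_n) / (rho * m)

with cn_n = 2 in the normal compartment.  Normal-tissue samples are treated
as pure (rho = 1) and copy-number neutral (cn_t = 2), where the formula
reduces to CCF = 2 * VAF for heterozygous mutations.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (CopyNumberSegment, SampleMeta, ValidationError,
                         VariantRecord)

#: CCF values above this are capped before reporting; binomial noise pushes
#: genuinely clonal mutations above 1.
CCF_CAP = 1.2


@dataclass
class CCFEntry:
    """Per-mutation, per-sample CCF with the quantities that produced it."""

    mutation_id: str
    sample_id: str
    vaf: float
    cn_t: int
    multiplicity: int
    ccf: float  # capped at CCF_CAP; clip at 1 for reporting


def compute_ccf(vaf: float, purity: float, cn_t: int, cn_n: int = 2,
                m: int = 1) -> float:
    """Clonal cell fraction from allele fraction, purity and copy number."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    if m < 1:
        raise ValueError("multiplicity must be >= 1")
    if not 0 <= vaf <= 1:
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    return vaf * (purity * cn_t + (1 - purity) * cn_n) / (purity * m)


def estimate_multiplicity(vaf: float, purity: float, cn_t: int) -> int:
    """Most likely number of mutated allele copies, clipped to [1, cn_t].

    Rounds the implied mutation copy number vaf * (rho*cn_t + (1-rho)*2)/rho;
    the standard convention when no subclonal copy-number genotyping is done.
    """
    if purity <= 0:
        raise ValueError("purity must be positive")
    raw = vaf * (purity * cn_t + (1 - purity) * 2) / purity
    return int(min(max(round(raw), 1), max(cn_t, 1)))


def attach_copy_number(variants: Sequence[VariantRecord],
                       segments: Sequence[CopyNumberSegment],
                       sample_metas: Sequence[SampleMeta],
                       default_cn: int = 2) -> dict[tuple[str, str], int]:
    """Total copy number per (mutation_id, sample_id).

    A variant takes the covering segment's major+minor total (segment ends
    inclusive) and ``default_cn`` elsewhere.  Normal-class samples always get
    ``default_cn``: the study tissue shows no copy-number alterations.
    """
    tumour_ids = {m.sample_id for m in sample_metas if m.tissue_class == "tumour"}
    # per (sample, chrom): sorted starts with parallel (end, cn)
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    index: dict[tuple[str, str], tuple[list[int], list[tuple[int, int]]]] = {}
    for key, segs in by_key.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping segments for sample {key[0]} on {key[1]}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        index[key] = ([s.start for s in segs],
                      [(s.end, s.total_cn) for s in segs])

    out: dict[tuple[str, str], int] = {}
    for rec in variants:
        for sid in rec.counts:
            cn = default_cn
            if sid in tumour_ids and (sid, rec.chrom) in index:
                starts, ends_cn = index[(sid, rec.chrom)]
                i = bisect_right(starts, rec.pos) - 1
                if i >= 0 and rec.pos <= ends_cn[i][0]:
                    cn = ends_cn[i][1]
            out[(rec.mutation_id, sid)] = cn
    return out


def compute_ccf_table(variants: Sequence[VariantRecord],
                      sample_metas: Sequence[SampleMeta],
                      segments: Sequence[CopyNumberSegment] = (),
                      cap: float = CCF_CAP) -> pd.DataFrame:
    """Per-mutation per-sample CCF table for one patient.

    Missing depth in a sample yields a missing (NaN) CCF, not zero: absence
    of reads is not evidence of absence of the clone.  Columns: mutation_id,
    sample_id, vclass, vaf, cn_t, multiplicity, ccf.
    """
    metas = {m.sample_id: m for m in sample_metas}
    cn_map = attach_copy_number(variants, segments, sample_metas)
    rows = []
    for rec in variants:
        for sid, (depth, alt) in rec.counts.items():
            if sid not in metas:  # e.g. control samples: no CCF is defined
                continue
            meta = metas[sid]
            if depth == 0:
                rows.append((rec.mutation_id, sid, rec.vclass,
                             np.nan, cn_map[(rec.mutation_id, sid)], 1, np.nan))
                continue
            vaf = alt / depth
            cn_t = cn_map[(rec.mutation_id, sid)]
            m = estimate_multiplicity(vaf, meta.purity, cn_t)
            ccf = min(compute_ccf(vaf, meta.purity, cn_t, 2, m), cap)
            rows.append((rec.mutation_id, sid, rec.vclass, vaf, cn_t, m, ccf))
    return pd.DataFrame(
        rows, columns=["mutation_id", "sample_id", "vclass", "vaf",
                       "cn_t", "multiplicity", "ccf"],
    )
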
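"""96-channel mutation spectra and signature exposure refitting.

Each SNV is mapped to one of 96 channels (six pyrimidine-centred
substitutions x 16 flanking contexts).  A sample's spectrum is decomposed
over a signature catalog by forward selection with non-negative least
squares: signatures are added while they improve the cosine similarity
between the reconstructed and observed spectra, and any signature whose
fitted exposure falls at or below the reporting cutoff (0.06) is dropped
and the remainder refitted.  Samples with fewer than 100 SNVs are excluded
from the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_formats import (CHANNEL_INDEX, CHANNELS_96, SignatureCatalog,
                         ValidationError, VariantRecord, revcomp)

log = logging.getLogger(__name__)

EXPOSURE_CUTOFF = 0.06
MIN_SNVS = 100
COSINE_GAIN = 0.01


@dataclass
class Spectrum96:
    """Counts over the 96 substitution channels in fixed COSMIC order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,):
            raise ValidationError("spectrum must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValidationError("negative channel count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS_96))


@dataclass
class ExposureResult:
    exposures: dict[str, float] = field(default_factory=dict)
    cosine_similarity: float = float("nan")
    excluded: bool = False
    reason: str | None = None


def snv_channel(ref: str, alt: str, context: str) -> str:
    """COSMIC channel of an SNV; purine references are strand-flipped."""
    if context[1] != ref:
        raise ValidationError(f"context {context!r} does not centre on {ref!r}")
    if ref in "AG":
        context = revcomp(context)
        ref = context[1]
        alt = revcomp(alt)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_96_spectrum(variants: Sequence[VariantRecord]) -> Spectrum96:
    """Accumulate SNVs with trinucleotide contexts into a 96-channel spectrum."""
    counts = np.zeros(96, dtype=int)
    for v in variants:
        if v.vclass != "SNV":
            continue
        if v.context is None:
            raise ValidationError(
                f"SNV {v.mutation_id} lacks a trinucleotide context"
            )
        counts[CHANNEL_INDEX[snv_channel(v.ref, v.alt, v.context)]] += 1
    return Spectrum96(counts)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _nnls_fit(p: np.ndarray, catalog: SignatureCatalog,
              names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    M = np.column_stack([catalog[n] for n in names])
    w, _ = nnls(M, p)
    return w, M @ w


def fit_signatures(spectrum: Spectrum96, catalog: SignatureCatalog,
                   cutoff: float = EXPOSURE_CUTOFF,
                   min_snvs: int = MIN_SNVS,
                   gain_threshold: float = COSINE_GAIN) -> ExposureResult:
    """Decompose a spectrum into catalog exposures by forward selection.

    Starts from the best single-cosine signature and adds whichever
    signature most increases the reconstruction cosine, while the increase
    exceeds ``gain_threshold``.  Exposures at or below ``cutoff`` are
    dropped (with refit) so only confidently present signatures are
    reported; reported fractions are normalised to sum to 1.
    """
    if len(catalog) == 0:
        raise ValueError("empty signature catalog")
    if spectrum.total < min_snvs:
        return ExposureResult(excluded=True, reason="min_snvs")
    p = spectrum.counts / spectrum.total

    selected: list[str] = []
    current_cos = -1.0
    while True:
        best_name, best_cos, best_w = None, current_cos, None
        for name in catalog.names:
            if name in selected:
                continue
            w, recon = _nnls_fit(p, catalog, selected + [name])
            c = cosine(p, recon)
            if c > best_cos:
                best_name, best_cos, best_w = name, c, w
        if best_name is None:
            break
        gain = best_cos - current_cos if selected else np.inf
        if selected and gain < gain_threshold:
            break
        selected.append(best_name)
        current_cos = best_cos

    # drop weakly-exposed signatures and refit until stable
    while True:
        w, recon = _nnls_fit(p, catalog, selected)
        frac = w / w.sum() if w.sum() > 0 else w
        weak = [n for n, f in zip(selected, frac) if f <= cutoff]
        if not weak or len(selected) <= 1:
            break
        drop = selected[int(np.argmin(frac))]
        selected.remove(drop)

    exposures = {n: float(f) for n, f in zip(selected, frac) if f > cutoff}
    if not exposures and selected:  # single signature left; report it fully
        exposures = {selected[0]: 1.0}
    return ExposureResult(exposures=exposures,
                          cosine_similarity=cosine(p, recon))


def summarize_cohort_signatures(results: Mapping[str, ExposureResult],
                                groups: Mapping[str, str],
                                cutoff: float = EXPOSURE_CUTOFF
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary presence table plus per-signature group-enrichment Fisher tests.

    ``groups`` maps sample id to a group label; tests compare each pair of
    groups with a 2x2 Fisher exact test on presence/absence counts.  Empty
    groups are skipped with a warning.
    """
    from .cohort import fisher_exact_2x2

    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    included = {s: r for s, r in results.items() if not r.excluded}
    signatures = sorted({n for r in included.values() for n in r.exposures})
    presence = pd.DataFrame(
        {sig: {s: r.exposures.get(sig, 0.0) > cutoff
               for s, r in included.items()} for sig in signatures}
    )
    presence.index.name = "sample_id"

    rows = []
    for ga, gb in [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]:
        sa = [s for s in included if groups[s] == ga]
        sb = [s for s in included if groups[s] == gb]
        if not sa or not sb:
            log.warning("group %s or %s empty after exclusions; test skipped",
                        ga, gb)
            continue
        for sig in signatures:
            a1 = int(presence.loc[sa, sig].sum())
            b1 = int(presence.loc[sb, sig].sum())
            p = fisher_exact_2x2([[a1, len(sa) - a1], [b1, len(sb) - b1]])
            rows.append({"signature": sig, "group_a": ga, "group_b": gb,
                         "present_a": a1, "n_a": len(sa),
                         "present_b": b1, "n_b": len(sb), "p_value": p})
    return presence, pd.DataFrame(rows)
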
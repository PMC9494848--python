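"""End-to-end orchestration: one seed, one config, plain-text outputs.

Stage order per patient: CCF estimation -> Dirichlet-process clustering ->
background and support filters -> neutrality filter -> clone tree ->
signature refitting; then cohort aggregation and statistics.  Every stage
writes TSV/Newick/JSON so any intermediate can be inspected or replaced,
and the whole run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ccf as ccf_mod
from . import cohort as cohort_mod
from . import dp, neutrality, signatures, tree
from .io_formats import (read_copy_number, read_sample_sheet,
                         read_signature_catalog, read_vcf)

log = logging.getLogger(__name__)

STAGES = ("ccf", "cluster", "neutrality", "tree", "signatures", "cohort")
#: stages that cannot run unless their prerequisite ran in the same config
STAGE_DEPS = {"cluster": ("ccf",), "neutrality": ("cluster",),
              "tree": ("cluster",), "signatures": (), "cohort": ("cluster",)}

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    input_dir: str = "."
    out_dir: str = "run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    gibbs_iterations: int = 2000
    gibbs_burn_in: int = 1000
    gibbs_truncation: int = 30
    min_support_fraction: float = 0.01
    background_alpha: float = 0.05
    background_error_rate: float | None = None
    neutrality_fmin: float = 0.1
    neutrality_fmax: float = 0.25
    neutrality_min_mutations: int = 12
    neutrality_sims: int = 1000
    signature_cutoff: float = 0.06
    signature_min_snvs: int = 100
    signature_exclude: tuple[str, ...] = ()
    min_alt_reads: int = 2

    def validate(self) -> None:
        for stage, deps in STAGE_DEPS.items():
            if self.stages.get(stage, False):
                for dep in deps:
                    if not self.stages.get(dep, False):
                        raise PipelineError(
                            f"stage {stage!r} requires stage {dep!r} to be enabled"
                        )
        if self.seed < 0:
            raise PipelineError("seed must be a non-negative integer")

    def parameter_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        params = {k: v for k, v in asdict(self).items()
                  if k not in ("input_dir", "out_dir")}
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "signature_exclude" in data:
        data["signature_exclude"] = tuple(data["signature_exclude"])
    if "stages" in data:
        base = {s: True for s in STAGES}
        base.update(data["stages"])
        data["stages"] = base
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _n_band(n: int) -> int:
    """Geometric band for the null cache: 12 * 2^k nearest to n."""
    if n <= 12:
        return 12
    k = int(round(np.log2(n / 12)))
    return 12 * 2 ** max(k, 0)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Any stage failure aborts with the stage name and patient id, except an
    unresolvable phylogeny, which is reported as a machine-parsable warning
    for that patient and leaves the remaining patients untouched.
    """
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    metas = read_sample_sheet(indir / "sample_sheet.tsv")
    seg_path = indir / "copy_number.tsv"
    segments = read_copy_number(seg_path) if seg_path.exists() else []
    catalog = None
    cat_path = indir / "signature_catalog.tsv"
    if cat_path.exists():
        catalog = read_signature_catalog(cat_path,
                                         exclude=config.signature_exclude)
    rearr: dict[str, int] = {}
    rearr_path = indir / "rearrangements.tsv"
    if rearr_path.exists():
        t = pd.read_csv(rearr_path, sep="\t")
        rearr = dict(zip(t["sample_id"], t["n_rearrangements"]))

    patients = sorted({m.patient_id for m in metas})
    seed_streams = {pid: s for pid, s in
                    zip(patients, np.random.SeedSequence(config.seed).spawn(len(patients)))}

    clusters_by_patient: dict[str, list[dp.ClusterResult]] = {}
    snv_counts: dict[str, int] = {}
    indel_counts: dict[str, int] = {}
    exposure_results: dict[str, signatures.ExposureResult] = {}
    null_cache: dict[tuple, neutrality.NullDistribution] = {}
    cluster_rows, assign_rows, neut_rows, expo_rows, spectrum_rows = [], [], [], [], []

    for pid in patients:
        pmetas = [m for m in metas if m.patient_id == pid]
        analysis = [m for m in pmetas if m.tissue_class != "control"]
        control = next((m for m in pmetas if m.tissue_class == "control"), None)
        vcf = indir / f"{pid}.vcf"
        if not vcf.exists():
            raise PipelineError(f"stage io: missing variant file for patient {pid}")
        variants = read_vcf(vcf)
        snvs = [v for v in variants if v.vclass == "SNV"]
        indels = [v for v in variants if v.vclass == "indel"]
        for m in analysis:
            snv_counts[m.sample_id] = sum(
                1 for v in snvs
                if v.counts.get(m.sample_id, (0, 0))[1] >= config.min_alt_reads)
            indel_counts[m.sample_id] = sum(
                1 for v in indels
                if v.counts.get(m.sample_id, (0, 0))[1] >= config.min_alt_reads)

        psegs = [s for s in segments
                 if s.sample_id in {m.sample_id for m in analysis}]
        ccf_table = (ccf_mod.compute_ccf_table(variants, analysis, psegs)
                     if config.stages.get("ccf") else None)
        if ccf_table is not None:
            _write_tsv(ccf_table, outdir / f"{pid}.ccf.tsv")
        if not config.stages.get("cluster"):
            continue

        try:
            child = seed_streams[pid].generate_state(1)[0] % (2 ** 31)
            settings = dp.GibbsSettings(
                truncation=config.gibbs_truncation,
                iterations=config.gibbs_iterations,
                burn_in=config.gibbs_burn_in, seed=int(child))
            cn_map = ccf_mod.attach_copy_number(variants, psegs, analysis)
            clusters = dp.fit_dirichlet_process(snvs, analysis, settings, cn_map)
            dp.filter_support(clusters, max(len(snvs), 1),
                              config.min_support_fraction)
            control_counts = None
            if control is not None:
                control_counts = {
                    v.mutation_id: (v.counts[control.sample_id][0],
                                    v.counts[control.sample_id][1])
                    for v in variants if control.sample_id in v.counts}
            dp.filter_background(clusters, snvs, control_counts,
                                 config.background_error_rate,
                                 config.background_alpha)
        except (dp.ConfigurationError, ValueError) as exc:
            raise PipelineError(f"stage cluster failed for patient {pid}: {exc}")

        if config.stages.get("neutrality"):
            reports = {}
            for m in analysis:
                vafs, depths = [], []
                for v in snvs:
                    depth, alt = v.counts.get(m.sample_id, (0, 0))
                    if alt >= config.min_alt_reads and depth > 0:
                        vafs.append(alt / depth)
                        depths.append(depth)
                mean_depth = float(np.mean(depths)) if depths else 50.0
                n_window = int(np.sum((np.array(vafs) > config.neutrality_fmin)
                                      & (np.array(vafs) < config.neutrality_fmax))
                               ) if vafs else 0
                key = (int(round(mean_depth / 10) * 10), _n_band(n_window),
                       config.neutrality_fmin, config.neutrality_fmax)
                null = None
                if n_window >= config.neutrality_min_mutations:
                    if key not in null_cache:
                        null_cache[key] = neutrality.calibrate_null(
                            depth=key[0], n_mutations=key[1],
                            n_sims=config.neutrality_sims,
                            fmin=config.neutrality_fmin,
                            fmax=config.neutrality_fmax,
                            seed=config.seed + 7919)
                    null = null_cache[key]
                reports[m.sample_id] = neutrality.fit_neutral_model(
                    vafs, null, config.neutrality_fmin, config.neutrality_fmax,
                    config.neutrality_min_mutations, sample_id=m.sample_id)
            neutrality.apply_neutrality_filter(clusters, reports)
            for rep in reports.values():
                neut_rows.append({"patient_id": pid, **rep.__dict__})

        indel_ccfs = (ccf_table[ccf_table["vclass"] == "indel"]
                      if ccf_table is not None else pd.DataFrame(
                          columns=["mutation_id", "sample_id", "ccf"]))
        dp.assign_indels(clusters, indel_ccfs)
        clusters_by_patient[pid] = clusters
        for c in clusters:
            row = {"patient_id": pid, "cluster_id": c.cluster_id,
                   "n_snvs": c.n_snvs, "n_indels": c.n_indels,
                   "fraction_of_total": c.fraction_of_total,
                   "retained": c.retained, "removal_reason": c.removal_reason}
            for s, v in c.ccf.items():
                row[f"ccf_{s}"] = v
            cluster_rows.append(row)
            for mid, prob in sorted(c.members.items()):
                assign_rows.append({"patient_id": pid, "mutation_id": mid,
                                    "cluster_id": c.cluster_id,
                                    "posterior_prob": prob})

        if config.stages.get("tree"):
            retained = [c for c in clusters
                        if c.retained and c.removal_reason == "none"]
            if retained:
                try:
                    ptree = tree.build_tree(retained)
                    newick, nodes = tree.render_tree(ptree)
                    (outdir / f"{pid}.tree.nwk").write_text(newick + "\n")
                    _write_tsv(nodes, outdir / f"{pid}.tree_nodes.tsv")
                except tree.NoConsistentPhylogenyError as exc:
                    log.warning("WARN stage=tree patient=%s %s", pid, exc)

        if config.stages.get("signatures") and catalog is not None:
            for m in analysis:
                sample_snvs = [
                    v for v in snvs
                    if v.counts.get(m.sample_id, (0, 0))[1] >= config.min_alt_reads
                    and v.context is not None]
                spectrum = signatures.build_96_spectrum(sample_snvs)
                res = signatures.fit_signatures(
                    spectrum, catalog, config.signature_cutoff,
                    config.signature_min_snvs)
                exposure_results[m.sample_id] = res
                spectrum_rows.append({"sample_id": m.sample_id,
                                      **dict(zip(spectrum.as_series().index,
                                                 spectrum.counts))})
                for sig, frac in sorted(res.exposures.items()):
                    expo_rows.append({"patient_id": pid,
                                      "sample_id": m.sample_id,
                                      "signature": sig, "exposure": frac,
                                      "cosine": res.cosine_similarity})
                if res.excluded:
                    expo_rows.append({"patient_id": pid,
                                      "sample_id": m.sample_id,
                                      "signature": "EXCLUDED", "exposure": np.nan,
                                      "cosine": np.nan})

    if cluster_rows:
        _write_tsv(pd.DataFrame(cluster_rows), outdir / "clusters.tsv")
        _write_tsv(pd.DataFrame(assign_rows), outdir / "assignments.tsv")
    if neut_rows:
        _write_tsv(pd.DataFrame(neut_rows), outdir / "neutrality.tsv")
    if expo_rows:
        _write_tsv(pd.DataFrame(expo_rows), outdir / "exposures.tsv")
    if spectrum_rows:
        _write_tsv(pd.DataFrame(spectrum_rows), outdir / "spectra.tsv")

    stats_report: dict = {}
    if config.stages.get("cohort"):
        cna_counts: dict[str, int] = {}
        for s in segments:
            cna_counts[s.sample_id] = cna_counts.get(s.sample_id, 0) + 1
        table = cohort_mod.build_cohort_table(
            metas, snv_counts, indel_counts, clusters_by_patient,
            rearr, cna_counts)
        _write_tsv(table, outdir / "cohort_table.tsv")
        stats_report = cohort_statistics(table, exposure_results,
                                         config.signature_cutoff)
        (outdir / "stats.json").write_text(
            json.dumps(stats_report, indent=1, sort_keys=True, default=float))

    manifest = {"seed": config.seed,
                "parameter_hash": config.parameter_hash(),
                "patients": patients,
                "stages": {s: bool(config.stages.get(s)) for s in STAGES}}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def cohort_statistics(table: pd.DataFrame,
                      exposure_results: dict | None = None,
                      cutoff: float = 0.06) -> dict:
    """The standard cohort comparisons on an assembled cohort table."""
    out: dict = {}
    normals = table[table["group"].isin(["cancer_normal", "noncancer_normal"])]
    if set(normals["group"]) == {"cancer_normal", "noncancer_normal"}:
        for col in ("n_snvs", "n_indels"):
            d = normals.rename(columns={col: "value"})[
                ["patient_id", "group", "value"]]
            try:
                out[f"{col}_cancer_vs_noncancer"] = cohort_mod.group_compare(d)
            except ValueError as exc:
                log.warning("comparison skipped: %s", exc)
        counts, p = cohort_mod.expansion_contingency(table)
        out["expansion_vs_cancer_status"] = {"table": counts, "p_value": p}
        with_age = normals.dropna(subset=["age"])
        per_pat = with_age.groupby("patient_id").agg(
            n_snvs=("n_snvs", "median"),
            status=("donor_has_cancer", "first"), age=("age", "median"))
        if per_pat["status"].nunique() == 2 and len(per_pat) >= 6:
            out["burden_status_age_model"] = cohort_mod.burden_model(
                per_pat["n_snvs"], per_pat["status"].astype(float),
                per_pat["age"])
            rho, p = cohort_mod.correlate(with_age["age"], with_age["n_snvs"])
            out["age_vs_snvs_spearman"] = {"rho": rho, "p_value": p}
    expanded = table[table["group"].isin(["cancer_normal", "noncancer_normal",
                                          "bph"])]
    out["ccf_vs_epithelial"] = cohort_mod.ccf_vs_epithelial(expanded)

    tumour_pairs = table[table["group"].isin(["cancer_normal", "tumour"])]
    if set(tumour_pairs["group"]) == {"cancer_normal", "tumour"}:
        d = tumour_pairs.rename(columns={"n_snvs": "value"})[
            ["patient_id", "group", "value"]]
        try:
            out["n_snvs_normal_vs_tumour_paired"] = cohort_mod.group_compare(
                d, paired=True)
        except ValueError as exc:
            log.warning("paired comparison skipped: %s", exc)
    if exposure_results:
        groups = {}
        for _, row in table.iterrows():
            if row["sample_id"] in exposure_results:
                groups[row["sample_id"]] = (
                    "tumour" if row["tissue_class"] == "tumour" else "normal")
        if len(set(groups.values())) == 2:
            presence, tests = signatures.summarize_cohort_signatures(
                exposure_results, groups, cutoff)
            out["signature_enrichment"] = tests.to_dict("records")
    return out
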
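"""End-to-end orchestration: simulate → CTC call → qPCR call → CNV call → integrate.

Each stage is a plain function over files written by the previous stage, so
the same code path serves the CLI, the numbered analysis drivers and the
tests.  A run directory gains a ``manifest.json`` with the config echo and
SHA-256 checksums of every artifact; reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cnv import (
    FocalParams,
    call_ar_amplification,
    call_focal_events,
    estimate_tumor_fraction_naive,
    gc_correct,
    normalize_depth,
    read_bed,
    read_bins,
    recenter_haploid_x,
    segment_log2,
)
from .insitu import call_ctcs, cohort_positivity, derive_cutoffs, summarize_distribution, summarize_patient
from .integrate import ASSAYS, integration_report, validate_ledger
from .qpcr import REFERENCE_GENE, compute_delta_cq, call_expression, derive_thresholds, impute_no_amplification
from .simulate import SimConfig, build_genome_model, gen_plasma_counts, write_inputs

log = logging.getLogger("liquidmix")


@dataclass
class RunConfig:
    """Shared configuration of a full pipeline run."""

    outdir: str | Path = "run"
    sim: SimConfig = field(default_factory=SimConfig)
    het_fold: float = 2.0
    lowess_span: float = 0.3
    lowess_iterations: int = 2
    penalty: float = 10.0
    min_segment_bins: int = 3
    focal: FocalParams = field(default_factory=FocalParams)
    haploid_x: bool = False
    n_plasma_patients: int = 10
    n_amp_patients: int = 5

    @property
    def seed(self) -> int:
        return self.sim.seed


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(config: RunConfig) -> dict[str, Path]:
    """Write all synthetic inputs, including one plasma bin table per
    ctDNA-assayed patient (the first ``n_amp_patients`` carry the focal
    amplification at the configured tumor fraction, the rest are flat)."""
    indir = Path(config.outdir) / "inputs"
    paths = write_inputs(config.sim, indir)
    model = build_genome_model(config.sim)
    flat = dataclasses.replace(config.sim, tumor_fraction=0.0)
    for i in range(config.n_plasma_patients):
        pid = f"P{i + 1:02d}"
        cfg = config.sim if i < config.n_amp_patients else flat
        bins = gen_plasma_counts(model, cfg, seed_offset=i + 1)
        p = indir / f"bins_{pid}.tsv"
        bins.to_csv(p, sep="\t", index=False)
        paths[f"bins_{pid}"] = p
    return paths


def input_paths(indir: str | Path) -> dict[str, Path]:
    """Reconstruct the stage-input path map from a simulate output directory."""
    indir = Path(indir)
    paths = {
        name: indir / fname
        for name, fname in (
            ("cells", "cells.tsv"),
            ("cq", "cq.csv"),
            ("bins", "bins.tsv"),
            ("genes", "genes.bed"),
            ("segdups", "segdups.bed"),
            ("known_cnv", "known_cnv.bed"),
            ("ledger", "ledger.tsv"),
        )
    }
    for p in sorted(indir.glob("bins_*.tsv")):
        paths[p.stem] = p
    return paths


def stage_ctc(config: RunConfig, cells_path: Path, outdir: Path) -> dict:
    cells = pd.read_csv(cells_path, sep="\t")
    controls = cells[cells["sample_id"].str.startswith("HC")]
    patients = cells[~cells["sample_id"].str.startswith("HC")]
    cutoffs = derive_cutoffs(controls)
    calls = call_ctcs(patients, cutoffs)
    summaries = [
        summarize_patient(sub, pid, het_fold=config.het_fold)
        for pid, sub in calls.groupby("sample_id", sort=True)
    ]
    outdir.mkdir(parents=True, exist_ok=True)
    calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "n_ctcs": s.n_ctcs,
                **{f"pos_{m}": s.marker_positive[m] for m in s.marker_positive},
                **{f"max_rcp_{m}": s.max_rcp[m] for m in s.max_rcp},
                "heterogeneous": s.heterogeneous,
            }
            for s in summaries
        ]
    ).to_csv(outdir / "patient_summary.tsv", sep="\t", index=False)
    summarize_distribution(controls).to_csv(outdir / "distribution.tsv", sep="\t", index=False)
    (outdir / "cutoffs.json").write_text(json.dumps(cutoffs, indent=2))
    return {"cutoffs": cutoffs, "summaries": summaries, "positivity": cohort_positivity(summaries)}


def stage_qpcr(config: RunConfig, cq_path: Path, outdir: Path) -> dict:
    records = pd.read_csv(cq_path)
    imputed, invalid = impute_no_amplification(records, REFERENCE_GENE)
    deltas = compute_delta_cq(imputed, REFERENCE_GENE)
    thresholds = derive_thresholds(deltas[deltas["group"] == "control"])
    calls = call_expression(deltas[deltas["group"] == "patient"], thresholds)
    outdir.mkdir(parents=True, exist_ok=True)
    deltas.to_csv(outdir / "delta_cq.tsv", sep="\t", index=False)
    (outdir / "thresholds.json").write_text(json.dumps(thresholds, indent=2))
    calls.to_csv(outdir / "expression_calls.tsv", sep="\t", index=False)
    if invalid:
        (outdir / "unevaluable_samples.txt").write_text("\n".join(invalid) + "\n")
    return {"thresholds": thresholds, "calls": calls, "unevaluable": invalid}


def cnv_call_single(
    bins: pd.DataFrame,
    genes: pd.DataFrame,
    segdups: pd.DataFrame,
    known_cnvs: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Full CNV chain for one plasma sample: normalize → GC-correct →
    segment → focal events → AR status and naive tumor-fraction surrogate."""
    normalized = gc_correct(
        normalize_depth(bins),
        span=config.lowess_span,
        iterations=config.lowess_iterations,
    )
    segments = segment_log2(normalized, penalty=config.penalty, min_size=config.min_segment_bins)
    if config.haploid_x:
        segments = recenter_haploid_x(segments)
    events = call_focal_events(segments, genes, segdups, known_cnvs, config.focal)
    tf = estimate_tumor_fraction_naive(segments)
    return {
        "normalized": normalized,
        "segments": segments,
        "events": events,
        "ar_amplification": call_ar_amplification(events),
        "tumor_fraction": tf,
    }


def stage_cnv(config: RunConfig, inputs: dict[str, Path], outdir: Path) -> dict:
    for key in ("genes", "segdups", "known_cnv"):
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"cnv stage: missing annotation file {inputs[key]}")
    genes = read_bed(inputs["genes"], with_name=True)
    segdups = read_bed(inputs["segdups"])
    known_cnvs = read_bed(inputs["known_cnv"])
    outdir.mkdir(parents=True, exist_ok=True)
    per_patient = {}
    for key, path in sorted(inputs.items()):
        if not key.startswith("bins_"):
            continue
        pid = key.removeprefix("bins_")
        res = cnv_call_single(read_bins(path), genes, segdups, known_cnvs, config)
        res["normalized"].to_csv(outdir / f"normalized_bins_{pid}.tsv", sep="\t", index=False)
        res["segments"].to_csv(outdir / f"segments_{pid}.tsv", sep="\t", index=False)
        res["events"].to_csv(outdir / f"focal_events_{pid}.tsv", sep="\t", index=False)
        per_patient[pid] = {
            "ar_amplification": bool(res["ar_amplification"]),
            "tumor_fraction_naive": res["tumor_fraction"].tf,
            "quantifiable": res["tumor_fraction"].quantifiable,
        }
    (outdir / "summary.json").write_text(
        json.dumps({"estimator": "naive surrogate", "patients": per_patient}, indent=2)
    )
    return per_patient


def assemble_ledger(
    ctc_summaries: list,
    qpcr_calls: pd.DataFrame,
    cnv_summary: dict,
    patients: list[str],
) -> pd.DataFrame:
    """Build the tri-state patients × assays matrix from the stage outputs."""
    ledger = pd.DataFrame(
        "not_assayed", index=pd.Index(patients, name="patient_id"), columns=list(ASSAYS)
    )
    marker_assay = {"AR-V7": "ARV7", "AR-FL": "ARFL", "KLK3": "KLK3"}
    for s in ctc_summaries:
        if s.patient_id not in ledger.index:
            continue
        ledger.loc[s.patient_id, "insitu_CTC"] = "positive" if s.n_ctcs > 0 else "negative"
        for marker, suffix in marker_assay.items():
            ledger.loc[s.patient_id, f"insitu_{suffix}"] = (
                "positive" if s.marker_positive[marker] else "negative"
            )
    for (sample, gene), sub in qpcr_calls.groupby(["sample_id", "gene"]):
        if sample in ledger.index and gene in marker_assay:
            ledger.loc[sample, f"qpcr_{marker_assay[gene]}"] = (
                "positive" if bool(sub["positive"].any()) else "negative"
            )
    for pid, summary in cnv_summary.items():
        if pid in ledger.index:
            ledger.loc[pid, "ctdna_AR_amp"] = (
                "positive" if summary["ar_amplification"] else "negative"
            )
    return validate_ledger(ledger)


def ledger_from_output_files(outdir: str | Path, patients: list[str] | None = None) -> pd.DataFrame:
    """Assemble the tri-state ledger from stage output files under ``outdir``
    (ctc/patient_summary.tsv, qpcr/expression_calls.tsv, cnv/summary.json)."""
    outdir = Path(outdir)
    summary = pd.read_csv(outdir / "ctc" / "patient_summary.tsv", sep="\t")
    calls = pd.read_csv(outdir / "qpcr" / "expression_calls.tsv", sep="\t")
    cnv = json.loads((outdir / "cnv" / "summary.json").read_text())["patients"]
    if patients is None:
        patients = sorted(set(summary["patient_id"]) | set(calls["sample_id"]) | set(cnv))
    ledger = pd.DataFrame(
        "not_assayed", index=pd.Index(patients, name="patient_id"), columns=list(ASSAYS)
    )
    marker_assay = {"AR-V7": "ARV7", "AR-FL": "ARFL", "KLK3": "KLK3"}
    for _, row in summary.iterrows():
        pid = row["patient_id"]
        if pid not in ledger.index:
            continue
        ledger.loc[pid, "insitu_CTC"] = "positive" if row["n_ctcs"] > 0 else "negative"
        for marker, suffix in marker_assay.items():
            ledger.loc[pid, f"insitu_{suffix}"] = (
                "positive" if bool(row[f"pos_{marker}"]) else "negative"
            )
    for (sample, gene), sub in calls.groupby(["sample_id", "gene"]):
        if sample in ledger.index and gene in marker_assay:
            ledger.loc[sample, f"qpcr_{marker_assay[gene]}"] = (
                "positive" if bool(sub["positive"].any()) else "negative"
            )
    for pid, s in cnv.items():
        if pid in ledger.index:
            ledger.loc[pid, "ctdna_AR_amp"] = "positive" if s["ar_amplification"] else "negative"
    return validate_ledger(ledger)


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and write manifest.json; returns the
    integration report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages = {}
    try:
        log.info("stage simulate")
        inputs = stage_simulate(config)
        stages["simulate"] = True
        log.info("stage ctc-call")
        ctc = stage_ctc(config, inputs["cells"], outdir / "ctc")
        stages["ctc"] = True
        log.info("stage qpcr-call")
        qpcr = stage_qpcr(config, inputs["cq"], outdir / "qpcr")
        stages["qpcr"] = True
        log.info("stage cnv-call")
        cnv = stage_cnv(config, inputs, outdir / "cnv")
        stages["cnv"] = True
        log.info("stage integrate")
        patients = [f"P{i + 1:02d}" for i in range(config.sim.n_patients)]
        ledger = assemble_ledger(ctc["summaries"], qpcr["calls"], cnv, patients)
        intdir = outdir / "integration"
        intdir.mkdir(parents=True, exist_ok=True)
        ledger.to_csv(intdir / "ledger.tsv", sep="\t")
        report = integration_report(ledger)
        (intdir / "integration_report.json").write_text(json.dumps(report, indent=2, default=str))
        stages["integrate"] = True
    except Exception as err:  # noqa: BLE001 - re-raise with stage attribution
        failed = next((s for s in ("simulate", "ctc", "qpcr", "cnv", "integrate") if s not in stages), "?")
        raise RuntimeError(f"pipeline stage '{failed}' failed: {err}") from err

    artifacts = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "elapsed_s": round(time.time() - t0, 2),
        "checksums": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
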
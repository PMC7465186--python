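"""Seeded synthetic cohort generator for the multi-analyte pipeline.

Emulates the statistical structure of every input the analysis consumes:

* per-cell RCP count tables — healthy background drawn from categorical
  occupancy probabilities calibrated to published PBMC marginals, tumor cells
  from per-marker negative binomials loosely matching the VCaP positive
  control;
* whole-blood RT-qPCR Cq tables — truncated-normal Cq per gene × group with
  gene-specific no-amplification (dropout) probabilities, emitted as missing
  values (the analysis imputes them to 46);
* plasma shallow-WGS bin counts — Poisson counts over a miniature tiled
  genome with a smooth unimodal multiplicative GC bias and a focal
  amplification blended in at a configurable tumor fraction;
* patient ledgers with exact per-assay positive/assayed marginals.

Every generator draws from its own RNG stream derived from ``seed`` plus a
stable offset, so outputs are byte-reproducible and mutually independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import stream
from .integrate import ASSAYS
from .qpcr import REFERENCE_GENE, TARGET_GENES
from .reference_data import MARKER_COLUMNS, MARKERS

# per-generator RNG stream offsets (stable; do not renumber)
_GENOME, _CELLS, _CQ, _PLASMA, _LEDGER = 11, 12, 13, 14, 15

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


def _default_background() -> dict[str, tuple[float, ...]]:
    # occupancy probabilities over 0..3 RCPs/cell, calibrated to PBMC controls
    return {
        "KLK3": (1.0, 0.0, 0.0, 0.0),
        "AR-V7": (0.9923, 0.0077, 0.0, 0.0),
        "AR-FL": (0.98910, 0.010634, 0.000266, 0.0),
    }


def _default_tumor_params() -> dict[str, tuple[float, float]]:
    # (negative-binomial mean, dispersion); loosely matched to VCaP marginals
    return {"KLK3": (0.01, 2.0), "AR-V7": (2.4, 2.0), "AR-FL": (9.0, 2.0)}


def _default_cq_means() -> dict[str, dict[str, float]]:
    return {
        REFERENCE_GENE: {"control": 25.0, "patient": 25.0},
        "AR-V7": {"control": 40.0, "patient": 39.0},
        "AR-FL": {"control": 33.0, "patient": 31.5},
        "KLK3": {"control": 34.0, "patient": 32.0},
    }


def _default_cq_sds() -> dict[str, dict[str, float]]:
    return {
        REFERENCE_GENE: {"control": 0.3, "patient": 0.3},
        "AR-V7": {"control": 1.5, "patient": 2.0},
        "AR-FL": {"control": 1.0, "patient": 2.0},
        "KLK3": {"control": 1.0, "patient": 2.0},
    }


def _default_dropout() -> dict[str, dict[str, float]]:
    # AR-V7 no-amplification rate 9/16 in both groups, as in the study cohort
    return {
        REFERENCE_GENE: {"control": 0.0, "patient": 0.0},
        "AR-V7": {"control": 0.5625, "patient": 0.5625},
        "AR-FL": {"control": 0.05, "patient": 0.05},
        "KLK3": {"control": 0.05, "patient": 0.05},
    }


def _default_ledger_marginals() -> dict[str, tuple[int, int]]:
    # assay -> (n_positive, n_assayed) out of 19 enrolled, mirroring the cohort
    return {
        "insitu_CTC": (10, 19),
        "insitu_ARV7": (10, 19),
        "insitu_ARFL": (3, 19),
        "insitu_KLK3": (4, 19),
        "qpcr_ARV7": (1, 16),
        "qpcr_ARFL": (5, 16),
        "qpcr_KLK3": (6, 16),
        "ctdna_AR_amp": (5, 10),
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    # --- in situ cell tables ---
    n_control_samples: int = 2
    n_control_cells: int = 30_000
    n_patients: int = 19
    n_background_cells_patient: int = 2_000
    ctc_prevalence: float = 10 / 19
    tumor_cells_range: tuple[int, int] = (1, 10)
    background_rcp_rate: dict[str, tuple[float, ...]] = field(default_factory=_default_background)
    tumor_cell_params: dict[str, tuple[float, float]] = field(default_factory=_default_tumor_params)
    # --- RT-qPCR ---
    n_controls_qpcr: int = 16
    n_patients_qpcr: int = 16
    n_replicates: int = 2
    cq_means: dict[str, dict[str, float]] = field(default_factory=_default_cq_means)
    cq_sds: dict[str, dict[str, float]] = field(default_factory=_default_cq_sds)
    dropout_prob: dict[str, dict[str, float]] = field(default_factory=_default_dropout)
    # --- plasma sWGS ---
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 20_000_000),
        ("chr2", 20_000_000),
        ("chr3", 20_000_000),
        ("chrX", 15_000_000),
    )
    bin_size: int = 50_000
    depth: float = 180.0
    gc_bias_amplitude: float = 0.3
    tumor_fraction: float = 0.25
    amp_locus: tuple[str, int, int, float] = ("chrX", 5_000_000, 5_500_000, 4.0)
    n_par_mask_bins: int = 5
    # --- ledger fixture ---
    ledger_marginals: dict[str, tuple[int, int]] = field(default_factory=_default_ledger_marginals)

    def validate(self) -> None:
        for marker, probs in self.background_rcp_rate.items():
            p = np.asarray(probs, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError(f"invalid background probability vector for {marker}")
        for gene, by_group in self.cq_sds.items():
            for group, sd in by_group.items():
                if sd < 0:
                    raise ValueError(f"negative Cq sd for {gene}/{group}")
        for gene, by_group in self.dropout_prob.items():
            for group, p in by_group.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"dropout probability out of [0,1] for {gene}/{group}")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        chroms = {c for c, _ in self.genome}
        c, s, e, cn = self.amp_locus
        if c not in chroms:
            raise ValueError(f"amp_locus chromosome {c} not in genome")
        length = dict(self.genome)[c]
        if not (0 <= s < e <= length):
            raise ValueError("amp_locus must lie within its chromosome")
        if cn < 0:
            raise ValueError("amp_locus copy number must be non-negative")


@dataclass
class GenomeModel:
    """Tiled miniature genome with GC per bin plus annotation tracks."""

    bins: pd.DataFrame  # chrom, start, end, gc, masked
    genes: pd.DataFrame  # chrom, start, end, name, driver
    segdups: pd.DataFrame  # chrom, start, end
    known_cnvs: pd.DataFrame  # chrom, start, end


def build_genome_model(config: SimConfig) -> GenomeModel:
    """Tile the configured chromosomes into bins and lay down annotation tracks.

    GC per bin follows a smooth genome-wide sinusoid plus a small seeded
    jitter, clipped to [0.30, 0.62], giving LOWESS a realistic range to fit.
    The first ``n_par_mask_bins`` of chrX are flagged masked (PAR surrogate).
    Genes are placed every 1 Mb on autosomes (non-driver); the driver gene AR
    sits at the configured amplification locus on chrX.
    """
    config.validate()
    rng = stream(config.seed, _GENOME)
    rows = []
    for chrom, length in config.genome:
        starts = np.arange(0, length, config.bin_size, dtype=np.int64)
        ends = np.minimum(starts + config.bin_size, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    i = np.arange(len(bins))
    gc = 0.45 + 0.10 * np.sin(2 * np.pi * i / 173.0) + rng.normal(0.0, 0.01, len(bins))
    bins["gc"] = np.clip(gc, 0.30, 0.62)
    bins["masked"] = False
    x_idx = bins.index[bins["chrom"] == "chrX"]
    bins.loc[x_idx[: config.n_par_mask_bins], "masked"] = True

    gene_rows = []
    gid = 0
    for chrom, length in config.genome:
        if chrom in SEX_CHROMS:
            continue
        for start in range(500_000, length - 100_000, 1_000_000):
            gid += 1
            gene_rows.append((chrom, start, start + 100_000, f"G{gid:03d}", False))
    ac, as_, ae, _ = config.amp_locus
    gene_rows.append((ac, as_ + 100_000, as_ + 300_000, "AR", True))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name", "driver"])

    segdups = pd.DataFrame(
        [("chr2", 2_000_000, 2_600_000), ("chr2", 14_000_000, 14_400_000)],
        columns=["chrom", "start", "end"],
    )
    known_cnvs = pd.DataFrame(
        [("chr3", 6_000_000, 6_800_000), ("chr3", 17_000_000, 17_300_000)],
        columns=["chrom", "start", "end"],
    )
    return GenomeModel(bins, genes, segdups, known_cnvs)


def _sample_background(rng: np.random.Generator, probs, n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    return rng.choice(len(p), size=n, p=p / p.sum()).astype(np.int64)


def _sample_tumor(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n).astype(np.int64)


def gen_cell_table(config: SimConfig, group: str) -> pd.DataFrame:
    """Per-cell RCP count table for 'control' or 'patient' samples.

    Controls are pure background.  Each patient mixes background cells with a
    seeded number of tumor cells (possibly zero, per ``ctc_prevalence``).
    """
    config.validate()
    if group not in ("control", "patient"):
        raise ValueError("group must be 'control' or 'patient'")
    rng = stream(config.seed, _CELLS, 0 if group == "control" else 1)
    frames = []
    if group == "control":
        for s in range(config.n_control_samples):
            sid = f"HC{s + 1:02d}"
            data = {
                "sample_id": sid,
                "cell_id": [f"{sid}_c{i}" for i in range(config.n_control_cells)],
                "source": "slide",
            }
            for marker in MARKERS:
                data[MARKER_COLUMNS[marker]] = _sample_background(
                    rng, config.background_rcp_rate[marker], config.n_control_cells
                )
            frames.append(pd.DataFrame(data))
    else:
        lo, hi = config.tumor_cells_range
        for p in range(config.n_patients):
            sid = f"P{p + 1:02d}"
            n_bg = config.n_background_cells_patient
            has_ctc = rng.random() < config.ctc_prevalence
            n_tumor = int(rng.integers(lo, hi + 1)) if has_ctc else 0
            n = n_bg + n_tumor
            data = {
                "sample_id": sid,
                "cell_id": [f"{sid}_c{i}" for i in range(n)],
                "source": "collector",
            }
            for marker in MARKERS:
                bg = _sample_background(rng, config.background_rcp_rate[marker], n_bg)
                mean, disp = config.tumor_cell_params[marker]
                tum = _sample_tumor(rng, mean, disp, n_tumor)
                data[MARKER_COLUMNS[marker]] = np.concatenate([bg, tum])
            frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def gen_cq_table(config: SimConfig) -> pd.DataFrame:
    """Cq table over samples × genes × replicates; dropouts emitted as missing.

    Cq ~ Normal(mean, sd) clipped to (0, 45]; with the gene/group dropout
    probability the reaction yields no amplification (missing Cq).  The
    reference gene never drops out.
    """
    config.validate()
    rng = stream(config.seed, _CQ)
    genes = (REFERENCE_GENE, *TARGET_GENES)
    rows = []
    groups = [("control", f"HCQ{i + 1:02d}") for i in range(config.n_controls_qpcr)] + [
        ("patient", f"P{i + 1:02d}") for i in range(config.n_patients_qpcr)
    ]
    for group, sid in groups:
        for gene in genes:
            mean = config.cq_means[gene][group]
            sd = config.cq_sds[gene][group]
            p_drop = config.dropout_prob.get(gene, {}).get(group, 0.0)
            if gene == REFERENCE_GENE:
                p_drop = 0.0
            for rep in range(1, config.n_replicates + 1):
                if rng.random() < p_drop:
                    cq = np.nan
                else:
                    cq = float(np.clip(rng.normal(mean, sd), 0.01, 45.0))
                rows.append(
                    {"sample_id": sid, "group": group, "gene": gene, "replicate": rep, "cq": cq}
                )
    return pd.DataFrame(rows)


def gc_bias_curve(gc: np.ndarray, amplitude: float, center: float = 0.45) -> np.ndarray:
    """Smooth unimodal multiplicative coverage bias, peaking at ``center``."""
    bias = 1.0 + amplitude - amplitude * ((np.asarray(gc, float) - center) / 0.2) ** 2
    return np.maximum(bias, 0.2)


def gen_plasma_counts(
    model: GenomeModel, config: SimConfig, seed_offset: int = 0
) -> pd.DataFrame:
    """Poisson bin counts with GC bias and the configured focal amplification.

    Expected count per bin = depth × (blended copy number)/2 × gc_bias(gc),
    where copy number is the amplification locus' total CN inside the locus
    and 2 elsewhere, blended by tumor fraction:
    cn_blend = tf·CN + (1−tf)·2.  Masked bins still receive counts but carry
    the masked flag.  ``seed_offset`` distinguishes multiple plasma samples.
    """
    config.validate()
    rng = stream(config.seed, _PLASMA, seed_offset)
    bins = model.bins.copy()
    ac, as_, ae, cn = config.amp_locus
    in_locus = (bins["chrom"] == ac) & (bins["start"] < ae) & (bins["end"] > as_)
    local_cn = np.where(in_locus, cn, 2.0)
    tf = config.tumor_fraction
    blend = tf * local_cn + (1.0 - tf) * 2.0
    expected = config.depth * (blend / 2.0) * gc_bias_curve(bins["gc"].to_numpy(), config.gc_bias_amplitude)
    bins["count"] = rng.poisson(expected).astype(np.int64)
    return bins[["chrom", "start", "end", "gc", "count", "masked"]]


def gen_ledger_fixture(config: SimConfig) -> pd.DataFrame:
    """Tri-state patients × assays matrix with exact per-assay marginals.

    For each assay, the first ``n_assayed`` patients are assayed and exactly
    ``n_positive`` of them (seeded random subset) are positive.
    """
    config.validate()
    rng = stream(config.seed, _LEDGER)
    n_patients = max(n for _, n in config.ledger_marginals.values())
    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    ledger = pd.DataFrame("not_assayed", index=pd.Index(patients, name="patient_id"), columns=list(ASSAYS))
    for assay, (n_pos, n_assayed) in config.ledger_marginals.items():
        if not 0 <= n_pos <= n_assayed <= n_patients:
            raise ValueError(f"invalid marginal for {assay}: {n_pos}/{n_assayed}")
        ledger.loc[patients[:n_assayed], assay] = "negative"
        pos = rng.choice(n_assayed, size=n_pos, replace=False)
        ledger.loc[[patients[i] for i in pos], assay] = "positive"
    return ledger


# ---------------------------------------------------------------------------
# file output

def write_bed(df: pd.DataFrame, path: Path, name_col: str | None = None, score_col: str | None = None) -> None:
    out = df[["chrom", "start", "end"]].copy()
    if name_col is not None:
        out["name"] = df[name_col]
        out["score"] = df[score_col].astype(int) if score_col is not None else 0
    out.to_csv(path, sep="\t", header=False, index=False)


def write_inputs(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input under ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_genome_model(config)
    paths = {}

    cells = pd.concat(
        [gen_cell_table(config, "control"), gen_cell_table(config, "patient")],
        ignore_index=True,
    )
    paths["cells"] = outdir / "cells.tsv"
    cells.to_csv(paths["cells"], sep="\t", index=False)

    paths["cq"] = outdir / "cq.csv"
    gen_cq_table(config).to_csv(paths["cq"], index=False)

    paths["bins"] = outdir / "bins.tsv"
    gen_plasma_counts(model, config).to_csv(paths["bins"], sep="\t", index=False)

    paths["genes"] = outdir / "genes.bed"
    write_bed(model.genes, paths["genes"], name_col="name", score_col="driver")
    paths["segdups"] = outdir / "segdups.bed"
    write_bed(model.segdups, paths["segdups"])
    paths["known_cnv"] = outdir / "known_cnv.bed"
    write_bed(model.known_cnvs, paths["known_cnv"])

    paths["ledger"] = outdir / "ledger.tsv"
    gen_ledger_fixture(config).to_csv(paths["ledger"], sep="\t")

    paths["config"] = outdir / "sim_config.json"
    paths["config"].write_text(json.dumps(dataclasses.asdict(config), indent=2, default=list))
    return paths
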
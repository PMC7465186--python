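"""Whole-blood RT-qPCR expression calling via reference-normalized ΔCq.

Target transcripts (AR-V7, AR-FL, KLK3) are normalized to the GUSB reference
gene: ΔCq = Cq(target) − Cq(GUSB), so lower ΔCq means higher expression.
Reactions with no amplification within the 45-cycle run are imputed at Cq 46
before normalization.  Per-gene positivity thresholds are the minimum mean
ΔCq observed among healthy-donor (negative control) samples; a patient is
positive when its ΔCq falls strictly below the threshold, so no control is
ever positive under its own thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REFERENCE_GENE = "GUSB"
TARGET_GENES = ("AR-V7", "AR-FL", "KLK3")
NO_AMPLIFICATION_CQ = 46.0
MAX_CYCLES = 45.0

__all__ = [
    "impute_no_amplification",
    "compute_delta_cq",
    "derive_thresholds",
    "call_expression",
    "REFERENCE_GENE",
    "TARGET_GENES",
    "NO_AMPLIFICATION_CQ",
]


def impute_no_amplification(
    records: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    imputed_cq: float = NO_AMPLIFICATION_CQ,
) -> tuple[pd.DataFrame, list[str]]:
    """Replace missing target-gene Cq values (no amplification) by ``imputed_cq``.

    The reference gene is never imputed: a sample whose reference failed to
    amplify has no valid ΔCq and is dropped from the returned table; such
    sample ids are returned separately so callers can report them.
    """
    out = records.copy()
    is_ref = out["gene"] == reference_gene
    bad_ref = out.loc[is_ref & out["cq"].isna(), "sample_id"].unique().tolist()
    if bad_ref:
        out = out[~out["sample_id"].isin(bad_ref)]
    target_missing = ~out["gene"].eq(reference_gene) & out["cq"].isna()
    out.loc[target_missing, "cq"] = imputed_cq
    return out, bad_ref


def compute_delta_cq(
    records: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    average_level: str = "delta",
) -> pd.DataFrame:
    """Reference-normalized expression per sample × gene, averaged over replicates.

    Replicates are paired by replicate index (ΔCq per replicate, then mean).
    If a gene's replicate indices do not match the reference's for a sample —
    or ``average_level="cq"`` is selected — Cq values are averaged first and a
    single ΔCq is formed from the means.
    """
    if average_level not in ("delta", "cq"):
        raise ValueError("average_level must be 'delta' or 'cq'")
    if records["cq"].isna().any():
        raise ValueError("records contain missing Cq values; impute first")
    rows = []
    for (sample, group), sub in records.groupby(["sample_id", "group"], sort=True):
        ref = sub[sub["gene"] == reference_gene].set_index("replicate")["cq"]
        if len(ref) == 0:
            raise ValueError(f"sample {sample} lacks reference gene {reference_gene}")
        for gene, gsub in sub[sub["gene"] != reference_gene].groupby("gene", sort=True):
            tgt = gsub.set_index("replicate")["cq"]
            paired = average_level == "delta" and set(tgt.index) == set(ref.index)
            if paired:
                delta = float((tgt - ref.reindex(tgt.index)).mean())
            else:
                delta = float(tgt.mean() - ref.mean())
            rows.append(
                {"sample_id": sample, "group": group, "gene": gene, "delta_cq": delta}
            )
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "delta_cq"])


def derive_thresholds(control_deltas: pd.DataFrame) -> dict[str, float]:
    """Positivity threshold per gene: the lowest control ΔCq (most expression seen
    in any healthy donor)."""
    if len(control_deltas) == 0:
        raise ValueError("no control ΔCq records")
    thresholds = {
        gene: float(sub["delta_cq"].min())
        for gene, sub in control_deltas.groupby("gene", sort=True)
    }
    for gene, t in thresholds.items():
        if not np.isfinite(t):
            raise ValueError(f"non-finite threshold for {gene}")
    return thresholds


def call_expression(
    patient_deltas: pd.DataFrame, thresholds: dict[str, float]
) -> pd.DataFrame:
    """Positive iff ΔCq is strictly below the gene's control-derived threshold.

    Ties are negative: the threshold is itself a control value and controls
    are negative by construction.
    """
    missing = set(patient_deltas["gene"]) - set(thresholds)
    if missing:
        raise ValueError(f"no threshold for genes: {sorted(missing)}")
    out = patient_deltas.copy()
    thr = out["gene"].map(thresholds)
    out["threshold"] = thr
    out["positive"] = out["delta_cq"] < thr
    return out
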
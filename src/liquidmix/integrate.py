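"""Patient-level integration of the three liquid-biopsy assays.

A patient ledger is a patients × assays matrix over the tri-state result set
{positive, negative, not_assayed}.  not_assayed is first-class: per-assay
percentages are computed over assayed patients only, while the overall
informative rate uses every enrolled patient, matching the mixed denominators
such summaries are reported with (x/16 assayed vs 17/19 enrolled).
Resistance is defined as AR-V7 positivity by either transcript assay or
ctDNA AR amplification; a resistant patient is "exclusive" when exactly one
of those three assays is positive.
"""

from __future__ import annotations

import pandas as pd

from ._util import percent

POSITIVE, NEGATIVE, NOT_ASSAYED = "positive", "negative", "not_assayed"
RESULT_STATES = (POSITIVE, NEGATIVE, NOT_ASSAYED)

ASSAYS = (
    "insitu_CTC",
    "insitu_ARV7",
    "insitu_ARFL",
    "insitu_KLK3",
    "qpcr_ARV7",
    "qpcr_ARFL",
    "qpcr_KLK3",
    "ctdna_AR_amp",
)
METHOD_ASSAYS = {
    "insitu": ("insitu_CTC", "insitu_ARV7", "insitu_ARFL", "insitu_KLK3"),
    "qpcr": ("qpcr_ARV7", "qpcr_ARFL", "qpcr_KLK3"),
    "ctdna": ("ctdna_AR_amp",),
}
RESISTANCE_ASSAYS = ("insitu_ARV7", "qpcr_ARV7", "ctdna_AR_amp")

__all__ = [
    "ASSAYS",
    "METHOD_ASSAYS",
    "RESISTANCE_ASSAYS",
    "validate_ledger",
    "informative_rate",
    "resistance_summary",
    "assay_concordance",
    "per_assay_positivity",
    "integration_report",
]


def validate_ledger(ledger: pd.DataFrame) -> pd.DataFrame:
    """Check the patients × assays matrix; index = patient_id, values tri-state."""
    unknown = set(ledger.columns) - set(ASSAYS)
    if unknown:
        raise ValueError(f"unknown assays in ledger: {sorted(unknown)}")
    bad = ~ledger.isin(RESULT_STATES)
    if bad.to_numpy().any():
        raise ValueError("ledger contains values outside {positive, negative, not_assayed}")
    if ledger.index.duplicated().any():
        raise ValueError("duplicate patient ids in ledger")
    return ledger


def informative_rate(ledger: pd.DataFrame) -> dict:
    """Fraction of patients with at least one positive assayed result.

    Patients with no assayed entries at all violate the ledger contract; they
    are excluded from the denominator and reported under ``excluded``.
    """
    validate_ledger(ledger)
    if len(ledger) == 0:
        raise ValueError("empty ledger")
    assayed_any = (ledger != NOT_ASSAYED).any(axis=1)
    excluded = ledger.index[~assayed_any].tolist()
    kept = ledger[assayed_any]
    if len(kept) == 0:
        raise ValueError("no patient has any assayed result")
    informative = (kept == POSITIVE).any(axis=1)
    n, k = len(kept), int(informative.sum())
    return {
        "n_patients": n,
        "n_informative": k,
        "fraction": k / n,
        "percent": percent(k, n),
        "excluded": excluded,
    }


def resistance_summary(ledger: pd.DataFrame) -> dict:
    """Resistance-marker detection (AR-V7 or AR amplification) and exclusivity.

    Exclusive detection means exactly one of the three resistance-bearing
    assays is positive for that patient; exclusive and multi-assay counts
    partition the resistant patients.
    """
    validate_ledger(ledger)
    cols = [a for a in RESISTANCE_ASSAYS if a in ledger.columns]
    pos = ledger[cols] == POSITIVE
    n_pos_assays = pos.sum(axis=1)
    resistant = n_pos_assays > 0
    n = len(ledger)
    n_resistant = int(resistant.sum())
    exclusive = resistant & (n_pos_assays == 1)
    out = {
        "n_patients": n,
        "n_resistant": n_resistant,
        "resistant_pct": percent(n_resistant, n) if n else 0,
        "n_exclusive": int(exclusive.sum()),
        "n_multi_assay": int((n_pos_assays > 1).sum()),
        "resistant_patients": ledger.index[resistant].tolist(),
        "exclusive_patients": ledger.index[exclusive].tolist(),
    }
    out["exclusive_pct"] = percent(out["n_exclusive"], n_resistant) if n_resistant else None
    return out


def assay_concordance(ledger: pd.DataFrame, marker: str) -> dict:
    """Agreement between the in situ and RT-qPCR calls for one marker.

    Concordance = share of patients assayed by both methods whose calls agree,
    as an integer percent.
    """
    validate_ledger(ledger)
    a, b = f"insitu_{marker}", f"qpcr_{marker}"
    if a not in ledger.columns or b not in ledger.columns:
        raise ValueError(f"ledger lacks columns for marker {marker}")
    both = (ledger[a] != NOT_ASSAYED) & (ledger[b] != NOT_ASSAYED)
    n = int(both.sum())
    if n == 0:
        raise ValueError(f"no patient assayed by both methods for {marker}")
    agree = int((ledger.loc[both, a] == ledger.loc[both, b]).sum())
    return {"marker": marker, "n_co_assayed": n, "n_agree": agree, "percent": percent(agree, n)}


def per_assay_positivity(ledger: pd.DataFrame) -> pd.DataFrame:
    """Positivity per assay over assayed patients, plus per-method cumulative rows.

    A method's cumulative positivity counts a patient positive when any of the
    method's assays is positive, over patients assayed by at least one of
    them.  Assays never performed are reported with percent = None, not 0.
    """
    validate_ledger(ledger)
    rows = []
    for assay in ledger.columns:
        assayed = ledger[assay] != NOT_ASSAYED
        n, k = int(assayed.sum()), int((ledger[assay] == POSITIVE).sum())
        rows.append(
            {
                "assay": assay,
                "n_positive": k,
                "n_assayed": n,
                "percent": percent(k, n) if n else None,
            }
        )
    for method, assays in METHOD_ASSAYS.items():
        cols = [a for a in assays if a in ledger.columns]
        if not cols:
            continue
        assayed = (ledger[cols] != NOT_ASSAYED).any(axis=1)
        pos = (ledger[cols] == POSITIVE).any(axis=1)
        n, k = int(assayed.sum()), int((pos & assayed).sum())
        rows.append(
            {
                "assay": f"{method}_cumulative",
                "n_positive": k,
                "n_assayed": n,
                "percent": percent(k, n) if n else None,
            }
        )
    return pd.DataFrame(rows)


def integration_report(ledger: pd.DataFrame) -> dict:
    """Full multi-analyte summary: informativeness, resistance, concordance, positivity."""
    report = {
        "informative": informative_rate(ledger),
        "resistance": resistance_summary(ledger),
        "positivity": per_assay_positivity(ledger).to_dict(orient="records"),
        "concordance": {},
    }
    for marker in ("ARV7", "ARFL", "KLK3"):
        try:
            report["concordance"][marker] = assay_concordance(ledger, marker)
        except ValueError:
            report["concordance"][marker] = None
    return report
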
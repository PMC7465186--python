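"""CTC calling from in situ padlock-probe RCP counts.

Each analyzed cell carries a rolling-circle-product (RCP) count per marker
transcript (KLK3, AR-V7, AR-FL).  Healthy-control material shows a low
background of false-positive signals, so a per-marker cut-off is derived from
the controls as (maximum background count + 1); a cell is rated a circulating
tumor cell (CTC) when it reaches the cut-off for at least one marker.
Patient-level summaries cover CTC number, per-marker positivity and
intrapatient heterogeneity; distribution summaries reproduce the standard
{0, 1, 2, 3, >3} RCPs/cell occupancy layout of assay validation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import percent, round_half_up
from .reference_data import MARKER_COLUMNS, MARKERS

__all__ = [
    "derive_cutoffs",
    "call_ctcs",
    "summarize_patient",
    "summarize_distribution",
    "cohort_positivity",
    "PatientCtcSummary",
]

_BIN_LABELS = ("0", "1", "2", "3", ">3")


def _require_marker_columns(cells: pd.DataFrame) -> None:
    missing = [c for c in MARKER_COLUMNS.values() if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table lacks marker columns: {missing}")


def derive_cutoffs(control_cells: pd.DataFrame) -> dict[str, int]:
    """Per-marker CTC cut-off: maximum RCP count seen in any control cell, plus one.

    A marker never observed in the controls gets cut-off 1 (any signal counts).
    """
    if len(control_cells) == 0:
        raise ValueError("cannot derive cut-offs from an empty control table")
    _require_marker_columns(control_cells)
    cutoffs = {}
    for marker, col in MARKER_COLUMNS.items():
        counts = control_cells[col].to_numpy()
        if (counts < 0).any():
            raise ValueError(f"negative RCP counts for {marker}")
        cutoffs[marker] = int(counts.max()) + 1 if len(counts) else 1
    return cutoffs


def call_ctcs(cells: pd.DataFrame, cutoffs: dict[str, int]) -> pd.DataFrame:
    """Classify each cell against the per-marker cut-offs.

    Returns the cell table with one boolean column per marker
    (``pos_<marker>``), the combined ``is_ctc`` flag and a comma-joined
    ``positive_markers`` string.  A cell is a CTC iff at least one marker
    count reaches its cut-off; raising any count can only add markers.
    """
    unknown = set(cutoffs) - set(MARKERS)
    if unknown:
        raise ValueError(f"cut-offs given for unknown markers: {sorted(unknown)}")
    for marker, cut in cutoffs.items():
        if cut < 1:
            raise ValueError(f"cut-off for {marker} must be >= 1, got {cut}")
    _require_marker_columns(cells)
    out = cells.copy()
    pos_cols = []
    for marker in MARKERS:
        col = f"pos_{MARKER_COLUMNS[marker]}"
        cut = cutoffs.get(marker)
        out[col] = (cells[MARKER_COLUMNS[marker]] >= cut) if cut is not None else False
        pos_cols.append(col)
    out["is_ctc"] = out[pos_cols].any(axis=1)
    marker_arr = np.array(MARKERS, dtype=object)
    out["positive_markers"] = [
        ",".join(marker_arr[row]) for row in out[pos_cols].to_numpy(dtype=bool)
    ]
    return out


@dataclass
class PatientCtcSummary:
    """Per-patient roll-up of CTC calls."""

    patient_id: str
    n_ctcs: int
    marker_positive: dict[str, bool]
    max_rcp: dict[str, int]  # max count per marker among this patient's CTCs
    heterogeneous: bool
    extra: dict = field(default_factory=dict)

    @property
    def any_positive(self) -> bool:
        return self.n_ctcs > 0


def summarize_patient(
    calls: pd.DataFrame, patient_id: str, het_fold: float = 2.0
) -> PatientCtcSummary:
    """Summarize one patient's CTC calls, including intrapatient heterogeneity.

    A patient is scored heterogeneous when there are at least two CTCs and
    either the positive-marker sets of two CTCs differ, or some marker shared
    by two or more CTCs spans more than ``het_fold`` between its lowest and
    highest count.
    """
    if het_fold <= 0:
        raise ValueError("het_fold must be positive")
    ctcs = calls[calls["is_ctc"]] if len(calls) else calls
    n_ctcs = int(len(ctcs))
    marker_positive, max_rcp = {}, {}
    for marker in MARKERS:
        col = MARKER_COLUMNS[marker]
        pos = ctcs[f"pos_{col}"] if n_ctcs else pd.Series(dtype=bool)
        marker_positive[marker] = bool(pos.any()) if n_ctcs else False
        max_rcp[marker] = int(ctcs.loc[pos, col].max()) if marker_positive[marker] else 0

    heterogeneous = False
    if n_ctcs >= 2:
        marker_sets = set(map(tuple, ctcs[[f"pos_{c}" for c in MARKER_COLUMNS.values()]].to_numpy()))
        if len(marker_sets) > 1:
            heterogeneous = True
        else:
            for marker in MARKERS:
                col = MARKER_COLUMNS[marker]
                shared = ctcs.loc[ctcs[f"pos_{col}"], col]
                if len(shared) >= 2 and shared.max() > het_fold * shared.min():
                    heterogeneous = True
                    break
    return PatientCtcSummary(str(patient_id), n_ctcs, marker_positive, max_rcp, heterogeneous)


def summarize_distribution(cells: pd.DataFrame) -> pd.DataFrame:
    """Occupancy table over {0,1,2,3,>3} RCPs/cell per marker, with quartiles.

    Percentages carry two decimals (half-up).  Median and quartiles are linear
    interpolation quantiles of the raw per-cell counts; data binned at ">3"
    should be encoded at a representative count (4) by the caller.
    Requires full cell totals — tables of positive-only cells (no totals
    recorded) cannot be summarized this way.
    """
    if len(cells) == 0:
        raise ValueError("cannot summarize an empty cell table")
    _require_marker_columns(cells)
    n = len(cells)
    rows = []
    for marker in MARKERS:
        counts = cells[MARKER_COLUMNS[marker]].to_numpy()
        bin_n = [
            int((counts == 0).sum()),
            int((counts == 1).sum()),
            int((counts == 2).sum()),
            int((counts == 3).sum()),
            int((counts > 3).sum()),
        ]
        q1, med, q3 = np.percentile(counts, [25, 50, 75])
        for label, k in zip(_BIN_LABELS, bin_n):
            rows.append(
                {
                    "marker": marker,
                    "bin": label,
                    "n_cells": k,
                    "pct": round_half_up(100.0 * k / n, 2),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows)


def cohort_positivity(summaries: list[PatientCtcSummary]) -> dict:
    """Fraction of patients CTC-positive overall and per marker (integer percent)."""
    n = len(summaries)
    if n == 0:
        raise ValueError("no patient summaries")
    out = {
        "n_patients": n,
        "ctc_positive": sum(s.any_positive for s in summaries),
        "ctc_positive_pct": percent(sum(s.any_positive for s in summaries), n),
    }
    for marker in MARKERS:
        k = sum(s.marker_positive[marker] for s in summaries)
        out[f"{marker}_positive"] = k
        out[f"{marker}_positive_pct"] = percent(k, n)
    return out
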
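"""Published background RCP distributions for the in situ padlock-probe assay.

These are the per-cell rolling-circle-product (RCP) count occupancies reported
for the assay's control material: four healthy donors sampled in vivo on
CellCollector wires (only positive cells were counted; total cell numbers were
not recorded on the wires), two healthy-donor PBMC preparations on glass
slides, and the PC-3 (negative) and VCaP (positive) prostate-cancer cell
lines.  They are the inputs from which the CTC-calling cut-offs are derived
and against which distribution summaries are checked.

Occupancies map an RCP count per cell to the number of cells showing that
count.  Counts above three were reported as a single ">3" bin; it is encoded
here at the representative value 4, which is how medians/quartiles over the
binned data are computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MARKERS = ("KLK3", "AR-V7", "AR-FL")

#: cells table column per marker
MARKER_COLUMNS = {"KLK3": "klk3_rcp", "AR-V7": "arv7_rcp", "AR-FL": "arfl_rcp"}

#: CellCollector healthy controls 1-4: only positive cells, no totals.
#: marker -> per-control list of occupancies {rcp_count: n_cells}
COLLECTOR_CONTROL_POSITIVES = {
    "KLK3": [{}, {}, {}, {}],
    "AR-V7": [{1: 5}, {1: 9}, {1: 6}, {1: 6}],
    "AR-FL": [{1: 6}, {1: 4, 2: 1}, {1: 1}, {1: 3}],
}

#: Slide-based samples with full totals: sample -> (total cells, marker -> occupancy)
SLIDE_SAMPLES = {
    "PBMC_Ctrl5": (
        33855,
        {
            "KLK3": {0: 33855},
            "AR-V7": {0: 33593, 1: 262},
            "AR-FL": {0: 33486, 1: 360, 2: 9},
        },
    ),
    "PBMC_Ctrl6": (
        34544,
        {
            "KLK3": {0: 34544},
            "AR-V7": {0: 34298, 1: 246},
            "AR-FL": {0: 34213, 1: 327, 2: 4},
        },
    ),
    "PC3": (
        4573,
        {
            "KLK3": {0: 4573},
            "AR-V7": {0: 4511, 1: 62},
            "AR-FL": {0: 4502, 1: 70, 2: 1},
        },
    ),
    "VCaP": (
        2200,
        {
            "KLK3": {0: 2181, 1: 18, 2: 1},
            "AR-V7": {0: 411, 1: 451, 2: 423, 3: 296, 4: 619},
            "AR-FL": {0: 51, 1: 58, 2: 79, 3: 121, 4: 1891},
        },
    ),
}

#: Healthy-control sample names (the six used for cut-off derivation).
CONTROL_SAMPLES = (
    "Collector_Ctrl1",
    "Collector_Ctrl2",
    "Collector_Ctrl3",
    "Collector_Ctrl4",
    "PBMC_Ctrl5",
    "PBMC_Ctrl6",
)


def cells_from_occupancy(
    sample_id: str,
    occupancy: dict[str, dict[int, int]],
    total: int | None,
    source: str = "slide",
) -> pd.DataFrame:
    """Expand per-marker occupancies into a per-cell RCP count table.

    Marker counts are assigned to cells independently (high counts first), so
    per-marker marginals match the occupancy exactly; the joint structure
    across markers is not recorded in the published tables and does not affect
    per-marker maxima or distribution summaries.

    With ``total=None`` (CellCollector material) only the positive cells are
    emitted, one cell per positive count.
    """
    if total is None:
        rows = []
        i = 0
        for marker, occ in occupancy.items():
            col = MARKER_COLUMNS[marker]
            for count, n in sorted(occ.items(), reverse=True):
                if count == 0:
                    continue
                for _ in range(n):
                    row = {c: 0 for c in MARKER_COLUMNS.values()}
                    row.update(sample_id=sample_id, cell_id=f"{sample_id}_c{i}", source=source)
                    row[col] = count
                    rows.append(row)
                    i += 1
        cols = ["sample_id", "cell_id", "source", *MARKER_COLUMNS.values()]
        return pd.DataFrame(rows, columns=cols)

    data = {
        "sample_id": sample_id,
        "cell_id": [f"{sample_id}_c{i}" for i in range(total)],
        "source": source,
    }
    for marker in MARKERS:
        occ = occupancy.get(marker, {0: total})
        if sum(occ.values()) != total:
            raise ValueError(
                f"{sample_id}/{marker}: occupancy sums to {sum(occ.values())}, expected {total}"
            )
        arr = np.zeros(total, dtype=np.int64)
        pos = 0
        for count, n in sorted(occ.items(), reverse=True):
            arr[pos : pos + n] = count
            pos += n
        data[MARKER_COLUMNS[marker]] = arr
    return pd.DataFrame(data)


def control_cells() -> pd.DataFrame:
    """Cell table for all six healthy-control samples (cut-off derivation input)."""
    frames = []
    for i in range(4):
        occ = {m: COLLECTOR_CONTROL_POSITIVES[m][i] for m in MARKERS}
        frames.append(cells_from_occupancy(f"Collector_Ctrl{i + 1}", occ, None, source="collector"))
    for name in ("PBMC_Ctrl5", "PBMC_Ctrl6"):
        total, occ = SLIDE_SAMPLES[name]
        frames.append(cells_from_occupancy(name, occ, total))
    return pd.concat(frames, ignore_index=True)


def slide_sample_cells(name: str) -> pd.DataFrame:
    """Cell table for one slide-based sample ('PBMC_Ctrl5', 'PBMC_Ctrl6', 'PC3', 'VCaP')."""
    total, occ = SLIDE_SAMPLES[name]
    return cells_from_occupancy(name, occ, total)
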
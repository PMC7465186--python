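import numpy as np
import pandas as pd
import pytest

from liquidmix.simulate import SimConfig


@pytest.fixture
def fast_sim() -> SimConfig:
    """Scaled-down cohort: full structure, seconds to generate."""
    return SimConfig(
        seed=7,
        n_control_samples=2,
        n_control_cells=3_000,
        n_patients=6,
        n_background_cells_patient=300,
        n_controls_qpcr=8,
        n_patients_qpcr=8,
        genome=(("chr1", 10_000_000), ("chr2", 10_000_000), ("chrX", 8_000_000)),
        depth=120.0,
        n_par_mask_bins=3,
    )


def make_cells(rows: list[tuple[int, int, int]], sample_id: str = "S") -> pd.DataFrame:
    """Cell table from (klk3, arv7, arfl) tuples."""
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": [f"{sample_id}_c{i}" for i in range(len(rows))],
            "source": "slide",
            "klk3_rcp": [r[0] for r in rows],
            "arv7_rcp": [r[1] for r in rows],
            "arfl_rcp": [r[2] for r in rows],
        }
    )


def make_log2_bins(
    log2: np.ndarray, chrom: str = "chr1", bin_size: int = 50_000
) -> pd.DataFrame:
    """Bin table ready for segment_log2 (already normalized/corrected)."""
    log2 = np.asarray(log2, dtype=float)
    n = len(log2)
    starts = np.arange(n) * bin_size
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + bin_size,
            "gc": 0.45,
            "count": 100,
            "masked": False,
            "ratio": 2.0**log2,
            "ratio_gc": 2.0**log2,
            "log2_ratio": log2,
        }
    )


def make_segments(rows: list[tuple[str, int, int, float]]) -> pd.DataFrame:
    """Segment table from (chrom, start, end, log2) tuples."""
    return pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "start": [r[1] for r in rows],
            "end": [r[2] for r in rows],
            "n_bins": [(r[2] - r[1]) // 50_000 for r in rows],
            "log2_ratio": [r[3] for r in rows],
        }
    )


def brute_force_segmentation(
    x: np.ndarray, penalty: float, min_size: int = 3
) -> tuple[int, ...]:
    """Independent oracle: enumerate every admissible segmentation and return
    the breakpoints minimizing total SSE + penalty*var(x) per breakpoint."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    beta = penalty * float(np.var(x))
    cum = np.concatenate([[0.0], np.cumsum(x)])
    cum2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(a: int, b: int) -> float:
        s = cum[b] - cum[a]
        return (cum2[b] - cum2[a]) - s * s / (b - a)

    best_cost, best_breaks = np.inf, ()

    def recurse(start: int, cost: float, breaks: tuple[int, ...]) -> None:
        nonlocal best_cost, best_breaks
        for end in range(start + min_size, n + 1):
            if 0 < n - end < min_size:
                continue
            c = cost + sse(start, end) + (beta if start > 0 else 0.0)
            if end == n:
                if c < best_cost:
                    best_cost, best_breaks = c, breaks
            else:
                recurse(end, c, breaks + (end,))

    if n < min_size:
        return ()
    recurse(0, 0.0, ())
    return best_breaks
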
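"""Plasma shallow-WGS copy-number analysis and focal-event calling.

Fragment counts in 50 kb genomic bins are depth-normalized (autosomal mean
ratio = 1), GC-corrected by dividing out a LOWESS fit of ratio vs GC, and
log2-transformed.  Per-chromosome log2 ratios are segmented by exact
penalized least-squares segmentation.  Segments become focal events
only when all six filters hold:

1. segment shorter than 20 Mb;
2. |log2| above 0.2 (gain direction for amplifications, loss for deletions);
3. the segment contains at least one but at most 100 genes;
4. the segment's log2 stands out from the length-weighted mean of the
   segments in the 20 Mb flanks on both sides by ≥ 0.2 if it contains a
   known tumor driver gene, ≥ 0.58 otherwise (same sign as the event);
5. segmental duplications cover ≤ 50% of the segment;
6. known germline CNV entries cover less than a configurable fraction
   (default 50%) of the segment.

A deliberately naive tumor-fraction surrogate inverts the most aberrant
broad autosomal segment under a clonal single-copy-change assumption; it is
labelled as such everywhere and is not a probabilistic tumor-fraction model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .simulate import SEX_CHROMS

__all__ = [
    "FocalParams",
    "bin_fragments",
    "read_fragments_sam",
    "read_bins",
    "read_bed",
    "normalize_depth",
    "gc_correct",
    "segment_log2",
    "weighted_flank_mean",
    "call_focal_events",
    "call_ar_amplification",
    "estimate_tumor_fraction_naive",
]


@dataclass
class FocalParams:
    """Thresholds of the six-criterion focal caller (units: bp, log2, fractions)."""

    max_length: float = 20e6
    min_log2: float = 0.2
    min_genes: int = 1
    max_genes: int = 100
    driver_contrast: float = 0.2
    nondriver_contrast: float = 0.58
    flank_window: float = 20e6
    max_segdup_frac: float = 0.5
    max_known_cnv_frac: float = 0.5


# ---------------------------------------------------------------------------
# binning and I/O

def bin_fragments(fragments, model_bins: pd.DataFrame) -> pd.DataFrame:
    """Count fragments into the model's bins by fragment start coordinate.

    ``fragments`` is an iterable of (chrom, start) or a DataFrame with those
    columns.  Bins are 0-based half-open; a fragment starting exactly on a
    boundary belongs to the downstream bin.  Fragments on chromosomes absent
    from the model are skipped (tallied in the ``n_skipped`` attribute of the
    returned frame's ``attrs``).
    """
    if isinstance(fragments, pd.DataFrame):
        frag_iter = fragments[["chrom", "start"]].itertuples(index=False)
    else:
        frag_iter = fragments
    out = model_bins.copy()
    out["count"] = 0
    index = {}
    for chrom, sub in out.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        index[chrom] = (starts, sub["end"].to_numpy(), sub.index.to_numpy())
    counts = np.zeros(len(out), dtype=np.int64)
    n_skipped = 0
    for chrom, start in frag_iter:
        entry = index.get(chrom)
        if entry is None:
            n_skipped += 1
            continue
        starts, ends, idx = entry
        j = np.searchsorted(starts, start, side="right") - 1
        if j < 0 or start >= ends[j]:
            n_skipped += 1
            continue
        counts[out.index.get_loc(idx[j])] += 1
    out["count"] = counts
    out.attrs["n_skipped"] = n_skipped
    if n_skipped:
        warnings.warn(f"{n_skipped} fragments fell outside the binned genome", stacklevel=2)
    return out


def read_fragments_sam(path: str | Path):
    """Yield (chrom, start) for mapped primary alignments in a SAM/BAM file."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            yield read.reference_name, read.reference_start


def read_bins(path: str | Path) -> pd.DataFrame:
    """Read a bins.tsv table (chrom, start, end, gc, count, masked)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gc", "count", "masked"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bins table lacks columns: {sorted(missing)}")
    df["masked"] = df["masked"].astype(bool)
    return df


def read_bed(path: str | Path, with_name: bool = False) -> pd.DataFrame:
    """Read a BED3(+name+score) file; score 1 in gene BEDs marks driver genes."""
    names = ["chrom", "start", "end", "name", "score"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    if with_name:
        if "name" not in df.columns:
            raise ValueError(f"{path}: gene BED requires a name column")
        df["driver"] = df["score"].astype(int).astype(bool) if "score" in df.columns else False
    return df


# ---------------------------------------------------------------------------
# normalization

def _is_autosome(chrom: pd.Series) -> pd.Series:
    return ~chrom.isin(SEX_CHROMS)


def normalize_depth(bins: pd.DataFrame) -> pd.DataFrame:
    """Depth-normalize: ratio = count / mean(count over unmasked autosomal bins)."""
    use = _is_autosome(bins["chrom"]) & ~bins["masked"]
    if not use.any():
        raise ValueError("no unmasked autosomal bins")
    mean = bins.loc[use, "count"].mean()
    if mean <= 0:
        raise ValueError("all-zero bin counts; cannot normalize")
    out = bins.copy()
    out["ratio"] = out["count"] / mean
    return out


def gc_correct(
    bins: pd.DataFrame,
    span: float = 0.3,
    iterations: int = 2,
    floor_log2: float = -4.0,
) -> pd.DataFrame:
    """Divide out a LOWESS fit of ratio vs GC; add corrected ratio and log2.

    The curve is fitted on unmasked autosomal bins (robustified,
    ``iterations`` reweighting passes) and evaluated at every bin's GC by
    interpolation.  Zero-count bins are assigned ``floor_log2`` instead of
    −inf so segmentation stays finite.
    """
    if "ratio" not in bins.columns:
        raise ValueError("run normalize_depth first")
    use = _is_autosome(bins["chrom"]) & ~bins["masked"]
    if use.sum() < 30:
        raise ValueError("need at least 30 unmasked autosomal bins for GC correction")
    gc = bins.loc[use, "gc"].to_numpy()
    ratio = bins.loc[use, "ratio"].to_numpy()
    out = bins.copy()
    if np.ptp(gc) < 1e-6:
        warnings.warn("degenerate GC range; GC correction skipped", stacklevel=2)
        out["ratio_gc"] = out["ratio"]
    else:
        fit = lowess(ratio, gc, frac=span, it=iterations, return_sorted=True)
        fitted = np.interp(out["gc"].to_numpy(), fit[:, 0], fit[:, 1])
        fitted = np.maximum(fitted, 1e-3)
        out["ratio_gc"] = out["ratio"] / fitted
    with np.errstate(divide="ignore"):
        log2 = np.log2(out["ratio_gc"].to_numpy())
    out["log2_ratio"] = np.where(out["count"] > 0, log2, floor_log2)
    return out


# ---------------------------------------------------------------------------
# segmentation

def _segment_indices(x: np.ndarray, penalty: float, min_size: int) -> list[int]:
    """Interior breakpoint indices of the optimal penalized segmentation.

    Minimizes total within-segment squared error plus a cost of
    ``penalty`` × variance of the chromosome's bin values per breakpoint,
    over all partitions with segments of at least ``min_size`` bins
    (optimal-partitioning dynamic program, exact).  Adding a breakpoint
    therefore pays off only when it reduces the squared error by more than
    the penalty, but — unlike greedy binary splitting — short interior
    events are found because both of their flanking breakpoints are placed
    jointly.
    """
    n = len(x)
    if n < 2 * min_size:
        return []
    beta = penalty * float(np.var(x))
    if beta <= 0:  # constant signal: nothing to split
        return []
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cost = np.full(n + 1, np.inf)
    cost[0] = -beta
    back = np.zeros(n + 1, dtype=np.int64)
    for j in range(min_size, n + 1):
        i = np.arange(0, j - min_size + 1)
        s = prefix[j] - prefix[i]
        s2 = prefix2[j] - prefix2[i]
        seg_sse = s2 - s * s / (j - i)
        total = cost[i] + beta + seg_sse
        k = int(np.argmin(total))
        cost[j], back[j] = total[k], i[k]
    breaks = []
    j = n
    while j > 0:
        i = int(back[j])
        if i > 0:
            breaks.append(i)
        j = i
    return sorted(breaks)


def segment_log2(bins: pd.DataFrame, penalty: float = 10.0, min_size: int = 3) -> pd.DataFrame:
    """Piecewise-constant segmentation of log2 ratios, per chromosome.

    Exact penalized least-squares segmentation: breakpoints minimize total
    within-segment SSE + penalty × var(chromosome bin log2) per breakpoint.
    Masked bins are excluded.  Returns segments (chrom, start, end, n_bins,
    log2_ratio) ordered and covering all unmasked bins.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    if "log2_ratio" not in bins.columns:
        raise ValueError("run gc_correct first")
    rows = []
    for chrom, sub in bins[~bins["masked"]].groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        x = sub["log2_ratio"].to_numpy(dtype=float)
        if len(x) == 0:
            continue
        breaks = [0, *_segment_indices(x, penalty, min_size), len(x)]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for a, b in zip(breaks[:-1], breaks[1:]):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[a]),
                    "end": int(ends[b - 1]),
                    "n_bins": b - a,
                    "log2_ratio": float(x[a:b].mean()),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "log2_ratio"])


# ---------------------------------------------------------------------------
# focal events

def _overlap_lengths(start: int, end: int, track: pd.DataFrame) -> np.ndarray:
    lo = np.maximum(track["start"].to_numpy(), start)
    hi = np.minimum(track["end"].to_numpy(), end)
    return np.maximum(hi - lo, 0)


def _union_coverage(start: int, end: int, track: pd.DataFrame) -> int:
    """Length of [start, end) covered by the union of track intervals."""
    ivs = sorted(
        (max(s, start), min(e, end))
        for s, e in zip(track["start"], track["end"])
        if min(e, end) > max(s, start)
    )
    covered, cur_s, cur_e = 0, None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def weighted_flank_mean(
    segments: pd.DataFrame, target_index: int, window: float = 20e6
) -> float | None:
    """Length-weighted mean log2 of segment material in the two 20 Mb flanks.

    Both flanks are pooled into a single weighted average; flanks are
    truncated at chromosome ends.  Returns None when no flank material
    exists (the neighbor-contrast criterion then auto-fails).
    """
    target = segments.loc[target_index]
    same = segments[(segments["chrom"] == target["chrom"]) & (segments.index != target_index)]
    if len(same) == 0:
        return None
    windows = [
        (target["start"] - window, target["start"]),
        (target["end"], target["end"] + window),
    ]
    weights, values = [], []
    for ws, we in windows:
        w = _overlap_lengths(int(ws), int(we), same)
        weights.append(w)
        values.append(same["log2_ratio"].to_numpy())
    w = np.concatenate(weights)
    v = np.concatenate(values)
    if w.sum() == 0:
        return None
    return float(np.average(v, weights=w))


def call_focal_events(
    segments: pd.DataFrame,
    genes: pd.DataFrame,
    segdups: pd.DataFrame,
    known_cnvs: pd.DataFrame,
    params: FocalParams | None = None,
) -> pd.DataFrame:
    """Apply the six focal-event criteria to every segment.

    Returns one row per segment with the per-criterion pass flags
    (size, magnitude, gene_count, neighbor_contrast, segdup, known_cnv),
    the tentative event class, the overlapped gene list, and ``is_event``
    (all six criteria pass).
    """
    for name, track in (("genes", genes), ("segdups", segdups), ("known_cnvs", known_cnvs)):
        if track is None:
            raise ValueError(f"missing annotation track: {name}")
    if params is None:
        params = FocalParams()
    rows = []
    for idx, seg in segments.iterrows():
        length = seg["end"] - seg["start"]
        log2 = seg["log2_ratio"]
        event_class = "amplification" if log2 > 0 else "deletion"
        sign = 1.0 if event_class == "amplification" else -1.0

        g = genes[genes["chrom"] == seg["chrom"]]
        overlap = _overlap_lengths(seg["start"], seg["end"], g) > 0
        gene_names = g.loc[overlap, "name"].tolist()
        contains_driver = bool(g.loc[overlap, "driver"].any()) if "driver" in g.columns else False

        flank = weighted_flank_mean(segments, idx, params.flank_window)
        margin = params.driver_contrast if contains_driver else params.nondriver_contrast
        contrast_ok = flank is not None and sign * (log2 - flank) >= margin

        sd = segdups[segdups["chrom"] == seg["chrom"]]
        kc = known_cnvs[known_cnvs["chrom"] == seg["chrom"]]
        segdup_frac = _union_coverage(seg["start"], seg["end"], sd) / length
        cnv_frac = _union_coverage(seg["start"], seg["end"], kc) / length

        crit = {
            "size": length < params.max_length,
            "magnitude": sign * log2 > params.min_log2,
            "gene_count": params.min_genes <= len(gene_names) <= params.max_genes,
            "neighbor_contrast": contrast_ok,
            "segdup": segdup_frac <= params.max_segdup_frac,
            "known_cnv": cnv_frac < params.max_known_cnv_frac,
        }
        rows.append(
            {
                "chrom": seg["chrom"],
                "start": seg["start"],
                "end": seg["end"],
                "n_bins": seg.get("n_bins", np.nan),
                "log2_ratio": log2,
                "class": event_class,
                "contains_driver": contains_driver,
                "genes": ",".join(gene_names),
                **{f"pass_{k}": v for k, v in crit.items()},
                "is_event": all(crit.values()),
            }
        )
    return pd.DataFrame(rows)


def recenter_haploid_x(segments: pd.DataFrame, shift: float = 1.0) -> pd.DataFrame:
    """Recenter chrX segment log2 ratios for a male (single-X) genome.

    With one X copy the neutral X log2 sits near −1 relative to autosomes;
    adding +1 puts X events on the same scale as the autosomal thresholds.
    """
    out = segments.copy()
    on_x = out["chrom"].isin(SEX_CHROMS)
    out.loc[on_x, "log2_ratio"] = out.loc[on_x, "log2_ratio"] + shift
    return out


def call_ar_amplification(events: pd.DataFrame, gene_name: str = "AR") -> bool:
    """True iff some called amplification event contains the named gene."""
    if len(events) == 0:
        return False
    amp = events[(events["is_event"]) & (events["class"] == "amplification")]
    return bool(
        amp["genes"].apply(lambda s: gene_name in s.split(",") if s else False).any()
    )


def cnv_call_single_files(
    bins_path,
    genes_path,
    segdups_path,
    known_cnv_path,
    outdir,
    penalty: float = 10.0,
    lowess_span: float = 0.3,
    lowess_iterations: int = 2,
    min_segment_bins: int = 3,
    haploid_x: bool = False,
    params: "FocalParams | None" = None,
) -> dict:
    """File-level CNV chain for one sample; writes tables and summary.json."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bins = read_bins(bins_path)
    genes = read_bed(genes_path, with_name=True)
    segdups = read_bed(segdups_path)
    known_cnvs = read_bed(known_cnv_path)
    normalized = gc_correct(normalize_depth(bins), span=lowess_span, iterations=lowess_iterations)
    segments = segment_log2(normalized, penalty=penalty, min_size=min_segment_bins)
    if haploid_x:
        segments = recenter_haploid_x(segments)
    events = call_focal_events(segments, genes, segdups, known_cnvs, params)
    tf = estimate_tumor_fraction_naive(segments)
    normalized.to_csv(outdir / "normalized_bins.tsv", sep="\t", index=False)
    segments.to_csv(outdir / "segments.tsv", sep="\t", index=False)
    events.to_csv(outdir / "focal_events.tsv", sep="\t", index=False)
    summary = {
        "ar_amplification": bool(call_ar_amplification(events)),
        "tumor_fraction_naive": tf.tf,
        "quantifiable": tf.quantifiable,
        "estimator": tf.label,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


@dataclass
class TumorFractionEstimate:
    """Naive surrogate tumor-fraction estimate (single-copy-change inversion)."""

    tf: float
    quantifiable: bool
    label: str = "naive surrogate"


def estimate_tumor_fraction_naive(
    segments: pd.DataFrame,
    min_span: float = 2e6,
    quantifiable_threshold: float = 0.03,
) -> TumorFractionEstimate:
    """Invert the most aberrant broad autosomal segment assuming one clonal
    single-copy gain or loss: tf = 2·|2^L − 1|, clipped to [0, 1].

    This is a naive surrogate for probabilistic tumor-fraction models: it
    ignores ploidy, subclonality and multi-copy events, and is labelled as
    such in all outputs.
    """
    auto = segments[_is_autosome(segments["chrom"])]
    if len(auto) == 0:
        raise ValueError("no autosomal segments")
    broad = auto[(auto["end"] - auto["start"]) >= min_span]
    if len(broad) == 0:
        broad = auto
    log2 = broad.loc[broad["log2_ratio"].abs().idxmax(), "log2_ratio"]
    tf = float(np.clip(2.0 * abs(2.0 ** log2 - 1.0), 0.0, 1.0))
    return TumorFractionEstimate(tf=tf, quantifiable=tf >= quantifiable_threshold)
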
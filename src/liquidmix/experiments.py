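"""Seeded simulation experiments quantifying pipeline performance.

These drive the replicate studies reported by the analysis scripts: focal
amplification spike-recovery and false-positive rates, and recovery of the
simulated tumor fraction by the naive surrogate estimator.  All replication
is controlled by a single base seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cnv import (
    call_ar_amplification,
    call_focal_events,
    estimate_tumor_fraction_naive,
    gc_correct,
    normalize_depth,
    segment_log2,
)
from .simulate import SimConfig, build_genome_model, gen_plasma_counts

__all__ = ["spike_recovery", "tf_recovery"]


def _rep_seed(seed: int, rep: int) -> int:
    return (int(seed) * 10_007 + rep) % (2**31 - 1)


def _cnv_chain(config: SimConfig):
    model = build_genome_model(config)
    bins = gen_plasma_counts(model, config)
    segments = segment_log2(gc_correct(normalize_depth(bins)))
    events = call_focal_events(segments, model.genes, model.segdups, model.known_cnvs)
    return segments, events


def spike_recovery(
    seed: int, n_replicates: int = 100, tumor_fraction: float = 0.25
) -> dict:
    """Fraction of seeded replicates in which the focal AR amplification is called.

    Each replicate simulates one plasma sample carrying the default CN-4,
    10-bin amplification at the AR locus blended at ``tumor_fraction``
    (``tumor_fraction=0`` measures the false-call rate on a flat genome).
    """
    n_called = 0
    for rep in range(n_replicates):
        config = SimConfig(seed=_rep_seed(seed, rep), tumor_fraction=tumor_fraction)
        _, events = _cnv_chain(config)
        if tumor_fraction > 0:
            n_called += bool(call_ar_amplification(events))
        else:
            n_called += bool(
                (events["is_event"] & (events["class"] == "amplification")).any()
            )
    return {
        "tumor_fraction": tumor_fraction,
        "n_called": n_called,
        "n_replicates": n_replicates,
        "rate": n_called / n_replicates,
    }


def tf_recovery(
    seed: int,
    tumor_fractions: tuple[float, ...] = (0.1, 0.2, 0.4),
    n_replicates: int = 5,
) -> dict[float, float]:
    """Mean naive tumor-fraction estimate under a clonal single-copy gain.

    The gain spans 5 Mb (100 bins) at copy number 3 on chr1, so the blended
    segment sits at log2(1 + tf/2) and the surrogate's inversion
    tf = 2·|2^L − 1| should recover the simulated value.
    """
    out = {}
    for tf in tumor_fractions:
        estimates = []
        for rep in range(n_replicates):
            config = SimConfig(
                seed=_rep_seed(seed, 1_000 + rep),
                tumor_fraction=tf,
                amp_locus=("chr1", 2_000_000, 7_000_000, 3.0),
            )
            segments, _ = _cnv_chain(config)
            estimates.append(estimate_tumor_fraction_naive(segments).tf)
        out[tf] = float(np.mean(estimates))
    return out
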
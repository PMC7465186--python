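"""Copy-number chain: binning, normalization, GC correction, segmentation,
flank contrast, the six-criterion focal caller, and the naive tumor-fraction
surrogate."""

import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_segmentation, make_log2_bins, make_segments
from liquidmix.cnv import (
    FocalParams,
    bin_fragments,
    call_ar_amplification,
    call_focal_events,
    estimate_tumor_fraction_naive,
    gc_correct,
    normalize_depth,
    recenter_haploid_x,
    segment_log2,
    weighted_flank_mean,
)

MB = 1_000_000


def bins_from_counts(counts, chrom="chr1", gc=None, masked=None):
    n = len(counts)
    starts = np.arange(n) * 50_000
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + 50_000,
            "gc": 0.45 if gc is None else gc,
            "count": counts,
            "masked": False if masked is None else masked,
        }
    )


def empty_track():
    return pd.DataFrame(columns=["chrom", "start", "end"])


def gene_track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "driver"])


class TestBinFragments:
    def _model(self):
        return bins_from_counts([0, 0, 0]).drop(columns="count")

    def test_no_fragments_all_zero(self):
        out = bin_fragments([], self._model())
        assert (out["count"] == 0).all()

    def test_half_open_boundary(self):
        """A fragment starting exactly at 50,000 belongs to the second bin."""
        out = bin_fragments([("chr1", 50_000)], self._model())
        assert out["count"].tolist() == [0, 1, 0]

    def test_unknown_chromosome_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            out = bin_fragments([("chrZ", 10)], self._model())
        assert out.attrs["n_skipped"] == 1


class TestNormalizeDepth:
    def test_constant_counts_unit_ratio(self):
        out = normalize_depth(bins_from_counts([10] * 6))
        assert np.allclose(out["ratio"], 1.0)

    def test_worked_example_mean_twelve(self):
        out = normalize_depth(bins_from_counts([10, 10, 20, 10, 10]))
        assert np.allclose(out["ratio"], [10 / 12, 10 / 12, 20 / 12, 10 / 12, 10 / 12])
        assert out["ratio"].mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = normalize_depth(bins_from_counts([10, 10, 20, 10, 10]))
        b = normalize_depth(bins_from_counts([30, 30, 60, 30, 30]))
        assert np.allclose(a["ratio"], b["ratio"])

    def test_sex_chromosome_excluded_from_mean(self):
        bins = pd.concat(
            [bins_from_counts([10, 10]), bins_from_counts([40, 40], chrom="chrX")],
            ignore_index=True,
        )
        out = normalize_depth(bins)
        assert np.allclose(out.loc[out["chrom"] == "chr1", "ratio"], 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_depth(bins_from_counts([0, 0, 0]))


def bias(gc):
    return 1.0 + 0.3 - 0.3 * ((np.asarray(gc) - 0.45) / 0.2) ** 2


class TestGcCorrect:
    def _bins(self, ratio, gc):
        out = bins_from_counts(np.maximum((ratio * 100).astype(int), 1), gc=gc)
        out["ratio"] = ratio
        return out

    def test_null_bias_leaves_ratio_unchanged(self):
        rng = np.random.default_rng(2)
        gc = rng.uniform(0.32, 0.58, 400)
        ratio = np.ones(400)
        out = gc_correct(self._bins(ratio, gc))
        interior = (gc > 0.35) & (gc < 0.55)
        assert np.allclose(out.loc[interior, "ratio_gc"], 1.0, atol=0.02)

    def test_known_unimodal_bias_is_divided_out(self):
        rng = np.random.default_rng(3)
        gc = rng.uniform(0.32, 0.58, 600)
        out = gc_correct(self._bins(bias(gc), gc))
        lo, hi = np.quantile(gc, [0.1, 0.9])
        interior = (gc > lo) & (gc < hi)
        assert np.abs(out.loc[interior, "ratio_gc"] - 1.0).max() <= 0.02

    def test_copy_number_spike_survives_correction(self):
        rng = np.random.default_rng(4)
        gc = rng.uniform(0.32, 0.58, 300)
        ratio = bias(gc).copy()
        ratio[100:110] *= 1.5
        out = gc_correct(self._bins(ratio, gc))
        amp = out["ratio_gc"].to_numpy()[100:110].mean()
        flank = np.r_[out["ratio_gc"].to_numpy()[:100], out["ratio_gc"].to_numpy()[110:]].mean()
        assert amp / flank > 1.3

    def test_degenerate_gc_skips_with_warning(self):
        ratio = np.ones(50)
        with pytest.warns(UserWarning, match="degenerate"):
            out = gc_correct(self._bins(ratio, np.full(50, 0.45)))
        assert np.allclose(out["ratio_gc"], out["ratio"])

    def test_zero_count_bins_get_floor_log2(self):
        b = bins_from_counts([10] * 40, gc=np.linspace(0.35, 0.55, 40))
        b.loc[0, "count"] = 0
        out = gc_correct(normalize_depth(b))
        assert out["log2_ratio"].iloc[0] == -4.0


class TestSegmentation:
    def test_constant_input_single_segment(self):
        seg = segment_log2(make_log2_bins(np.zeros(50)))
        assert len(seg) == 1 and seg["n_bins"].iloc[0] == 50

    def test_step_recovered_with_boundary_within_one_bin(self):
        rng = np.random.default_rng(17)
        x = np.r_[np.zeros(60), np.full(20, 0.8)] + rng.normal(0, 0.05, 80)
        seg = segment_log2(make_log2_bins(x))
        assert len(seg) == 2
        assert abs(seg["start"].iloc[1] // 50_000 - 60) <= 1
        assert seg["log2_ratio"].iloc[1] == pytest.approx(0.8, abs=0.05)

    def test_interior_focal_event_isolated(self):
        rng = np.random.default_rng(23)
        x = rng.normal(0, 0.1, 200)
        x[90:100] += 0.6
        seg = segment_log2(make_log2_bins(x))
        assert len(seg) == 3
        assert seg["n_bins"].iloc[1] == 10

    def test_matches_exhaustive_oracle_on_small_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            n = int(rng.integers(6, 31))
            x = rng.normal(0, 0.1, n)
            for _ in range(int(rng.integers(0, 3))):
                at = int(rng.integers(0, n))
                x[at:] += rng.uniform(0.3, 1.0) * rng.choice([-1, 1])
            seg = segment_log2(make_log2_bins(x))
            impl = tuple(seg["start"].to_numpy()[1:] // 50_000)
            assert impl == brute_force_segmentation(x, penalty=10.0)

    def test_masked_bins_excluded(self):
        bins = make_log2_bins(np.zeros(30))
        bins.loc[:2, "masked"] = True
        seg = segment_log2(bins)
        assert seg["start"].iloc[0] == 3 * 50_000

    def test_nonpositive_penalty_rejected(self):
        with pytest.raises(ValueError):
            segment_log2(make_log2_bins(np.zeros(10)), penalty=0.0)


class TestFlankMean:
    def test_uniform_flanks(self):
        segs = make_segments(
            [("chr1", 0, 30 * MB, 0.0), ("chr1", 30 * MB, 31 * MB, 0.5), ("chr1", 31 * MB, 60 * MB, 0.0)]
        )
        assert weighted_flank_mean(segs, 1) == pytest.approx(0.0)

    def test_length_weighted_average_of_both_sides(self):
        segs = make_segments(
            [("chr1", 10 * MB, 30 * MB, 0.2), ("chr1", 30 * MB, 31 * MB, 0.5), ("chr1", 31 * MB, 51 * MB, 0.4)]
        )
        assert weighted_flank_mean(segs, 1) == pytest.approx(0.3)

    def test_truncation_at_chromosome_start(self):
        segs = make_segments([("chr1", 0, 1 * MB, 0.5), ("chr1", 1 * MB, 21 * MB, 0.1)])
        assert weighted_flank_mean(segs, 0) == pytest.approx(0.1)

    def test_no_flank_material_returns_none(self):
        segs = make_segments([("chr1", 0, 1 * MB, 0.5)])
        assert weighted_flank_mean(segs, 0) is None


def passing_scene():
    """A 1 Mb driver-containing amplification that satisfies all six criteria."""
    segments = make_segments(
        [("chr1", 0, 30 * MB, 0.0), ("chr1", 30 * MB, 31 * MB, 0.5), ("chr1", 31 * MB, 60 * MB, 0.0)]
    )
    genes = gene_track([("chr1", int(30.2 * MB), int(30.4 * MB), "DRV", True)])
    return segments, genes, empty_track(), empty_track()


class TestFocalCaller:
    def test_all_criteria_pass(self):
        events = call_focal_events(*passing_scene())
        target = events.iloc[1]
        assert target["is_event"] and target["class"] == "amplification"
        assert target["genes"] == "DRV" and target["contains_driver"]

    @pytest.mark.parametrize(
        "fault, expected_flag",
        [
            ("size", "pass_size"),
            ("magnitude", "pass_magnitude"),
            ("gene_count", "pass_gene_count"),
            ("contrast", "pass_neighbor_contrast"),
            ("segdup", "pass_segdup"),
            ("known_cnv", "pass_known_cnv"),
        ],
    )
    def test_single_fault_flips_exactly_one_criterion(self, fault, expected_flag):
        segments, genes, segdups, known = passing_scene()
        if fault == "size":  # 25 Mb segment
            segments = make_segments(
                [("chr1", 0, 30 * MB, 0.0), ("chr1", 30 * MB, 55 * MB, 0.5), ("chr1", 55 * MB, 85 * MB, 0.0)]
            )
            genes = gene_track([("chr1", int(30.2 * MB), int(30.4 * MB), "DRV", True)])
        elif fault == "magnitude":  # log2 at exactly 0.2: contrast (>=) holds, magnitude (>) fails
            segments.loc[1, "log2_ratio"] = 0.2
        elif fault == "gene_count":  # 102 genes overlap the segment
            extra = [
                ("chr1", 30 * MB + 5_000 * i, 30 * MB + 5_000 * i + 2_000, f"G{i}", False)
                for i in range(101)
            ]
            genes = pd.concat([genes, gene_track(extra)], ignore_index=True)
        elif fault == "contrast":  # no driver: required margin rises to 0.58 > 0.5
            genes.loc[0, "driver"] = False
        elif fault == "segdup":  # 60% of the segment is segmental duplication
            segdups = pd.DataFrame(
                [("chr1", 30 * MB, int(30.6 * MB))], columns=["chrom", "start", "end"]
            )
        elif fault == "known_cnv":
            known = pd.DataFrame(
                [("chr1", int(30.2 * MB), int(30.8 * MB))], columns=["chrom", "start", "end"]
            )
        events = call_focal_events(segments, genes, segdups, known)
        target = events.iloc[1]
        flags = {c: target[c] for c in events.columns if c.startswith("pass_")}
        assert not target["is_event"]
        assert flags.pop(expected_flag) == False  # noqa: E712
        assert all(flags.values()), f"unexpected extra faults: {flags}"

    def test_deletion_direction_mirrored(self):
        segments, genes, segdups, known = passing_scene()
        segments.loc[1, "log2_ratio"] = -0.5
        target = call_focal_events(segments, genes, segdups, known).iloc[1]
        assert target["is_event"] and target["class"] == "deletion"

    def test_missing_track_rejected(self):
        segments, genes, segdups, known = passing_scene()
        with pytest.raises(ValueError):
            call_focal_events(segments, genes, None, known)


class TestArCallAndTumorFraction:
    def test_ar_amplification_requires_amplified_ar(self):
        segments, genes, segdups, known = passing_scene()
        genes.loc[0, "name"] = "AR"
        events = call_focal_events(segments, genes, segdups, known)
        assert call_ar_amplification(events)
        # a deletion over AR is not an AR amplification
        segments.loc[1, "log2_ratio"] = -0.5
        events = call_focal_events(segments, genes, segdups, known)
        assert not call_ar_amplification(events)
        assert not call_ar_amplification(events.iloc[0:0])

    def test_flat_genome_zero_tf(self):
        segs = make_segments([("chr1", 0, 30 * MB, 0.0)])
        est = estimate_tumor_fraction_naive(segs)
        assert est.tf == 0.0 and not est.quantifiable

    def test_closed_form_inversion_single_copy_gain(self):
        """A clonal single-copy gain at tf=0.2 sits at ratio 1.1; the
        surrogate inverts log2(1.1) back to 0.2."""
        segs = make_segments([("chr1", 0, 30 * MB, np.log2(1.1)), ("chr1", 30 * MB, 60 * MB, 0.0)])
        est = estimate_tumor_fraction_naive(segs)
        assert est.tf == pytest.approx(0.2, abs=1e-9)
        assert est.quantifiable and est.label == "naive surrogate"

    def test_sex_chromosome_ignored(self):
        segs = make_segments([("chrX", 0, 30 * MB, 1.0), ("chr1", 0, 30 * MB, 0.0)])
        assert estimate_tumor_fraction_naive(segs).tf == 0.0

    def test_no_autosomes_rejected(self):
        with pytest.raises(ValueError):
            estimate_tumor_fraction_naive(make_segments([("chrX", 0, MB, 0.5)]))

    def test_haploid_x_recentering(self):
        segs = make_segments([("chrX", 0, MB, -1.0), ("chr1", 0, MB, 0.1)])
        out = recenter_haploid_x(segs)
        assert out["log2_ratio"].tolist() == [0.0, 0.1]
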
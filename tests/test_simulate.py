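"""Synthetic cohort generator: determinism, calibration, degenerate configs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from liquidmix.simulate import (
    SimConfig,
    build_genome_model,
    gen_cell_table,
    gen_cq_table,
    gen_ledger_fixture,
    gen_plasma_counts,
)


class TestDeterminism:
    def test_identical_config_identical_outputs(self, fast_sim):
        model = build_genome_model(fast_sim)
        for gen in (
            lambda c: gen_cell_table(c, "control"),
            lambda c: gen_cell_table(c, "patient"),
            gen_cq_table,
            lambda c: gen_plasma_counts(model, c),
            gen_ledger_fixture,
        ):
            pd.testing.assert_frame_equal(gen(fast_sim), gen(dataclasses.replace(fast_sim)))

    def test_different_seed_changes_output(self, fast_sim):
        other = dataclasses.replace(fast_sim, seed=fast_sim.seed + 1)
        a = gen_cell_table(fast_sim, "control")
        b = gen_cell_table(other, "control")
        assert not a.equals(b)


class TestCellTables:
    def test_background_frequency_matches_configured_rate(self, fast_sim):
        """AR-V7 one-RCP frequency within 3 binomial SDs of 0.77%."""
        cfg = dataclasses.replace(fast_sim, n_control_cells=33_855, n_control_samples=1)
        cells = gen_cell_table(cfg, "control")
        p = cfg.background_rcp_rate["AR-V7"][1]
        n = len(cells)
        k = int((cells["arv7_rcp"] == 1).sum())
        sd = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) <= 3 * sd  # expectation ~262 cells

    def test_degenerate_background_all_zero(self, fast_sim):
        rate = dict(fast_sim.background_rcp_rate, **{"AR-V7": (1.0, 0.0, 0.0, 0.0)})
        cfg = dataclasses.replace(fast_sim, background_rcp_rate=rate)
        assert (gen_cell_table(cfg, "control")["arv7_rcp"] == 0).all()

    def test_invalid_probability_vector_rejected(self, fast_sim):
        rate = dict(fast_sim.background_rcp_rate, **{"KLK3": (0.5, 0.4, 0.0, 0.0)})
        with pytest.raises(ValueError):
            gen_cell_table(dataclasses.replace(fast_sim, background_rcp_rate=rate), "control")

    def test_patient_tables_contain_tumor_cells(self, fast_sim):
        cfg = dataclasses.replace(fast_sim, ctc_prevalence=1.0)
        cells = gen_cell_table(cfg, "patient")
        # NB(mean 9) AR-FL tumor cells push counts far above the 0..3 background
        assert cells.groupby("sample_id")["arfl_rcp"].max().min() >= 3


class TestCqTables:
    def test_row_count_matches_config_arithmetic(self, fast_sim):
        df = gen_cq_table(fast_sim)
        n_samples = fast_sim.n_controls_qpcr + fast_sim.n_patients_qpcr
        assert len(df) == n_samples * 4 * fast_sim.n_replicates
        assert df["sample_id"].nunique() == n_samples

    def test_full_dropout_removes_every_cq(self, fast_sim):
        drop = {g: dict(d) for g, d in fast_sim.dropout_prob.items()}
        drop["AR-V7"] = {"control": 1.0, "patient": 1.0}
        df = gen_cq_table(dataclasses.replace(fast_sim, dropout_prob=drop))
        assert df.loc[df["gene"] == "AR-V7", "cq"].isna().all()

    def test_reference_gene_never_drops_out(self, fast_sim):
        df = gen_cq_table(fast_sim)
        assert df.loc[df["gene"] == "GUSB", "cq"].notna().all()

    def test_zero_sd_yields_exact_means(self, fast_sim):
        sds = {g: {"control": 0.0, "patient": 0.0} for g in fast_sim.cq_sds}
        drop = {g: {"control": 0.0, "patient": 0.0} for g in fast_sim.dropout_prob}
        df = gen_cq_table(dataclasses.replace(fast_sim, cq_sds=sds, dropout_prob=drop))
        sub = df[(df["gene"] == "KLK3") & (df["group"] == "control")]
        assert (sub["cq"] == fast_sim.cq_means["KLK3"]["control"]).all()

    def test_negative_sd_rejected(self, fast_sim):
        sds = {g: dict(d) for g, d in fast_sim.cq_sds.items()}
        sds["KLK3"]["control"] = -1.0
        with pytest.raises(ValueError):
            gen_cq_table(dataclasses.replace(fast_sim, cq_sds=sds))


class TestGenomeAndPlasma:
    def test_bins_tile_chromosomes_exactly(self, fast_sim):
        bins = build_genome_model(fast_sim).bins
        for chrom, length in fast_sim.genome:
            sub = bins[bins["chrom"] == chrom]
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == length
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()
            assert sub["gc"].between(0, 1).all()

    def test_null_genome_is_poisson_at_depth(self, fast_sim):
        cfg = dataclasses.replace(fast_sim, tumor_fraction=0.0, gc_bias_amplitude=0.0)
        bins = gen_plasma_counts(build_genome_model(cfg), cfg)
        mean = bins.loc[~bins["masked"], "count"].mean()
        n = (~bins["masked"]).sum()
        assert abs(mean - cfg.depth) <= 3 * np.sqrt(cfg.depth / n)

    def test_clonal_amplification_doubles_locus_expectation(self, fast_sim):
        """tf=1, CN=4: expected locus count is 2x depth (4/2)."""
        cfg = dataclasses.replace(
            fast_sim, tumor_fraction=1.0, gc_bias_amplitude=0.0, depth=2000.0
        )
        bins = gen_plasma_counts(build_genome_model(cfg), cfg)
        chrom, s, e, _ = cfg.amp_locus
        locus = (bins["chrom"] == chrom) & (bins["start"] >= s) & (bins["end"] <= e)
        ratio = bins.loc[locus, "count"].mean() / cfg.depth
        assert ratio == pytest.approx(2.0, abs=0.05)

    def test_blended_amplification_ratio(self, fast_sim):
        """tf=0.2, CN=4: locus/flank expectation ratio is (0.2*4+0.8*2)/2 = 1.2."""
        cfg = dataclasses.replace(
            fast_sim, tumor_fraction=0.2, gc_bias_amplitude=0.0, depth=5000.0
        )
        bins = gen_plasma_counts(build_genome_model(cfg), cfg)
        chrom, s, e, _ = cfg.amp_locus
        locus = (bins["chrom"] == chrom) & (bins["start"] >= s) & (bins["end"] <= e)
        flank = (bins["chrom"] == chrom) & ~locus & ~bins["masked"]
        ratio = bins.loc[locus, "count"].mean() / bins.loc[flank, "count"].mean()
        assert ratio == pytest.approx(1.2, abs=0.02)

    def test_par_bins_emitted_masked(self, fast_sim):
        bins = gen_plasma_counts(build_genome_model(fast_sim), fast_sim)
        masked = bins[bins["masked"]]
        assert len(masked) == fast_sim.n_par_mask_bins
        assert (masked["count"] >= 0).all()

    def test_nonpositive_depth_rejected(self, fast_sim):
        cfg = dataclasses.replace(fast_sim, depth=0.0)
        with pytest.raises(ValueError):
            gen_plasma_counts(build_genome_model(dataclasses.replace(cfg, depth=1.0)), cfg)

    def test_amp_locus_outside_genome_rejected(self, fast_sim):
        cfg = dataclasses.replace(fast_sim, amp_locus=("chr9", 0, 1000, 4.0))
        with pytest.raises(ValueError):
            build_genome_model(cfg)


class TestLedgerFixture:
    def test_exact_marginals(self, fast_sim):
        ledger = gen_ledger_fixture(fast_sim)
        for assay, (n_pos, n_assayed) in fast_sim.ledger_marginals.items():
            col = ledger[assay]
            assert (col == "positive").sum() == n_pos
            assert (col != "not_assayed").sum() == n_assayed

    def test_all_negative_marginals(self, fast_sim):
        marg = {a: (0, n) for a, (_, n) in fast_sim.ledger_marginals.items()}
        ledger = gen_ledger_fixture(dataclasses.replace(fast_sim, ledger_marginals=marg))
        assert not (ledger == "positive").any().any()
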
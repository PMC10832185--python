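import numpy as np
import pandas as pd
import pytest

import gliostate as gs
from gliostate.errors import InvalidDesignError, InvalidParameterError
from gliostate.synthetic import profile_value


class TestDesignValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"replicates_per_timepoint": 1},
            {"timepoints": ()},
            {"timepoints": (0, 3, 1)},
            {"dispersion": -0.1},
            {"baseline_mean": 0.0},
            {"n_background": -5},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(InvalidDesignError):
            gs.default_design(**kwargs)

    def test_gene_count_bookkeeping(self):
        design = gs.default_design()
        assert design.n_genes == 2000 + 100 + 4 * 50 + 10


class TestTemporalProfiles:
    def test_acute_peaks_at_day_one_and_decays(self):
        days = np.array([0.0, 1.0, 3.0, 6.0, 9.0, 14.0])
        p = profile_value("acute", days)
        assert p[0] == 0.0
        assert p[1] == pytest.approx(1.0)
        assert np.all(np.diff(p[1:]) < 0)

    def test_chronic_saturates_by_day_six(self):
        days = np.array([0.0, 1.0, 3.0, 6.0, 9.0, 14.0])
        p = profile_value("chronic", days)
        assert p[0] == 0.0
        assert np.all(np.diff(p) > 0)
        assert p[3] > 0.99


class TestSimulateCounts:
    def test_seeded_determinism(self):
        design = gs.default_design(seed=11, n_background=100)
        a, _ = gs.simulate_counts(design)
        b, _ = gs.simulate_counts(design)
        assert a.counts.equals(b.counts)
        assert a.metadata.equals(b.metadata)

    def test_shape_matches_design(self, small_sim):
        design, counts, truth = small_sim
        assert counts.counts.shape == (
            design.n_genes,
            len(design.timepoints) * design.replicates_per_timepoint,
        )
        assert len(truth.gene_blocks) == design.n_genes
        assert not truth.gene_blocks.index.has_duplicates

    def test_null_design_moments_match_negative_binomial(self):
        # 2 timepoints x 100 replicates = 200 draws per gene, zero effects
        design = gs.default_design(
            seed=5,
            timepoints=(0, 1),
            replicates_per_timepoint=100,
            n_background=60,
            signature_blocks=(),
            n_housekeeping=0,
            libsize_sd=0.0,
        )
        counts, _ = gs.simulate_counts(design)
        mu = design.baseline_mean
        var = mu + design.dispersion * mu**2
        se = np.sqrt(var / counts.counts.shape[1])
        z = (counts.counts.mean(axis=1) - mu) / se
        # ~99.7% of genes within 3 SE; allow a single chance excursion
        assert (z.abs() > 3).sum() <= 1
        assert abs(z.mean()) < 3 / np.sqrt(len(z))

    def test_chronic_block_effect_recovered(self):
        design = gs.default_design(
            seed=3,
            replicates_per_timepoint=6,
            n_background=200,
            signature_blocks=(gs.SignatureBlock("dam", 50, "up", 2.0, "chronic"),),
        )
        counts, truth = gs.simulate_counts(design)
        norm = gs.housekeeping_normalize(counts, truth.housekeeping_genes)
        late = norm.metadata.index[norm.metadata["div"] >= 6]
        day0 = norm.metadata.index[norm.metadata["div"] == 0]
        block = truth.block_genes("dam")
        lfc = (
            norm.values.loc[block, late].mean(axis=1)
            - norm.values.loc[block, day0].mean(axis=1)
        )
        assert lfc.mean() == pytest.approx(2.0, abs=0.2)


class TestHumanCohort:
    def test_rho_one_is_exact(self, small_sim):
        _, _, truth = small_sim
        human, omap = gs.simulate_human_cohort(truth, 1.0, seed=0)
        r = gs.pearson_r(
            truth.chronic_log2fc.to_numpy(), human.table["log2fc"].to_numpy()
        )
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_rho_outside_unit_interval_rejected(self, small_sim):
        _, _, truth = small_sim
        for bad in (0.0, -0.5, 1.2):
            with pytest.raises(InvalidParameterError):
                gs.simulate_human_cohort(truth, bad)

    def test_correlation_calibration_at_2000_genes(self):
        counts, truth = gs.simulate_counts(gs.default_design(seed=1, n_background=1690))
        rs = []
        for seed in range(20):
            human, _ = gs.simulate_human_cohort(truth, 0.9, seed=seed)
            rs.append(
                gs.pearson_r(
                    truth.chronic_log2fc.to_numpy(), human.table["log2fc"].to_numpy()
                )
            )
        assert abs(np.mean(rs) - 0.9) <= 0.03


class TestSimulateSecretome:
    def test_zero_lag_zero_noise_matches_transcript_z(self, small_sim):
        _, _, truth = small_sim
        sec = gs.simulate_secretome(truth, [("A", "dam")], lag_days=0.0, noise_sd=0.0)
        z = gs.longitudinal_zscores(gs.to_rates(sec))
        assert np.allclose(
            z.values.loc["A"].to_numpy(),
            truth.block_transcript_z("dam").to_numpy(),
            atol=1e-9,
        )

    def test_lod_above_everything_censors_all(self, small_sim):
        _, _, truth = small_sim
        sec = gs.simulate_secretome(truth, [("A", "dam")], lod=1e9)
        assert not sec.detected.to_numpy().any()

    def test_unknown_block_rejected(self, small_sim):
        _, _, truth = small_sim
        with pytest.raises(InvalidParameterError):
            gs.simulate_secretome(truth, [("A", "no_such_block")])

    def test_down_block_trajectory_inverted(self, small_sim):
        _, _, truth = small_sim
        sec = gs.simulate_secretome(
            truth, [("up", "dam"), ("down", "homeostatic")], lag_days=0.0, noise_sd=0.0
        )
        z = gs.longitudinal_zscores(gs.to_rates(sec))
        assert np.allclose(
            z.values.loc["up"].to_numpy(), -z.values.loc["down"].to_numpy(), atol=1e-9
        )


class TestEmitPanels:
    def test_block_sizes_and_disjoint_categories(self, small_sim):
        design, _, truth = small_sim
        panel = gs.emit_panels(truth)
        sizes = panel.table.groupby("category")["gene"].count()
        for block in design.signature_blocks:
            assert sizes[block.name] == block.n_genes
        assert sizes["housekeeping"] == design.n_housekeeping
        assert not panel.table["gene"].duplicated().any()
        assert "background" not in set(panel.table["category"])
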
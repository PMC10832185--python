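import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gliostate as gs
from gliostate.errors import InvalidInputError


def z_of(values, **kwargs):
    frame = pd.DataFrame(
        np.atleast_2d(np.asarray(values, dtype=float)),
    )
    frame.index = [f"g{i}" for i in range(frame.shape[0])]
    frame.columns = [f"d{i}" for i in range(frame.shape[1])]
    return gs.zscore_rows(frame, **kwargs)


class TestZscoreRows:
    def test_three_point_row(self):
        z = z_of([1, 2, 3])
        assert np.allclose(z.values.iloc[0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_row_maps_to_zero(self):
        z = z_of([5, 5, 5])
        assert np.allclose(z.values.iloc[0], 0.0)

    def test_capping_clips_extremes(self):
        # one far outlier drives |Z| above 6 in a long row
        row = [0.0] * 60 + [100.0]
        z = z_of(row, cap=6.0)
        assert z.values.iloc[0].max() == pytest.approx(6.0)
        assert (z.values.abs() <= 6.0 + 1e-12).all().all()

    def test_single_condition_rejected(self):
        with pytest.raises(InvalidInputError):
            z_of([1.0])

    def test_column_mode_standardizes_conditions(self, rng):
        frame = pd.DataFrame(rng.normal(size=(6, 4)))
        z = gs.zscore_rows(frame, per="condition")
        assert np.allclose(z.values.mean(axis=0), 0.0, atol=1e-9)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=2, max_size=12
        ).filter(lambda v: np.std(v) > 1e-6)
    )
    def test_row_moments_property(self, row):
        z = z_of(row)
        vals = z.values.iloc[0].to_numpy()
        assert abs(vals.mean()) < 1e-9
        assert abs(vals.std(ddof=0) - 1.0) < 1e-9


def make_panel(mapping):
    rows = [
        ("p", category, gene, "") for category, genes in mapping.items() for gene in genes
    ]
    return gs.PanelDefinition(
        pd.DataFrame(rows, columns=["panel", "category", "gene", "direction"])
    )


class TestCategoryAUC:
    def _zmatrix(self, rows, days):
        frame = pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(rows))],
            columns=[f"d{d}" for d in days],
        )
        return gs.ZMatrix(values=frame), {f"d{d}": d for d in days}

    def test_unit_mean_z_gives_day_span(self):
        z, times = self._zmatrix([[1, 1, 1]], (0, 1, 3))
        panel = make_panel({"cat": ["g0"]})
        auc = gs.category_auc(z, panel, times)
        assert auc["auc"].iloc[0] == pytest.approx(3.0)

    def test_triangle_trapezoid(self):
        z, times = self._zmatrix([[0, 1, 0]], (0, 1, 3))
        auc = gs.category_auc(z, make_panel({"cat": ["g0"]}), times)
        assert auc["auc"].iloc[0] == pytest.approx(1.5)

    def test_null_signal_zero(self):
        z, times = self._zmatrix([[0, 0, 0]], (0, 1, 3))
        auc = gs.category_auc(z, make_panel({"cat": ["g0"]}), times)
        assert auc["auc"].iloc[0] == pytest.approx(0.0)

    def test_missing_category_reported_not_raised(self):
        z, times = self._zmatrix([[1, 2, 3]], (0, 1, 3))
        auc = gs.category_auc(z, make_panel({"cat": ["g0"], "ghost": ["nope"]}), times)
        ghost = auc[auc["category"] == "ghost"].iloc[0]
        assert np.isnan(ghost["auc"]) and ghost["n_found"] == 0

    def test_additive_over_adjacent_intervals_and_linear(self, rng):
        days = (0.0, 1.0, 3.0, 6.0)
        rows = rng.normal(size=(4, 4))
        z, times = self._zmatrix(rows, days)
        panel = make_panel({"cat": [f"g{i}" for i in range(4)]})
        total = gs.category_auc(z, panel, times)["auc"].iloc[0]
        first = gs.category_auc(
            gs.ZMatrix(values=z.values.iloc[:, :3]), panel, dict(list(times.items())[:3])
        )["auc"].iloc[0]
        second = gs.category_auc(
            gs.ZMatrix(values=z.values.iloc[:, 2:]), panel, dict(list(times.items())[2:])
        )["auc"].iloc[0]
        assert total == pytest.approx(first + second, rel=1e-12)
        doubled = gs.category_auc(gs.ZMatrix(values=2 * z.values), panel, times)
        assert doubled["auc"].iloc[0] == pytest.approx(2 * total, rel=1e-12)

    def test_too_few_timepoints_rejected(self):
        z, _ = self._zmatrix([[1, 2]], (0, 1))
        with pytest.raises(InvalidInputError):
            gs.category_auc(gs.ZMatrix(values=z.values.iloc[:, :1]), make_panel({"c": ["g0"]}), {"d0": 0})


def tiny_reference():
    expr = pd.DataFrame(
        {
            "microglia": [8.0, 7.0, 0.5, 0.2],
            "neuron": [0.5, 0.3, 9.0, 8.0],
        },
        index=["Mg1", "Mg2", "Nn1", "Nn2"],
    )
    return gs.CellTypeReference.from_expression(expr)


class TestCellTypeScores:
    def test_top_one_equals_single_marker(self):
        ref = tiny_reference()
        expr = pd.DataFrame({"s1": [3.0, 1.0, 2.0, 4.0]}, index=["Mg1", "Mg2", "Nn1", "Nn2"])
        scores = gs.celltype_expression_score(expr, ref, top_n=1)
        mg = scores[(scores.cell_type == "microglia") & (scores["sample"] == "s1")]
        assert mg["score"].iloc[0] == pytest.approx(3.0)

    def test_two_marker_sum(self):
        ref = tiny_reference()
        expr = pd.DataFrame({"s1": [2.0, 4.0, 0.0, 0.0]}, index=["Mg1", "Mg2", "Nn1", "Nn2"])
        scores = gs.celltype_expression_score(expr, ref, top_n=2)
        mg = scores[(scores.cell_type == "microglia")]
        assert mg["score"].iloc[0] == pytest.approx(6.0)
        assert mg["n_markers"].iloc[0] == 2

    def test_depletion_scenario_drops_only_target_score(self, small_sim, rng):
        # microglial depletion: zero the microglia markers, neuron markers intact
        ref = tiny_reference()
        base = pd.DataFrame(
            {"ctrl": [5.0, 5.0, 5.0, 5.0], "depleted": [0.0, 0.0, 5.0, 5.0]},
            index=["Mg1", "Mg2", "Nn1", "Nn2"],
        )
        scores = gs.celltype_expression_score(base, ref, top_n=2)
        pivot = scores.pivot(index="cell_type", columns="sample", values="score")
        assert pivot.loc["microglia", "depleted"] < pivot.loc["microglia", "ctrl"]
        assert pivot.loc["neuron", "depleted"] == pytest.approx(pivot.loc["neuron", "ctrl"])


class TestTFAttribution:
    def test_single_tf_returns_its_row(self):
        ref = tiny_reference()
        means, rows, missing = gs.tf_celltype_attribution(["Mg1"], ref)
        assert means["microglia"] == pytest.approx(8.0)
        assert missing == []

    def test_mean_of_two(self):
        ref = tiny_reference()
        means, _, _ = gs.tf_celltype_attribution(["Mg1", "Mg2"], ref)
        assert means["microglia"] == pytest.approx(7.5)

    def test_enriched_list_attributes_to_right_cell_type(self):
        ref = tiny_reference()
        means, _, missing = gs.tf_celltype_attribution(["Mg1", "Mg2", "Unknown"], ref)
        assert means.idxmax() == "microglia"
        assert missing == ["Unknown"]

    def test_all_absent_raises(self):
        with pytest.raises(InvalidInputError):
            gs.tf_celltype_attribution(["X", "Y"], tiny_reference())


class TestPanelDirectionality:
    def test_dam_auc_positive_homeostatic_negative(self, small_sim):
        # rising disease-associated program integrates positive, falling
        # homeostatic program negative, on the default simulated trajectory
        _, counts, truth = small_sim
        norm = gs.housekeeping_normalize(counts, truth.housekeeping_genes)
        lfc = {}
        for cond in ("DIV1", "DIV3", "DIV6", "DIV9", "DIV14"):
            lfc[cond] = gs.log2_fold_changes(norm, (cond, "DIV0")).table["log2fc"]
        lfc = pd.DataFrame(lfc)
        z = gs.zscore_rows(lfc, cap=6.0)
        times = {c: float(c[3:]) for c in lfc.columns}
        auc = gs.category_auc(z, gs.emit_panels(truth), times).set_index("category")
        assert auc.loc["dam", "auc"] > 0
        assert auc.loc["homeostatic", "auc"] < 0
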
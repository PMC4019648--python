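import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rangefinder.core import GeneSet
from rangefinder.dose_response import (
    CorrelationTable,
    _rowwise_pearson,
    assemble_table,
    dose_response_correlations,
    write_correlation_table,
)
from rangefinder.preprocess import TIME_MATCHED_DOSE0, RatioGrid
from rangefinder.sweetspot import EnrichmentDiagram, classify_sweet_spots, EnrichmentConfig


def grid_from_gene_curves(doses, time, curves):
    """RatioGrid with one time point; curves maps gene -> ratios over nonzero doses."""
    genes = list(curves)
    cells = {
        (d, time): np.array([curves[g][i] for g in genes])
        for i, d in enumerate(doses)
    }
    return RatioGrid(genes=genes, baseline_kind=TIME_MATCHED_DOSE0, cells=cells)


class TestPearsonScreen:
    def test_linear_response_has_perfect_correlation(self):
        grid = grid_from_gene_curves(
            [1.0, 2.0, 3.0], 60.0, {"lin": [0.5, 1.0, 1.5], "anti": [-1.0, -2.0, -3.0]}
        )
        table = dose_response_correlations(grid, GeneSet("s", frozenset(["lin", "anti"])))
        assert table.corr.loc["lin", 60.0] == pytest.approx(1.0)
        assert table.corr.loc["anti", 60.0] == pytest.approx(-1.0)
        # anti-correlation is just as relevant: the rule is on |r|
        assert table.relevant.loc["anti", 60.0]

    def test_symmetric_triple_is_uncorrelated(self):
        grid = grid_from_gene_curves([1.0, 2.0], 60.0, {"hump": [1.0, 0.0]})
        table = dose_response_correlations(
            grid, GeneSet("s", frozenset(["hump"])), min_points=3
        )
        # doses {0,1,2} with ratios {0,1,0}
        assert table.corr.loc["hump", 60.0] == pytest.approx(0.0, abs=1e-12)

    def test_worked_four_point_case(self):
        grid = grid_from_gene_curves([1.0, 2.0, 3.0], 60.0, {"g": [1.0, 1.0, 2.0]})
        table = dose_response_correlations(grid, GeneSet("s", frozenset(["g"])))
        # doses {0,1,2,3}, ratios {0,1,1,2}: r = 3 / sqrt(10)
        assert table.corr.loc["g", 60.0] == pytest.approx(3 / np.sqrt(10))
        assert table.relevant.loc["g", 60.0]

    def test_zero_dose_anchor_is_optional(self):
        grid = grid_from_gene_curves(
            [1.0, 2.0, 3.0, 4.0], 60.0, {"g": [2.0, 1.0, 3.0, 2.5]}
        )
        gene_set = GeneSet("s", frozenset(["g"]))
        with_anchor = dose_response_correlations(grid, gene_set)
        without = dose_response_correlations(grid, gene_set, include_zero_dose=False)
        r_ref = stats.pearsonr([1, 2, 3, 4], [2.0, 1.0, 3.0, 2.5]).statistic
        assert without.corr.loc["g", 60.0] == pytest.approx(r_ref)
        assert with_anchor.corr.loc["g", 60.0] != pytest.approx(r_ref)

    def test_too_few_doses_leaves_cell_absent(self):
        grid = grid_from_gene_curves([1.0, 2.0], 60.0, {"g": [1.0, 2.0]})
        table = dose_response_correlations(grid, GeneSet("s", frozenset(["g"])))
        assert np.isnan(table.corr.loc["g", 60.0])  # 3 points < min_points 4

    def test_constant_ratios_yield_no_correlation(self):
        grid = grid_from_gene_curves([1.0, 2.0, 3.0], 60.0, {"flat": [0.0, 0.0, 0.0]})
        table = dose_response_correlations(grid, GeneSet("s", frozenset(["flat"])))
        assert np.isnan(table.corr.loc["flat", 60.0])

    def test_genes_absent_from_filtered_data_are_omitted(self):
        grid = grid_from_gene_curves([1.0, 2.0, 3.0], 60.0, {"g": [1.0, 2.0, 3.0]})
        table = dose_response_correlations(grid, GeneSet("s", frozenset(["g", "gone"])))
        assert list(table.corr.index) == ["g"]

    def test_rowwise_pearson_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 20, 6)
        Y = rng.normal(0, 1, (10, 6))
        ours = _rowwise_pearson(x, Y)
        ref = [stats.pearsonr(x, row).statistic for row in Y]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    @given(
        dose_scale=st.floats(0.1, 50),
        ratio_scale=st.floats(0.1, 50),
        flip=st.booleans(),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_rescaling_invariance(self, dose_scale, ratio_scale, flip):
        """|r| is invariant to positive rescaling of dose and ratio units;
        a sign flip of the ratios flips r's sign."""
        rng = np.random.default_rng(12)
        x = np.array([0.0, 1.0, 2.5, 7.0])
        Y = rng.normal(0, 1, (4, 4))
        r0 = _rowwise_pearson(x, Y)
        sign = -1.0 if flip else 1.0
        r1 = _rowwise_pearson(x * dose_scale, Y * ratio_scale * sign)
        np.testing.assert_allclose(r1, sign * r0, atol=1e-9)


class TestAssembly:
    def make_table(self):
        doses = [1.0, 2.0, 3.0]
        genes = {
            "early": [1.0, 2.0, 3.0],      # r = 1 at both times
            "weak": [0.4, 0.1, 0.45],      # never relevant
        }
        cells = {}
        for time in (60.0, 120.0):
            for i, d in enumerate(doses):
                vec = np.array([genes[g][i] * (1 if time == 60.0 else 0.5) for g in genes])
                cells[(d, time)] = vec
        # make "late" relevant only at 120
        grid = RatioGrid(
            genes=list(genes), baseline_kind=TIME_MATCHED_DOSE0, cells=cells
        )
        return dose_response_correlations(grid, GeneSet("s", frozenset(genes)))

    def test_irrelevant_genes_dropped(self):
        table = self.make_table()
        out = assemble_table(table, None)
        assert list(out.corr.index) == ["early"]
        assert out.sweet_times == frozenset()

    def test_sweet_columns_flagged_from_diagram(self):
        table = self.make_table()
        cells = {(d, t): 0.5 for d in (1.0, 2.0, 3.0) for t in (60.0, 120.0)}
        cells[(2.0, 120.0)] = 0.001
        diagram = classify_sweet_spots(
            EnrichmentDiagram("s", dict(cells), dict(cells), pmax=0.01),
            EnrichmentConfig(pmax=0.01),
        )
        out = assemble_table(table, diagram)
        assert out.sweet_times == frozenset({120.0})
        header = out.to_display().columns.tolist()
        assert "2 h *" in header and "1 h" in header

    def test_set_mismatch_rejected(self):
        table = self.make_table()
        diagram = EnrichmentDiagram("other", {(1.0, 60.0): 0.5}, {(1.0, 60.0): 0.5}, 0.2)
        with pytest.raises(ValueError):
            assemble_table(table, diagram)

    def test_rows_ordered_by_earliest_relevant_time_then_strength(self):
        doses = [1.0, 2.0, 3.0]
        curves = {
            "late_strong": {60.0: [0.1, 0.05, 0.12], 120.0: [1.0, 2.0, 3.0]},
            "early": {60.0: [1.0, 2.0, 3.0], 120.0: [0.0, 0.1, 0.0]},
            "late_weak": {60.0: [0.1, 0.0, 0.1], 120.0: [1.0, 2.1, 2.8]},
        }
        cells = {
            (d, t): np.array([curves[g][t][i] for g in curves])
            for t in (60.0, 120.0)
            for i, d in enumerate(doses)
        }
        grid = RatioGrid(genes=list(curves), baseline_kind=TIME_MATCHED_DOSE0, cells=cells)
        table = dose_response_correlations(grid, GeneSet("s", frozenset(curves)))
        out = assemble_table(table, None)
        assert out.row_order[0] == "early"
        assert out.row_order[1] == "late_strong"  # |r|=1 beats the weaker late gene

    def test_written_table_shows_only_relevant_cells(self, tmp_path):
        out = assemble_table(self.make_table(), None)
        path = tmp_path / "table.tsv"
        write_correlation_table(out, path)
        text = path.read_text()
        assert "early" in text and "weak" not in text
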
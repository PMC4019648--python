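import itertools
import json
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rangefinder.core import GeneSet, GeneSetCollection
from rangefinder.design_space import RestrictionMask, USABLE
from rangefinder.preprocess import TIME_MATCHED_DOSE0, RatioGrid
from rangefinder.sweetspot import (
    EnrichmentConfig,
    EnrichmentDiagram,
    benjamini_hochberg,
    classify_sweet_spots,
    enrich_design_space,
    gene_set_test,
    random_set_diagnostic,
)
from rangefinder import synth
from rangefinder.preprocess import compute_ratio_grid


# -- independent oracle: exact subset enumeration on Fraction midranks ------


def oracle_rank_p(values, member_idx, alternative="mixed"):
    """P(random same-size subset has mean midrank >= observed), exactly."""
    if alternative == "mixed":
        values = [abs(v) for v in values]
    elif alternative == "down":
        values = [-v for v in values]
    n = len(values)
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(Fraction(2 * less + equal + 1, 2))  # midrank
    k = len(member_idx)
    obs = sum(ranks[i] for i in member_idx)
    hits = sum(
        1 for combo in itertools.combinations(range(n), k)
        if sum(ranks[i] for i in combo) >= obs
    )
    from math import comb

    return Fraction(hits, comb(n, k))


class TestRankTest:
    def test_top_two_of_six_distinct(self):
        values = np.array([0.1, -0.2, 0.3, 0.5, -2.0, 3.0])
        p = gene_set_test(values, np.array([False] * 4 + [True, True]))
        assert p == pytest.approx(1 / 15)

    def test_constant_vector_gives_p_one(self, caplog):
        with caplog.at_level("WARNING"):
            p = gene_set_test(np.ones(6), np.array([True, True] + [False] * 4))
        assert p == 1.0

    def test_identical_statistics_give_p_one(self):
        # all |statistics| tie: no subset outranks any other
        values = np.array([1.0, -1.0, 1.0, -1.0, 1.0, 1.0])
        assert gene_set_test(values, np.array([True, True] + [False] * 4)) == 1.0

    @pytest.mark.parametrize("alternative", ["mixed", "up", "down"])
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exact_enumeration_oracle(self, seed, alternative):
        """Small instances (<=10 genes, set <=4): exact equality with brute force."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        k = int(rng.integers(2, 5))
        values = np.round(rng.normal(0, 1, n), 1)  # rounding induces ties
        member_idx = sorted(rng.choice(n, size=k, replace=False).tolist())
        member = np.zeros(n, dtype=bool)
        member[member_idx] = True
        config = EnrichmentConfig(alternative=alternative)
        p = gene_set_test(values, member, config)
        expected = oracle_rank_p(values.tolist(), member_idx, alternative)
        assert p == pytest.approx(float(expected), abs=0)

    def test_tie_free_case_matches_wilcoxon_exact(self):
        """Cross-check against the exact Mann-Whitney distribution (no ties)."""
        rng = np.random.default_rng(42)
        values = rng.normal(0, 1, 9)
        member = np.zeros(9, dtype=bool)
        member[[1, 4, 6]] = True
        p = gene_set_test(values, member, EnrichmentConfig(alternative="up"))
        ref = stats.mannwhitneyu(
            values[member], values[~member], alternative="greater", method="exact"
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-12)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 10)
        member = np.zeros(10, dtype=bool)
        member[[0, 3, 7]] = True
        exact = gene_set_test(values, member)
        approx = gene_set_test(values, member, EnrichmentConfig(max_exact=1))
        assert approx == pytest.approx(exact, abs=0.05)

    def test_degenerate_sets_rejected(self):
        values = np.arange(5.0)
        with pytest.raises(ValueError):
            gene_set_test(values, np.array([True] + [False] * 4))
        with pytest.raises(ValueError):
            gene_set_test(values, np.ones(5, dtype=bool))


class TestPermutationTest:
    def test_converges_to_exhaustive_value(self):
        """Monte-Carlo p for the top-2-of-6 instance approaches 1/15."""
        values = np.array([0.1, -0.2, 0.3, 0.5, -2.0, 3.0])
        member = np.array([False] * 4 + [True, True])
        config = EnrichmentConfig(method="permutation", n_permutations=9999, seed=1)
        p = gene_set_test(values, member, config)
        truth = 1 / 15
        sd = np.sqrt(truth * (1 - truth) / 9999)
        assert abs(p - truth) <= 3 * sd + 1 / 9999

    def test_requires_enough_permutations(self):
        with pytest.raises(ValueError):
            EnrichmentConfig(method="permutation", n_permutations=10)

    def test_add_one_estimator_never_returns_zero(self):
        values = np.array([0.0] * 8 + [5.0, 6.0])
        member = np.array([False] * 8 + [True, True])
        config = EnrichmentConfig(method="permutation", n_permutations=99, seed=2)
        assert gene_set_test(values, member, config) >= 1 / 100


class TestBenjaminiHochberg:
    def test_closed_form_equal_spacing(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_trivial_vectors(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_step_up_oracle_and_order_invariance(self, pvals):
        """Matches the closed-form step-up rule and is permutation-invariant."""
        p = np.array(pvals)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        stepped = p[order] * m / np.arange(1, m + 1)
        expected = np.minimum.accumulate(stepped[::-1])[::-1].clip(max=1.0)
        adj = benjamini_hochberg(p)
        np.testing.assert_allclose(adj[order], expected, atol=1e-12)
        # order invariance
        perm = np.random.default_rng(0).permutation(m)
        np.testing.assert_allclose(benjamini_hochberg(p[perm]), adj[perm], atol=1e-12)
        # monotone: adjusted values never fall below raw ones
        assert np.all(adj >= p - 1e-12)


def make_diagram(p_adj, pmax=0.01):
    cells = {(float(i), 60.0): p for i, p in enumerate(p_adj)}
    return EnrichmentDiagram(set_name="s", p_raw=dict(cells), p_adj=cells, pmax=pmax)


class TestColorKeyAndSweetSpots:
    def test_pmin_cell_is_maximally_red_and_sweet(self):
        d = classify_sweet_spots(make_diagram([0.001, 0.5]), EnrichmentConfig(pmax=0.01))
        assert d.color_value[(0.0, 60.0)] == 0.0
        assert d.sweet_mask[(0.0, 60.0)]

    def test_red_band_boundary_is_inclusive(self):
        # (0.0035 - 0.001) / 0.01 = 0.25, exactly the band edge
        d = classify_sweet_spots(
            make_diagram([0.001, 0.0035]), EnrichmentConfig(pmax=0.01)
        )
        assert d.color_value[(1.0, 60.0)] == pytest.approx(0.25)
        assert d.sweet_mask[(1.0, 60.0)]

    def test_fallback_scale_declares_no_sweet_spots(self):
        d = classify_sweet_spots(make_diagram([1.0, 1.0, 0.4]))
        assert not any(d.sweet_mask.values())
        assert d.color_value[(2.0, 60.0)] == pytest.approx((0.4 - 0.3) / 0.2)

    @given(
        p_new=st.floats(1e-6, 1.0),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_lowering_a_p_value_never_unsweetens(self, p_new, seed):
        rng = np.random.default_rng(seed)
        p_adj = rng.uniform(0, 1, 6).tolist()
        config = EnrichmentConfig(pmax=0.2)
        before = classify_sweet_spots(make_diagram(p_adj, pmax=0.2), config)
        for i, p in enumerate(p_adj):
            cell = (float(i), 60.0)
            if before.sweet_mask[cell] and p_new < p:
                lowered = list(p_adj)
                lowered[i] = p_new
                after = classify_sweet_spots(make_diagram(lowered, pmax=0.2), config)
                assert after.sweet_mask[cell]


def planted_ratio_grid(seed=0, n_genes=500, amplitude=1.5, set_size=30, sd=0.5):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    doses, times = (1.0, 2.0, 3.0), (60.0, 120.0)
    cells = {
        (d, t): rng.normal(0, sd, n_genes) for d in doses for t in times
    }
    target = (2.0, 120.0)
    cells[target][:set_size] += amplitude
    grid = RatioGrid(genes=genes, baseline_kind=TIME_MATCHED_DOSE0, cells=cells)
    return grid, genes[:set_size], target


class TestDesignSpaceScreen:
    def test_planted_activation_is_argmin(self):
        grid, set_genes, target = planted_ratio_grid(seed=3)
        sets = GeneSetCollection([GeneSet("planted", frozenset(set_genes))])
        (diagram,) = enrich_design_space(grid, None, sets, EnrichmentConfig())
        assert diagram.argmin_cell() == target
        assert target in diagram.sweet_cells()

    def test_bh_is_per_diagram(self):
        grid, set_genes, _ = planted_ratio_grid(seed=4)
        sets = GeneSetCollection([GeneSet("planted", frozenset(set_genes))])
        (diagram,) = enrich_design_space(grid, None, sets, EnrichmentConfig())
        order = sorted(diagram.p_raw)
        np.testing.assert_allclose(
            [diagram.p_adj[c] for c in order],
            benjamini_hochberg([diagram.p_raw[c] for c in order]),
        )
        for c in order:
            assert diagram.p_adj[c] >= diagram.p_raw[c] - 1e-12

    def test_restriction_mask_limits_tested_cells(self):
        grid, set_genes, target = planted_ratio_grid(seed=5)
        mask = RestrictionMask(
            cells={c: (USABLE if c != target else "nonspecific") for c in grid.cells},
            threshold=2000,
        )
        sets = GeneSetCollection([GeneSet("planted", frozenset(set_genes))])
        (diagram,) = enrich_design_space(grid, mask, sets, EnrichmentConfig())
        assert target not in diagram.p_adj

    def test_absent_set_is_skipped_not_fatal(self, caplog):
        grid, set_genes, _ = planted_ratio_grid(seed=6)
        sets = GeneSetCollection(
            [
                GeneSet("planted", frozenset(set_genes)),
                GeneSet("ghost", frozenset({"nope1", "nope2"})),
            ]
        )
        with caplog.at_level("ERROR"):
            diagrams = enrich_design_space(grid, None, sets, EnrichmentConfig())
        assert [d.set_name for d in diagrams] == ["planted"]


class TestRandomSetDiagnostic:
    def test_seeded_runs_are_byte_identical(self):
        grid, _, _ = planted_ratio_grid(seed=7, amplitude=0.0)
        a = random_set_diagnostic(grid, None, size=20, n_sets=10, seed=9)
        b = random_set_diagnostic(grid, None, size=20, n_sets=10, seed=9)
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_null_data_reports_low_sweet_fraction(self):
        grid, _, _ = planted_ratio_grid(seed=8, amplitude=0.0)
        summary = random_set_diagnostic(grid, None, size=20, n_sets=20, seed=1)
        assert 0.0 <= summary["fraction_with_sweet_spot"] <= 1.0
        assert len(summary["per_set_pmin"]) == 20

    def test_degenerate_size_warned(self, caplog):
        grid, _, _ = planted_ratio_grid(seed=9, n_genes=50, set_size=5)
        with caplog.at_level("WARNING"):
            random_set_diagnostic(grid, None, size=49, n_sets=2, seed=0)
        assert any("degenerate" in r.message for r in caplog.records)

    def test_size_bounds(self):
        grid, _, _ = planted_ratio_grid(seed=10, n_genes=50, set_size=5)
        with pytest.raises(ValueError):
            random_set_diagnostic(grid, None, size=1, n_sets=2, seed=0)
        with pytest.raises(ValueError):
            random_set_diagnostic(grid, None, size=50, n_sets=2, seed=0)
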
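"""Strategy triangle, truncated-Poisson sampling and group partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fragmodes import (
    FragmentationDraw,
    FragmentationStrategy,
    GroupState,
    fragment_group,
    sample_cells_without_replacement,
    truncated_poisson_sample,
    validate_strategy,
)
from fragmodes.oracles import truncated_poisson_pmf
from conftest import make_group


class TestStrategyTriangle:
    @pytest.mark.parametrize("s,n,ok", [
        (0.5, 0.5, True),      # binary-fission corner (closed triangle)
        (0.01, 0.99, True),    # complete-fragmentation corner region
        (0.01, 0.01, True),    # single-cell-reproduction corner region
        (0.3, 0.2, False),     # lower triangle: logically impossible
        (0.2, 0.9, False),     # above the upper diagonal
        (0.6, 0.7, False),     # s > 1/2
        (0.0, 0.5, False),     # s must be positive
        (0.2, 0.0, False),
    ])
    def test_validity(self, s, n, ok):
        assert validate_strategy(FragmentationStrategy(s, n)) is ok

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(0.001, 0.5), st.floats(0.001, 1.0))
    def test_triangle_is_exactly_s_le_n_le_1ms(self, s, n):
        assert validate_strategy(FragmentationStrategy(s, n)) == (s <= n <= 1 - s)


class TestFragmentationDraw:
    def test_ceil_rule_and_sizes(self):
        d = FragmentationDraw(7, 3)
        assert d.G_offspring == 3
        assert d.sizes == (3, 3, 1)

    def test_exact_division(self):
        d = FragmentationDraw(6, 3)
        assert d.G_offspring == 2
        assert d.sizes == (3, 3)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            FragmentationDraw(5, 6)
        with pytest.raises(ValueError):
            FragmentationDraw(0, 1)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(1, 60), st.data())
    def test_sizes_partition_n_offspring(self, n_off, data):
        s_off = data.draw(st.integers(1, n_off))
        d = FragmentationDraw(n_off, s_off)
        assert sum(d.sizes) == n_off
        assert all(1 <= x <= s_off for x in d.sizes)


class TestTruncatedPoissonSampler:
    def test_degenerate_support(self, rng):
        assert truncated_poisson_sample(5.0, 1, rng) == 1

    def test_tiny_lambda_concentrates_on_one(self, rng):
        draws = truncated_poisson_sample(1e-9, 10, rng, size=2000)
        assert np.all(draws == 1)

    def test_pmf_ratio_lambda2_support3(self):
        # Pois(k;2) for k=1..3 is proportional to 2 : 2 : 4/3
        pmf = truncated_poisson_pmf(2.0, 3)
        expected = np.array([2.0, 2.0, 4.0 / 3.0])
        np.testing.assert_allclose(pmf, expected / expected.sum(), rtol=1e-12)

    @pytest.mark.parametrize("lam,sup", [(2.0, 3), (0.5, 10), (5.0, 8),
                                         (20.0, 15), (45.0, 50)])
    def test_sampler_matches_pmf_chisquare(self, lam, sup, rng):
        n = 100_000
        draws = truncated_poisson_sample(lam, sup, rng, size=n)
        observed = np.bincount(draws, minlength=sup + 1)[1:]
        expected = truncated_poisson_pmf(lam, sup) * n
        keep = expected > 1e-9
        _, p = stats.chisquare(observed[keep],
                               expected[keep] * observed[keep].sum()
                               / expected[keep].sum())
        assert p > 1e-3

    def test_bad_support_rejected(self, rng):
        with pytest.raises(ValueError):
            truncated_poisson_sample(1.0, 0, rng)


class TestSampleWithoutReplacement:
    def test_exhaustive_draw(self, rng):
        out = sample_cells_without_replacement(np.array([3]), 3, rng)
        assert out.tolist() == [3]

    def test_symmetry_half_half(self, rng):
        hits = sum(sample_cells_without_replacement(np.array([1, 1]), 1, rng)[0]
                   for _ in range(4000))
        assert abs(hits / 4000 - 0.5) < 0.05  # ~6 sigma band

    def test_both_wt_probability_one_sixth(self, rng):
        # census {wt:2, mut:2}, draw 2: P(both wt) = C(2,2)/C(4,2) = 1/6
        n = 30_000
        both = 0
        for _ in range(n):
            d = sample_cells_without_replacement(np.array([2, 2]), 2, rng)
            both += d[0] == 2
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        assert abs(both / n - 1 / 6) < 4 * se

    def test_overdraw_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_cells_without_replacement(np.array([2, 1]), 4, rng)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.integers(0, 10), min_size=1, max_size=6), st.data())
    def test_census_conservation(self, census, data):
        census = np.array(census)
        k = data.draw(st.integers(0, int(census.sum())))
        rng = np.random.Generator(np.random.PCG64(7))
        drawn = sample_cells_without_replacement(census, k, rng)
        assert drawn.sum() == k
        assert np.all(drawn >= 0)
        assert np.all(census - drawn >= 0)


class TestFragmentGroup:
    def test_forced_draw_conservation(self, rng):
        g = make_group([6], [4])
        parent, offspring, draw = fragment_group(
            g, FragmentationStrategy(0.5, 0.5), rng,
            forced_draws=FragmentationDraw(5, 5))
        assert len(offspring) == 1
        assert offspring[0].N == 5
        assert parent.N == 5
        assert parent.wt_counts[0] + offspring[0].wt_counts[0] == 6
        assert parent.mut_counts[0] + offspring[0].mut_counts[0] == 4

    def test_forced_draw_shapes(self, rng):
        g = make_group([10])
        parent, offspring, draw = fragment_group(
            g, FragmentationStrategy(0.3, 0.7), rng,
            forced_draws=FragmentationDraw(7, 3))
        assert draw.G_offspring == 3
        assert sorted(o.N for o in offspring) == [1, 3, 3]
        assert parent.N == 3

    def test_all_cells_transmitted_relabels_parent(self, rng):
        # 4 cells into four 1-cell parts: one part becomes the parent
        g = make_group([4])
        parent, offspring, _ = fragment_group(
            g, FragmentationStrategy(0.25, 1.0), rng,
            forced_draws=FragmentationDraw(4, 1))
        assert parent.N == 1
        assert len(offspring) == 3
        assert parent.N + sum(o.N for o in offspring) == 4

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            fragment_group(GroupState(np.array([0]), np.array([0])),
                           FragmentationStrategy(0.5, 0.5), rng)

    def test_invalid_strategy_rejected(self, rng):
        with pytest.raises(ValueError):
            fragment_group(make_group([10]), FragmentationStrategy(0.4, 0.2), rng)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(1, 25), st.integers(0, 25), st.data())
    def test_category_conservation_property(self, wt, mut, data):
        if wt + mut == 0:
            wt = 1
        s = data.draw(st.floats(0.02, 0.5))
        n = data.draw(st.floats(0.02, 1.0))
        if not (s <= n <= 1 - s):
            n = min(max(n, s), 1 - s)
        rng = np.random.Generator(np.random.PCG64(data.draw(st.integers(0, 2**20))))
        g = make_group([wt], [mut])
        parent, offspring, draw = fragment_group(
            g, FragmentationStrategy(s, n), rng)
        all_parts = [parent] + offspring
        assert sum(p.wt_counts[0] for p in all_parts) == wt
        assert sum(p.mut_counts[0] for p in all_parts) == mut
        assert all(p.N >= 1 for p in all_parts)
        assert draw.G_offspring == -(-draw.N_offspring // draw.S_offspring)

    def test_binary_fission_modal_split_is_half(self, rng):
        # at (0.5, 0.5) the two parts' modal sizes are floor/ceil of N/2
        N = 11
        sizes = []
        for _ in range(3000):
            parent, offspring, _ = fragment_group(
                make_group([N]), FragmentationStrategy(0.5, 0.5), rng)
            sizes.append(tuple(sorted([parent.N] + [o.N for o in offspring])))
        vals, counts = np.unique(["-".join(map(str, s)) for s in sizes],
                                 return_counts=True)
        assert vals[np.argmax(counts)] == "5-6"

    def test_complete_fragmentation_modal_outcome_all_singletons(self, rng):
        N = 10
        strat = FragmentationStrategy(1 / N, 1 - 1 / N)
        shapes = []
        for _ in range(4000):
            parent, offspring, _ = fragment_group(make_group([N]), strat, rng)
            shapes.append("-".join(map(str, sorted([parent.N] + [o.N for o in offspring]))))
        vals, counts = np.unique(shapes, return_counts=True)
        assert vals[np.argmax(counts)] == "-".join(["1"] * N)

    def test_single_cell_corner_modal_outcome_one_singleton(self, rng):
        N = 10
        strat = FragmentationStrategy(1 / N, 1 / N)
        shapes = []
        for _ in range(2000):
            parent, offspring, _ = fragment_group(make_group([N]), strat, rng)
            shapes.append((len(offspring), min(o.N for o in offspring)))
        vals, counts = np.unique([f"{a}:{b}" for a, b in shapes], return_counts=True)
        assert vals[np.argmax(counts)] == "1:1"
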
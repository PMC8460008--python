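"""Experiment protocols: schedules, smoothing, tidy outputs."""

import numpy as np
import pandas as pd
import pytest

from fragmodes import (
    FragmentationStrategy,
    ModelParams,
    default_mu_schedule,
    max_mutation_rate,
    neighbour_average,
    strategy_grid,
    strategy_scan,
    upper_transect,
)


class TestStrategySets:
    def test_upper_transect_runs_corner_to_corner(self):
        strats = upper_transect(6, s_min=0.02)
        assert strats[0].s == pytest.approx(0.02)
        assert strats[-1].as_tuple() == (0.5, 0.5)
        assert all(s.n == pytest.approx(1 - s.s) for s in strats)
        assert all(s.is_valid() for s in strats)

    def test_rect_grid_contains_invalid_points(self):
        strats = strategy_grid(4, 6)
        assert len(strats) == 24
        assert any(not s.is_valid() for s in strats)
        assert any(s.is_valid() for s in strats)


class TestMuSchedule:
    def test_default_descends_one_to_floor(self):
        sched = default_mu_schedule()
        assert sched[0] == 1.0
        assert np.all(np.diff(sched) < 0)
        assert sched[-1] == pytest.approx(1e-4, rel=1e-6)

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            default_mu_schedule(ratio=1.5)


class TestNeighbourAverage:
    def _table(self, pts):
        return pd.DataFrame([{"s": s, "n": n, "v": v} for s, n, v in pts])

    def test_constant_field_unchanged(self):
        t = self._table([(0.1, 0.5, 3.0), (0.2, 0.5, 3.0), (0.1, 0.6, 3.0)])
        out = neighbour_average(t, "v")
        assert np.allclose(out["v"], 3.0)

    def test_interior_point_is_mean_of_five(self):
        pts = [(0.2, 0.5, 10.0),
               (0.1, 0.5, 1.0), (0.3, 0.5, 2.0),
               (0.2, 0.4, 3.0), (0.2, 0.6, 4.0)]
        out = neighbour_average(self._table(pts), "v")
        centre = out[(out.s == 0.2) & (out.n == 0.5)]["v"].iloc[0]
        assert centre == pytest.approx((10 + 1 + 2 + 3 + 4) / 5)

    def test_corner_point_averages_only_present_neighbours(self):
        pts = [(0.1, 0.5, 10.0), (0.2, 0.5, 2.0)]
        out = neighbour_average(self._table(pts), "v")
        corner = out[(out.s == 0.1)]["v"].iloc[0]
        assert corner == pytest.approx(6.0)

    def test_nan_points_do_not_contribute(self):
        pts = [(0.1, 0.5, 10.0), (0.2, 0.5, np.nan)]
        out = neighbour_average(self._table(pts), "v")
        assert out[(out.s == 0.1)]["v"].iloc[0] == pytest.approx(10.0)
        assert np.isnan(out[(out.s == 0.2)]["v"].iloc[0])


class TestProtocols:
    @pytest.fixture(scope="class")
    def tiny_params(self):
        return ModelParams(m=1, gamma=0.1, K_cells=30, B0=0.05, K_total=1_500.0)

    def test_scan_flags_invalid_points_without_dropping(self, tiny_params):
        strats = [FragmentationStrategy(0.5, 0.5), FragmentationStrategy(0.4, 0.2)]
        res = strategy_scan(strats, tiny_params, replicates=1, seed=1,
                            n_groups=10, init_cells=14, t_max=150.0,
                            ma_window=50, check_window=50)
        assert len(res.table) == 2
        bad = res.table[~res.table["valid"]]
        assert len(bad) == 1 and bad["reason"].iloc[0] == "skipped"
        assert (0.4, 0.2) not in set(zip(res.aggregate.s, res.aggregate.n))

    def test_scan_aggregate_recomputable_from_rows(self, tiny_params):
        strats = [FragmentationStrategy(0.3, 0.6)]
        res = strategy_scan(strats, tiny_params, replicates=3, seed=2,
                            n_groups=10, init_cells=14, t_max=150.0,
                            ma_window=50, check_window=50)
        by_hand = res.table[res.table.valid].groupby(["s", "n"])["N_total"].mean()
        assert res.aggregate["N_total"].iloc[0] == pytest.approx(by_hand.iloc[0])

    def test_maxmu_descends_and_flags(self, tiny_params):
        # a schedule whose top value is survivable yields the ceiling flag
        res = max_mutation_rate(
            FragmentationStrategy(0.25, 0.75), tiny_params,
            schedule=np.array([1e-4, 1e-5]), replicates=2, seed=3,
            n_groups=10, init_cells=14, t_max=400.0, persistence="alive")
        per_rep = res.meta["per_replicate"]
        assert set(per_rep["flag"]) <= {"ceiling", "ok", "below_floor"}
        # rows stop at the first persisting mu of each replicate
        for rep, sub in res.table.groupby("replicate"):
            assert sub["persisted"].sum() <= 1
            if sub["persisted"].any():
                assert sub["persisted"].iloc[-1]

    def test_maxmu_requires_decreasing_schedule(self, tiny_params):
        with pytest.raises(ValueError):
            max_mutation_rate(FragmentationStrategy(0.5, 0.5), tiny_params,
                              schedule=np.array([0.1, 0.2]))

    def test_sweep_at_baseline_reproduces_plain_protocol(self, tiny_params):
        # a sigma sweep over the single baseline value is the plain mu_max
        # protocol, row for row
        from fragmodes import sensitivity_sweep

        strat = FragmentationStrategy(0.3, 0.6)
        sched = np.array([1e-3, 1e-4])
        kw = dict(schedule=sched, replicates=2, n_groups=8, init_cells=14,
                  t_max=200.0, persistence="alive")
        swept = sensitivity_sweep("sigma", [tiny_params.sigma], [strat],
                                  tiny_params, seed=5, **kw)
        sub_seed = int(np.random.Generator(np.random.PCG64(5)).integers(1, 2**31 - 1))
        plain = max_mutation_rate(strat, tiny_params, seed=sub_seed, **kw)
        pd.testing.assert_frame_equal(
            swept.table.drop(columns=["sigma"]), plain.table)

    def test_reproducible_tables(self, tiny_params):
        kw = dict(replicates=2, seed=9, n_groups=8, init_cells=14, t_max=120.0)
        a = strategy_scan([FragmentationStrategy(0.5, 0.5)], tiny_params, **kw)
        b = strategy_scan([FragmentationStrategy(0.5, 0.5)], tiny_params, **kw)
        pd.testing.assert_frame_equal(a.table, b.table)
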
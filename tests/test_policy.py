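"""Value grid estimation, time-cost arithmetic and stopping policies."""

import numpy as np
import pytest

from thinktime import (
    CostFamily,
    OfferSample,
    RunConfig,
    TimeControl,
    ValueGrid,
    build_value_grid,
    delta_t_max_analytic,
    delta_t_max_empirical,
    implied_mean_move_times,
    time_cost,
)
from thinktime.policy import InestimableCellError
from thinktime.simulate import generate_value_records


def analytic_grid(law, t_max=300.0, t_bin=3.0, u_bin=0.03, count=50):
    t_edges = np.arange(0.0, t_max + t_bin, t_bin)
    u_edges = u_bin * np.arange(int(np.ceil(1.0 / u_bin)) + 1)
    return ValueGrid.from_function(law, t_edges, u_edges, count=count)


class TestCostFamily:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CostFamily("linear", rho=0.0)
        with pytest.raises(ValueError):
            CostFamily("power", a=1.0, b=1.0)
        with pytest.raises(ValueError):
            CostFamily("quadratic", a=1.0, b=2.0)


class TestAnalyticPolicies:
    def test_linear_policy_value(self):
        fam = CostFamily("linear", rho=0.01)
        assert delta_t_max_analytic(fam, 100.0, 0.1) == pytest.approx(10.0, abs=1e-12)

    def test_power_policy_value(self):
        fam = CostFamily("power", a=1.0, b=2.0)
        assert delta_t_max_analytic(fam, 100.0, 0.25) == pytest.approx(0.5, abs=1e-12)

    def test_power_timeleft_policy_value(self):
        fam = CostFamily("power_timeleft", a=1.0, b=2.0)
        assert delta_t_max_analytic(fam, 100.0, 0.04) == pytest.approx(20.0, abs=1e-12)

    def test_power_timeleft_homogeneous_in_time(self, rng):
        fam = CostFamily("power_timeleft", a=0.5, b=3.0)
        for _ in range(20):
            T, duc, c = rng.uniform(1, 500), rng.uniform(0, 0.5), rng.uniform(0.1, 5)
            assert delta_t_max_analytic(fam, c * T, duc) == pytest.approx(
                c * delta_t_max_analytic(fam, T, duc)
            )

    def test_power_policy_concave_in_benefit(self):
        fam = CostFamily("power", a=0.001, b=2.0)
        ducs = np.linspace(0.01, 0.5, 30)
        vals = np.array([delta_t_max_analytic(fam, 100, d) for d in ducs])
        assert np.all(np.diff(vals) > 0)
        assert np.all(np.diff(np.diff(vals)) < 0)


class TestBuildValueGrid:
    def test_counts_match_brute_force_tally(self, rng, tc_300):
        law = lambda T, U: np.clip(0.2 + 0.5 * U + 0.001 * T, 0, 1)
        recs = generate_value_records(
            law, 1_000, tc_300, rng, t_range=(3, 60), u_range=(0.3, 0.7)
        )
        cfg = RunConfig(grid_min_count=1)
        grid = build_value_grid(recs, tc_300, cfg)
        wins = np.zeros_like(grid.wins)
        totals = np.zeros_like(grid.totals)
        for r in recs:  # independent tally, scalar loops only
            it = int(r.clock_before // 3.0)
            iu = int(r.consideration_set.moves[0].shallow // 0.03)
            totals[it, iu] += 1
            wins[it, iu] += {"win": 1.0, "draw": 0.5, "loss": 0.0}[r.outcome]
        assert np.array_equal(grid.totals, totals)
        assert np.array_equal(grid.wins, wins)

    def test_opponent_clock_filter(self, rng, tc_300):
        law = lambda T, U: np.full_like(np.asarray(T, dtype=float), 0.5)
        recs = generate_value_records(law, 50, tc_300, rng)
        recs[0].opponent_clock = 59.0
        grid = build_value_grid(recs, tc_300, RunConfig(grid_min_count=1))
        assert grid.totals.sum() == 49

    def test_ply_window_filter(self, rng, tc_300):
        law = lambda T, U: np.full_like(np.asarray(T, dtype=float), 0.5)
        recs = generate_value_records(law, 20, tc_300, rng, ply=76)
        with pytest.raises(ValueError, match="ply"):
            build_value_grid(recs, tc_300, RunConfig(grid_min_count=1))

    def test_single_hot_cell(self, rng, tc_300):
        law = lambda T, U: np.ones_like(np.asarray(T, dtype=float))
        recs = generate_value_records(
            law, 10, tc_300, rng, t_range=(10.0, 10.5), u_range=(0.50, 0.51)
        )
        grid = build_value_grid(recs, tc_300, RunConfig(grid_min_count=10))
        assert grid.estimable.sum() == 1
        assert grid.value(10.2, 0.505) == 1.0


class TestTimeCost:
    def test_same_bin_costs_nothing(self):
        grid = analytic_grid(lambda T, U: np.clip(U * (1 - np.exp(-T / 100)), 0, 1))
        assert time_cost(grid, 100.0, 0.5, 0.0) == 0.0

    def test_injected_law_matches_closed_form(self):
        law = lambda T, U: np.clip(U * (1 - np.exp(-T / 100.0)), 0, 1)
        grid = analytic_grid(law)
        # bin centres carry the law exactly, so the difference is exact
        t_hi, t_lo, u_c = 100.5, 70.5, 0.495
        expected = law(t_hi, u_c) - law(t_lo, u_c)
        assert time_cost(grid, 100.0, 0.5, 30.0) == pytest.approx(expected, abs=1e-12)

    def test_monotone_law_gives_nonnegative_cost(self, rng, tc_300):
        law = lambda T, U: np.clip(0.2 + 0.4 * U + 0.002 * T, 0, 1)
        recs = generate_value_records(
            law, 120_000, tc_300, rng, t_range=(3, 90), u_range=(0.4, 0.6)
        )
        grid = build_value_grid(recs, tc_300, RunConfig(grid_min_count=100))
        # binomial noise bound: with >= 100 moves per cell a negative cost
        # beyond ~4 pooled standard errors would falsify monotonicity
        for dt in (15.0, 30.0, 60.0):
            c = time_cost(grid, 80.0, 0.5, dt, mode="fallback")
            assert c >= -4 * np.sqrt(2 * 0.25 / 100)

    def test_inestimable_cell_error_carries_coordinates(self):
        grid = analytic_grid(lambda T, U: U)
        grid.totals[5, 10] = 0.0
        grid.wins[5, 10] = 0.0
        with pytest.raises(InestimableCellError) as exc:
            grid.value(5 * 3.0 + 1, 10 * 0.03 + 0.01, mode="strict")
        assert (exc.value.t_index, exc.value.u_index) == (5, 10)

    def test_fallback_uses_nearest_estimable_along_time_axis(self):
        grid = analytic_grid(lambda T, U: np.clip(0.2 + 0.001 * T, 0, 1))
        grid.totals[5, 10] = 0.0
        grid.wins[5, 10] = 0.0
        v = grid.value(5 * 3.0 + 1, 10 * 0.03 + 0.01)
        # nearest estimable neighbour along T (one bin away, tie toward less time)
        assert v == pytest.approx(0.2 + 0.001 * (4 * 3.0 + 1.5), abs=1e-12)


class TestDeltaTMaxEmpirical:
    def test_zero_benefit_on_strictly_increasing_value(self):
        grid = analytic_grid(lambda T, U: np.clip(0.3 + 0.002 * T, 0, 1))
        assert delta_t_max_empirical(grid, 150.0, 0.5, 0.0) == 0.0

    def test_hand_solved_linear_law(self):
        # V = U + 0.001*T on fine bins: spending dT is worth it while
        # 0.001*dT <= dUC, so dTmax = 50 s at dUC = 0.05
        law = lambda T, U: np.clip(U + 0.001 * T, 0, 1)
        t_edges = np.arange(0.0, 201.0, 1.0)
        u_edges = 0.001 * np.arange(0, 1002)
        grid = ValueGrid.from_function(law, t_edges, u_edges)
        got = delta_t_max_empirical(grid, 100.0, 0.4, 0.05)
        assert abs(got - 50.0) <= 1.0

    def test_weakly_increasing_in_benefit(self):
        law = lambda T, U: np.clip(U * (1 - 0.5 * np.exp(-T / 60.0)), 0, 1)
        grid = analytic_grid(law)
        vals = [
            delta_t_max_empirical(grid, 120.0, 0.5, d)
            for d in np.arange(0.0, 0.31, 0.03)
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_benefit_above_grid_top_clamps(self):
        grid = analytic_grid(lambda T, U: np.clip(U * (1 - 0.5 * np.exp(-T / 60)), 0, 1))
        a = delta_t_max_empirical(grid, 120.0, 0.9, 0.3)
        b = delta_t_max_empirical(grid, 120.0, 0.9, 3.0)
        assert a == b  # both land in the top advantage bin

    def test_contiguous_mode_is_no_larger(self, rng, tc_300):
        law = lambda T, U: np.clip(0.2 + 0.4 * U + 0.002 * T, 0, 1)
        recs = generate_value_records(
            law, 60_000, tc_300, rng, t_range=(3, 90), u_range=(0.4, 0.7)
        )
        grid = build_value_grid(recs, tc_300, RunConfig(grid_min_count=50))
        for d in (0.0, 0.06, 0.12):
            strict = delta_t_max_empirical(grid, 75.0, 0.5, d, contiguous=True)
            loose = delta_t_max_empirical(grid, 75.0, 0.5, d)
            assert strict <= loose


class TestImpliedMeanMoveTimes:
    def test_all_accepted_offers(self):
        fam = CostFamily("linear", rho=1e-6)  # accepts everything offered
        offers = [OfferSample(100.0, 0.5, float(t), 0.05) for t in (1, 2, 3)]
        cfg = RunConfig(motor_time=1.0)
        out = implied_mean_move_times(fam, offers, cfg)
        assert len(out) == 1
        assert out["mean_time"].iloc[0] == pytest.approx(1.0 + 2.0)

    def test_all_declined_offers(self):
        fam = CostFamily("linear", rho=1e9)
        offers = [OfferSample(100.0, 0.5, float(t), 0.05) for t in (1, 2, 3)]
        cfg = RunConfig(motor_time=0.7)
        out = implied_mean_move_times(fam, offers, cfg)
        assert out["mean_time"].iloc[0] == pytest.approx(0.7)

    def test_enumerated_mixed_offers(self):
        # linear policy rho=0.01: dTmax = 100*dUC seconds
        fam = CostFamily("linear", rho=0.01)
        offers = []
        for duc, dtcs in [
            (0.010, [0.5, 1.5, 2.0, 9.0]),  # limit 1.0 -> accept only 0.5
            (0.040, [1.0, 3.0, 5.0, 9.0]),  # limit 4.0 -> accept 1 and 3
            (0.130, [2.0, 6.0, 12.0, 14.0]),  # limit 13 -> accept 2, 6, 12
        ]:
            offers += [OfferSample(100.0, 0.5, t, duc) for t in dtcs]
        out = implied_mean_move_times(fam, offers, RunConfig(motor_time=0.0))
        means = dict(zip(out["duc_bin_left"], out["mean_time"]))
        assert means[0.0] == pytest.approx(0.5 / 4)
        assert means[0.03] == pytest.approx((1.0 + 3.0) / 4)
        assert means[0.12] == pytest.approx((2.0 + 6.0 + 12.0) / 4)

    def test_empty_offers_rejected(self):
        with pytest.raises(ValueError):
            implied_mean_move_times(CostFamily("linear", rho=1.0), [])


class TestValueGridSerialization:
    def test_save_load_round_trip(self, tmp_path):
        grid = analytic_grid(lambda T, U: np.clip(0.2 + 0.5 * U, 0, 1), t_max=30.0)
        path = tmp_path / "grid.csv"
        grid.save(path)
        back = ValueGrid.load(path)
        assert back.time_control == grid.time_control
        assert back.min_count == grid.min_count
        assert np.allclose(back.wins, grid.wins)
        assert np.allclose(back.totals, grid.totals)
        assert np.allclose(back.time_edges, grid.time_edges)
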
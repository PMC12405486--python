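"""Distribution fitting, OWSA, PSA, CEAC and price-threshold search."""

import numpy as np
import pytest

from rheumcea import evaluate_all, evaluate_strategy
from rheumcea.frontier import icer
from rheumcea.parameters import uncertainty_parameters
from rheumcea.sensitivity import (
    ceac,
    fit_distribution,
    owsa,
    pairwise_scatter,
    price_threshold,
    run_psa,
)

from conftest import degenerate_config


class TestFitDistribution:
    def test_gamma_moments_recovered(self):
        dist = fit_distribution(45.0, 22.5, 67.5, "gamma", "cost")
        assert dist.mean == pytest.approx(45.0)
        assert dist.sd == pytest.approx(45.0 / 3.9199, abs=0.01)  # ~11.48
        rng = np.random.default_rng(0)
        draws = dist.rvs(rng, 100_000)
        assert np.mean(draws) == pytest.approx(45.0, rel=0.01)
        assert np.std(draws) == pytest.approx(dist.sd, rel=0.01)

    def test_beta_moments_recovered(self):
        dist = fit_distribution(0.43, 0.3225, 0.5375, "beta", "p")
        rng = np.random.default_rng(1)
        draws = dist.rvs(rng, 100_000)
        assert np.mean(draws) == pytest.approx(0.43, rel=0.01)
        assert np.std(draws) == pytest.approx(dist.sd, rel=0.01)
        assert np.all((draws > 0) & (draws < 1))

    def test_normal_moments_recovered(self):
        dist = fit_distribution(0.72, 0.54, 0.90, "normal", "u")
        rng = np.random.default_rng(2)
        draws = dist.rvs(rng, 100_000)
        assert np.mean(draws) == pytest.approx(0.72, rel=0.01)
        assert np.std(draws) == pytest.approx((0.90 - 0.54) / (2 * 1.96), rel=0.01)

    def test_degenerate_range_is_point_mass(self):
        dist = fit_distribution(5.0, 5.0, 5.0, "gamma", "x")
        assert dist.family == "point"
        rng = np.random.default_rng(3)
        assert np.all(dist.rvs(rng, 10) == 5.0)

    def test_infeasible_beta_sd_raises_with_name(self):
        with pytest.raises(ValueError, match="narrow_p"):
            fit_distribution(0.01, -1.0, 1.03, "beta", "narrow_p")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            fit_distribution(1.0, 0.5, 1.5, "lognormal", "x")


class TestOwsa:
    def test_entries_sorted_by_spread_and_bracket_base(self, zanzibar):
        entries = owsa(
            zanzibar, ["cost.btsdmard1", "cost.clinic_visit"], pair=(1, 3)
        )
        assert entries[0].parameter == "cost.btsdmard1"
        assert entries[0].spread >= entries[1].spread
        for e in entries:
            if not e.non_monotone:
                lo = min(e.icer_at_low, e.icer_at_high)
                hi = max(e.icer_at_low, e.icer_at_high)
                assert lo <= e.icer_base <= hi

    def test_biologic_price_at_low_bound_lowers_icer(self, zanzibar):
        [entry] = owsa(zanzibar, ["cost.btsdmard1"], pair=(1, 3))
        assert entry.icer_at_low < entry.icer_base < entry.icer_at_high

    def test_parameter_unused_by_pair_leaves_icer_unchanged(self, zanzibar):
        [entry] = owsa(zanzibar, ["cost.btsdmard2"], pair=(1, 3))
        assert entry.icer_at_low == pytest.approx(entry.icer_base)
        assert entry.icer_at_high == pytest.approx(entry.icer_base)

    def test_zero_range_parameter_collapses_to_base(self, zanzibar):
        # the Zanzibar rescue supplement has a degenerate (0, 0) range
        [entry] = owsa(zanzibar, ["cost.rescue_supplement"], pair=(1, 3))
        assert entry.icer_at_low == entry.icer_at_high == entry.icer_base

    def test_bounds_equal_direct_recomputation(self, zanzibar):
        name = "utility.hda"
        [entry] = owsa(zanzibar, [name], pair=(1, 3))
        cfg = zanzibar.copy()
        p = uncertainty_parameters(cfg)[name]
        p.set(cfg, p.get(cfg).high)
        a = evaluate_strategy(cfg.strategy(1), cfg, keep_trace=False)
        b = evaluate_strategy(cfg.strategy(3), cfg, keep_trace=False)
        assert entry.icer_at_high == pytest.approx(icer(a, b), rel=1e-12)

    def test_unknown_parameter_rejected(self, zanzibar):
        with pytest.raises(KeyError, match="nonsense"):
            owsa(zanzibar, ["cost.nonsense"], pair=(1, 3))


class TestRunPsa:
    def test_degenerate_distributions_reproduce_deterministic_run(self, zanzibar):
        cfg = degenerate_config(zanzibar)
        samples = run_psa(cfg, n_iterations=5, seed=9)
        base = {o.strategy_id: o for o in evaluate_all(cfg)}
        for j, sid in enumerate(samples.strategy_ids):
            assert np.allclose(samples.costs[:, j], base[sid].cost)
            assert np.allclose(samples.qalys[:, j], base[sid].qalys)

    def test_seeded_reproducibility(self, zanzibar):
        a = run_psa(zanzibar, 20, seed=5)
        b = run_psa(zanzibar, 20, seed=5)
        c = run_psa(zanzibar, 20, seed=6)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        assert not np.array_equal(a.costs, c.costs)

    def test_sample_ranges_plausible(self, zanzibar):
        samples = run_psa(zanzibar, 100, seed=7)
        assert np.all(samples.costs > 0)
        horizon_max = (
            zanzibar.econ.horizon_years * 1.0
        )  # utilities truncated at full health
        assert np.all(samples.qalys > 0)
        assert np.all(samples.qalys <= horizon_max)

    def test_mean_outcomes_converge_toward_larger_run(self, zanzibar):
        small = run_psa(zanzibar, 300, seed=11)
        large = run_psa(zanzibar, 3000, seed=12)
        assert np.allclose(
            small.costs.mean(axis=0), large.costs.mean(axis=0), rtol=0.10
        )
        assert np.allclose(
            small.qalys.mean(axis=0), large.qalys.mean(axis=0), rtol=0.03
        )

    def test_dirichlet_profile_sampling_runs(self, zanzibar):
        samples = run_psa(zanzibar, 20, seed=13, profile_sampling="dirichlet")
        assert samples.costs.shape == (20, 6)


@pytest.fixture(scope="module")
def samples(zanzibar):
    return run_psa(zanzibar, 400, seed=21)


class TestCeacAndScatter:

    def test_probabilities_sum_to_one_at_every_wtp(self, samples):
        frame = ceac(samples, [0, 282, 1136, 2272, 10_000])
        for _, sub in frame.groupby("wtp"):
            assert sub["p_optimal"].sum() == pytest.approx(1.0)

    def test_wtp_zero_matches_probability_of_being_cheapest(self, samples):
        frame = ceac(samples, [0.0])
        cheapest_counts = np.bincount(
            np.argmin(samples.costs, axis=1), minlength=len(samples.strategy_ids)
        )
        for j, sid in enumerate(samples.strategy_ids):
            p = float(
                frame[(frame.wtp == 0) & (frame.strategy == sid)]["p_optimal"].iloc[0]
            )
            assert p == pytest.approx(cheapest_counts[j] / samples.n_iterations)

    def test_scatter_share_matches_manual_count(self, samples):
        summary = pairwise_scatter(samples, (1, 3), wtp=282.0)
        d_cost = summary.points["d_cost"].to_numpy()
        d_q = summary.points["d_qalys"].to_numpy()
        manual = np.mean(d_q * 282.0 - d_cost > 0)
        assert summary.share_favoring == pytest.approx(manual)
        assert len(summary.points) == samples.n_iterations


class TestPriceThreshold:
    def test_threshold_is_fixed_point_of_icer(self, zanzibar):
        result = price_threshold(zanzibar, "btsdmard1", (1, 3), wtp=282.0)
        assert result.threshold_price is not None
        assert abs(result.icer_at_threshold - 282.0) <= 0.5
        # re-running the model at the returned price reproduces the ICER
        cfg = zanzibar.copy()
        cfg.drugs["btsdmard1"].cost_override = result.threshold_price
        a = evaluate_strategy(cfg.strategy(1), cfg, keep_trace=False)
        b = evaluate_strategy(cfg.strategy(3), cfg, keep_trace=False)
        assert abs(icer(a, b) - 282.0) <= 0.5

    def test_agrees_with_dense_grid_scan(self, zanzibar):
        result = price_threshold(zanzibar, "triple_therapy", (1, 2), wtp=282.0)
        prices = np.linspace(0.0, result.base_price, 2000)

        def icer_at(price):
            cfg = zanzibar.copy()
            cfg.drugs["triple_therapy"].cost_override = float(price)
            a = evaluate_strategy(cfg.strategy(1), cfg, keep_trace=False)
            b = evaluate_strategy(cfg.strategy(2), cfg, keep_trace=False)
            return icer(a, b)

        icers = np.array([icer_at(p) for p in prices[:: len(prices) // 40]])
        grid = prices[:: len(prices) // 40]
        crossing = grid[np.argmin(np.abs(icers - 282.0))]
        assert result.threshold_price == pytest.approx(
            crossing, abs=result.base_price / 40
        )

    def test_expensive_second_biologic_has_no_threshold(self, zanzibar):
        result = price_threshold(zanzibar, "btsdmard2", (1, 6), wtp=282.0)
        assert result.threshold_price is None

    def test_drug_unused_by_effective_strategy_rejected(self, zanzibar):
        with pytest.raises(ValueError, match="not used"):
            price_threshold(zanzibar, "btsdmard2", (1, 3), wtp=282.0)

    def test_unknown_drug_rejected(self, zanzibar):
        with pytest.raises(KeyError):
            price_threshold(zanzibar, "aspirin", (1, 3), wtp=282.0)
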
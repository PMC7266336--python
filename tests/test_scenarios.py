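"""Scenario generation: distribution calibration, samplers, trees."""

import numpy as np
import pytest
from scipy import stats

from irriplan.scenarios import (
    TABLE1_DAILY_MEAN_IN,
    TABLE1_DAILY_VARIANCE_IN2,
    TABLE1_WEEKLY_MEAN_IN,
    PrecipWeekModel,
    PriceModel,
    ScenarioFan,
    WaterLimitModel,
    calibrate_wet_probability,
    construct_tree,
    default_precip_models,
    default_price_model,
    default_water_limit_model,
    ev_realization,
    fit_gamma_moments,
    sample_price,
    sample_scenario_fan,
    sample_water_limit,
    simulate_weekly_precipitation,
    single_scenario_tree,
    tree_from_fan,
)
from irriplan.types import Realization
from irriplan.units import convert


class TestGammaMoments:
    def test_week1_parameters(self):
        shape, scale = fit_gamma_moments(0.44, 0.15)
        assert shape == pytest.approx(0.44**2 / 0.15, rel=1e-12)
        assert scale == pytest.approx(0.15 / 0.44, rel=1e-12)
        assert (shape, scale) == pytest.approx((1.2907, 0.3409), abs=1e-4)

    def test_unit_exponential(self):
        assert fit_gamma_moments(1.0, 1.0) == (1.0, 1.0)

    def test_moments_reproduced_exactly(self):
        for mean, var in zip(TABLE1_DAILY_MEAN_IN, TABLE1_DAILY_VARIANCE_IN2):
            shape, scale = fit_gamma_moments(mean, var)
            assert shape * scale == pytest.approx(mean, rel=1e-12)
            assert shape * scale**2 == pytest.approx(var, rel=1e-12)

    def test_week1_median_near_printed(self):
        shape, scale = fit_gamma_moments(0.44, 0.15)
        med = stats.gamma.ppf(0.5, shape, scale=scale)
        assert 0.33 <= med <= 0.34

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_gamma_moments(0.0, 0.1)
        with pytest.raises(ValueError):
            fit_gamma_moments(0.4, -0.1)


class TestWetProbability:
    @pytest.mark.parametrize(
        "daily,weekly,expected",
        [(0.44, 0.73, 0.73 / (7 * 0.44)),   # week 1 -> 0.2370
         (0.34, 0.38, 0.38 / (7 * 0.34)),   # week 8 -> 0.1597
         (0.5, 0.0, 0.0)],
    )
    def test_calibration(self, daily, weekly, expected):
        assert calibrate_wet_probability(daily, weekly) == pytest.approx(
            expected, abs=1e-4
        )

    def test_clipped_at_one(self):
        assert calibrate_wet_probability(0.1, 10.0) == 1.0

    def test_expected_weekly_total_matches_calibration(self):
        for mu, wk in zip(TABLE1_DAILY_MEAN_IN, TABLE1_WEEKLY_MEAN_IN):
            p = calibrate_wet_probability(mu, wk)
            assert 7 * p * mu == pytest.approx(wk, rel=1e-12)


class TestPrecipSimulation:
    def test_weekly_means_match_calibration(self):
        models = default_precip_models()
        sim = simulate_weekly_precipitation(models, 20_000, seed=42)
        means_in = np.array([convert(v, "m", "inch") for v in sim.mean(axis=0)])
        se_in = np.array(
            [convert(v, "m", "inch") for v in sim.std(axis=0, ddof=1)]
        ) / np.sqrt(sim.shape[0])
        z = np.abs(means_in - np.array(TABLE1_WEEKLY_MEAN_IN)) / se_in
        # all eight weeks within 3 standard errors of their targets
        assert np.all(z < 3.0), f"z-scores {z}"

    def test_dry_model_gives_zeros(self):
        dry = tuple(
            PrecipWeekModel(0.01, 1e-4, wet_prob=0.0) for _ in range(4)
        )
        assert np.all(simulate_weekly_precipitation(dry, 50, seed=0) == 0.0)

    def test_weekly_variance_compound_bernoulli(self):
        # var of a week total = 7 p (sigma^2 + (1-p) mu^2) under independence
        m = PrecipWeekModel(0.012, 9e-5, wet_prob=0.3)
        sim = simulate_weekly_precipitation((m,), 40_000, seed=7)[:, 0]
        expected = 7 * 0.3 * (9e-5 + 0.7 * 0.012**2)
        assert np.var(sim, ddof=1) == pytest.approx(expected, rel=0.05)

    def test_bit_reproducible_under_seed(self):
        models = default_precip_models()
        a = simulate_weekly_precipitation(models, 100, seed=5)
        b = simulate_weekly_precipitation(models, 100, seed=5)
        assert np.array_equal(a, b)

    def test_persistence_changes_occurrence_not_mean(self):
        base = PrecipWeekModel(0.012, 9e-5, wet_prob=0.3)
        sticky = PrecipWeekModel(0.012, 9e-5, wet_prob=0.3, persistence=0.5)
        a = simulate_weekly_precipitation((base,), 40_000, seed=3)[:, 0]
        b = simulate_weekly_precipitation((sticky,), 40_000, seed=3)[:, 0]
        assert np.mean(b) == pytest.approx(np.mean(a), rel=0.05)
        assert np.var(b, ddof=1) > np.var(a, ddof=1)  # clustering adds variance


class TestPriceAndWaterSamplers:
    def test_price_mean_and_sd(self):
        model = default_price_model(3.6)
        draws = sample_price(model, 20_000, seed=11)
        mean_bu = convert(float(np.mean(draws)), "usd_per_kg", "usd_per_bushel")
        sd_bu = convert(float(np.std(draws, ddof=1)), "usd_per_kg", "usd_per_bushel")
        se = 0.34 / np.sqrt(20_000)
        assert abs(mean_bu - 3.45) < 2 * se
        assert sd_bu == pytest.approx(0.34, rel=0.03)

    def test_degenerate_price(self):
        model = PriceModel(april_price=0.14, mean_shift=0.0, sd=0.0)
        assert np.all(sample_price(model, 10, seed=0) == 0.14)

    def test_negative_draws_floored(self):
        model = PriceModel(april_price=0.0, mean_shift=0.0, sd=1.0)
        assert np.min(sample_price(model, 1000, seed=0)) >= 0.0

    def test_water_limit_bounds_and_mean(self):
        model = default_water_limit_model()
        area = convert(150.0, "acre", "m2")
        draws = sample_water_limit(model, 20_000, seed=13, area=area)
        per_acre_in = np.array([
            convert(v, "m3", "acre_inch") / 150.0 for v in draws
        ])
        assert per_acre_in.min() >= 11.0 - 1e-9
        assert per_acre_in.max() <= 14.9 + 1e-9
        se = (14.9 - 11.0) / np.sqrt(12 * 20_000)
        assert abs(per_acre_in.mean() - 12.95) < 3 * se

    def test_constant_water_limit(self):
        model = WaterLimitModel(lower=0.3, upper=0.3)
        assert np.all(sample_water_limit(model, 5, seed=0, area=2.0) == 0.6)


class TestScenarioFan:
    def test_single_path(self):
        fan = sample_scenario_fan(
            default_price_model(), default_water_limit_model(),
            default_precip_models(), 1, seed=0, area=1e5,
        )
        assert fan.n_scenarios == 1
        assert fan.probabilities[0] == 1.0

    def test_probabilities_sum_to_one(self):
        for n in (3, 17, 200):
            fan = sample_scenario_fan(
                default_price_model(), default_water_limit_model(),
                default_precip_models(), n, seed=1, area=1e5,
            )
            assert float(np.sum(fan.probabilities)) == pytest.approx(1.0, abs=1e-12)

    def test_component_means_match_models(self):
        price, water = default_price_model(), default_water_limit_model()
        precip = default_precip_models()
        area = 6.07e5
        fan = sample_scenario_fan(price, water, precip, 5000, seed=2, area=area)
        assert np.mean(fan.prices) == pytest.approx(price.mean, rel=0.01)
        assert np.mean(fan.water_limits) == pytest.approx(water.mean * area, rel=0.01)
        assert np.mean(fan.precipitation[:, 0]) == pytest.approx(
            precip[0].weekly_mean, rel=0.05
        )

    def test_frame_round_trip(self):
        fan = sample_scenario_fan(
            default_price_model(), default_water_limit_model(),
            default_precip_models(), 7, seed=3, area=1e5,
        )
        back = ScenarioFan.from_frame(fan.to_frame())
        assert np.array_equal(back.prices, fan.prices)
        assert np.array_equal(back.precipitation, fan.precipitation)


class TestEvRealization:
    def test_table_weekly_averages(self):
        real = ev_realization(
            default_price_model(3.6), default_water_limit_model(),
            default_precip_models(), area=1.0,
        )
        precip_in = [convert(v, "m", "inch") for v in real.precipitation]
        assert precip_in[0] == pytest.approx(0.73, abs=1e-9)
        assert precip_in[7] == pytest.approx(0.38, abs=1e-9)
        assert convert(real.price, "usd_per_kg", "usd_per_bushel") == pytest.approx(
            3.45, abs=1e-9
        )

    def test_degenerate_models_give_support_point(self):
        price = PriceModel(april_price=0.2, mean_shift=0.0, sd=1e-12)
        water = WaterLimitModel(lower=0.3, upper=0.3)
        precip = tuple(PrecipWeekModel(0.01, 1e-4, 0.0) for _ in range(2))
        real = ev_realization(price, water, precip, area=10.0)
        assert real.price == pytest.approx(0.2)
        assert real.water_limit == pytest.approx(3.0)
        assert np.all(real.precipitation == 0.0)


def _fig2_fan():
    """Two distinct (price, limit) pairs, each with two R_1 branches."""
    return ScenarioFan(
        prices=np.array([0.10, 0.10, 0.20, 0.20]),
        water_limits=np.array([1e5, 1e5, 2e5, 2e5]),
        precipitation=np.array([
            [0.00, 0.01], [0.02, 0.01], [0.00, 0.03], [0.02, 0.03],
        ]),
        probabilities=np.full(4, 0.25),
    )


class TestTreeConstruction:
    def test_chain_from_all_ones(self):
        fan = sample_scenario_fan(
            default_price_model(), default_water_limit_model(),
            default_precip_models(), 20, seed=4, area=1e5,
        )
        tree = construct_tree(fan, (1,) * 8)
        assert tree.n_scenarios == 1
        assert tree.scenario_probs[0] == pytest.approx(1.0)
        # the chain is an actually-sampled path (the L1 medoid)
        real = tree.scenario_realization(0)
        assert any(abs(real.price - p) < 1e-15 for p in fan.prices)

    def test_fig2_shape_three_stages_four_scenarios(self):
        tree = construct_tree(_fig2_fan(), (2, 2))
        assert tree.n_stages == 3          # root + 2 observation stages
        assert tree.n_scenarios == 4
        # after the price/limit observation the scenarios bundle {0,1},{2,3}
        bundles = sorted(tuple(b) for b in tree.bundles(1))
        assert bundles == [(0, 1), (2, 3)]
        # after observing R_1 every scenario is distinguished
        assert sorted(tuple(b) for b in tree.bundles(2)) == [(0,), (1,), (2,), (3,)]

    @pytest.mark.parametrize("seed", range(10))
    def test_probability_conserved_and_bundles_refine(self, seed):
        fan = sample_scenario_fan(
            default_price_model(), default_water_limit_model(),
            default_precip_models(), 40, seed=seed, area=1e5,
        )
        tree = construct_tree(fan, (3, 2, 2))
        assert float(np.sum(tree.scenario_probs)) == pytest.approx(1.0, abs=1e-12)
        assert tree.n_scenarios <= 3 * 2 * 2
        nas = tree.node_at_stage
        for t in range(1, tree.n_periods + 1):
            # scenarios sharing a stage-t node share the stage-(t-1) node
            for node in np.unique(nas[:, t]):
                members = nas[:, t] == node
                assert len(np.unique(nas[members, t - 1])) == 1

    def test_tree_from_fan_is_lossless(self):
        fan = sample_scenario_fan(
            default_price_model(), default_water_limit_model(),
            default_precip_models(), 12, seed=9, area=1e5,
        )
        tree = tree_from_fan(fan)
        assert tree.n_scenarios == 12
        back = tree.as_fan()
        assert np.allclose(sorted(back.prices), sorted(fan.prices))

    def test_single_scenario_tree_collapses(self):
        real = Realization(price=0.14, water_limit=1e5,
                           precipitation=np.full(8, 0.01))
        tree = single_scenario_tree(real)
        assert tree.n_scenarios == 1
        got = tree.scenario_realization(0)
        assert got.price == real.price
        assert np.allclose(got.precipitation, real.precipitation)

    def test_construction_deterministic(self):
        fan = sample_scenario_fan(
            default_price_model(), default_water_limit_model(),
            default_precip_models(), 30, seed=6, area=1e5,
        )
        a = construct_tree(fan, (3, 2)).to_frame()
        b = construct_tree(fan, (3, 2)).to_frame()
        assert a.equals(b)

    def test_branching_too_large_rejected(self):
        with pytest.raises(ValueError, match="leaves"):
            construct_tree(_fig2_fan(), (4, 2))
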
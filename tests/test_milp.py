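"""MILP builders and solver contract.

The central correctness surface is the agreement between the MILP optimum
and the brute-force enumeration oracle on tiny instances, plus the
structural theorems relating the deterministic, two-stage and multistage
optima on scenario trees.
"""

import numpy as np
import pytest

from irriplan import milp
from irriplan.fixtures import (
    brute_force_solve,
    fixture_toy_instance,
    fixture_toy_models,
    TinyInstance,
)
from irriplan.scenarios import (
    ScenarioFan,
    construct_tree,
    sample_scenario_fan,
    single_scenario_tree,
)
from irriplan.types import (
    DecisionPlan,
    FarmInstance,
    ManagementOption,
    Realization,
    validate_instance,
)

from conftest import random_realization


def _toy_with_real(seed):
    tiny = fixture_toy_instance(seed)
    price, water, _ = fixture_toy_models(tiny, seed)
    real = Realization(**random_realization(tiny.instance, price, water, seed + 900))
    return tiny, real


def _toy_tree(seed, n=12, branching=(3, 2)):
    tiny = fixture_toy_instance(seed)
    price, water, precip = fixture_toy_models(tiny, seed)
    fan = sample_scenario_fan(price, water, precip, n, seed, tiny.instance.area)
    T = tiny.instance.n_periods
    return tiny.instance, construct_tree(fan, branching + (1,) * (T - len(branching)))


class TestSolverContract:
    def test_empty_model_objective_zero(self):
        spec = milp.ModelSpec()
        spec.add_var("u", 0.0, 1.0)
        sol = milp.solve(spec)
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_reported(self):
        tiny, real = _toy_with_real(0)
        inst = tiny.instance
        # a yield mandate above any attainable farm yield
        max_yield = max(o.max_yield for o in inst.options) * inst.area
        from dataclasses import replace
        bad = replace(inst, min_yield=10.0 * max_yield)
        sol = milp.solve(milp.build_deterministic(bad, real))
        assert sol.status == "infeasible"

    @pytest.mark.parametrize("seed", [1, 4, 9])
    def test_backends_agree(self, seed):
        tiny, real = _toy_with_real(seed)
        spec = milp.build_deterministic(tiny.instance, real)
        a = milp.solve(spec, backend="highs")
        b = milp.solve(spec, backend="branch-and-bound")
        assert a.status == "optimal" and b.status == "optimal"
        assert b.objective == pytest.approx(a.objective, rel=1e-5)

    def test_solution_satisfies_constraints(self):
        tiny, real = _toy_with_real(2)
        spec = milp.build_deterministic(tiny.instance, real)
        sol = milp.solve(spec)
        assert spec.constraint_violation(sol.x) < 1e-6

    def test_lp_dump_contains_structure(self):
        tiny, real = _toy_with_real(0)
        spec = milp.build_deterministic(tiny.instance, real)
        text = spec.to_lp_string()
        assert text.startswith("Maximize")
        assert "Binaries" in text and "x[0]" in text


class TestDeterministicModel:
    def test_no_water_forces_deficit_floor(self):
        # no rain, no allocation: ET = 0, level D = 0, yield = Ym (1 - K)
        opt = ManagementOption(0, 0.0, 0.01, 1.0, 0.6)
        inst = validate_instance(FarmInstance(
            area=1000.0, efficiency=0.9, holding_capacity=0.08,
            pre_irrigation=0.0, water_cost=0.1, fixed_irrigation_cost=0.0,
            overhead=0.0, min_yield=0.0, options=(opt,),
            max_et=np.array([0.04, 0.04]), deficit_grid=np.linspace(0, 1, 5),
            n_periods=2,
        ))
        real = Realization(price=0.5, water_limit=0.0, precipitation=np.zeros(2))
        spec = milp.build_deterministic(inst, real)
        sol = milp.solve(spec)
        assert sol.status == "optimal"
        plan, traj = milp.extract_plan(sol, spec)
        assert np.all(plan.irrigation == pytest.approx(0.0, abs=1e-9))
        assert traj.deficit_index == 0
        assert traj.actual_yield == pytest.approx(1.0 * (1 - 0.6), abs=1e-6)
        assert np.all(traj.actual_et == pytest.approx(0.0, abs=1e-8))

    def test_penultimate_level_pins_et_ratio(self):
        # forcing the level below full satisfaction pins the season ET sum
        # to 0.99 of the unstressed total (within the half-step tolerance)
        tiny, real = _toy_with_real(3)
        inst = tiny.instance
        from dataclasses import replace
        inst101 = validate_instance(replace(
            inst, deficit_grid=np.linspace(0, 1, 101),
            water_cost=0.0, pre_irrigation=0.0,
        ))
        rich = Realization(price=real.price, water_limit=1e12,
                           precipitation=np.full(inst.n_periods, 0.2))
        spec = milp.build_deterministic(inst101, rich)
        # pin d at the level whose grid value is 0.99
        for name, idx in zip(spec.var_names, range(spec.n_vars)):
            if name == "d[99]":
                spec.lb[idx] = spec.ub[idx] = 1.0
        sol = milp.solve(spec)
        assert sol.status == "optimal"
        eta = sum(sol.value(spec, f"ETa[{t}]") for t in range(1, inst.n_periods + 1))
        et_total = float(np.sum(inst101.max_et))
        assert eta / et_total == pytest.approx(0.99, abs=0.005 + 1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_mip_dominates_grid_oracle(self, seed):
        tiny, real = _toy_with_real(seed)
        obj_oracle, _ = brute_force_solve(tiny, real)
        sol = milp.solve(milp.build_deterministic(tiny.instance, real))
        assert sol.status == "optimal"
        assert sol.objective >= obj_oracle - 1e-6

    @pytest.mark.parametrize("seed", range(8))
    def test_mip_equals_oracle_on_augmented_grid(self, seed):
        # adding the MIP's own schedule to the oracle grid closes the gap
        tiny, real = _toy_with_real(seed)
        spec = milp.build_deterministic(tiny.instance, real)
        sol = milp.solve(spec)
        plan, _ = milp.extract_plan(sol, spec)
        grid = tuple(sorted(set(tiny.y_grid) | {float(v) for v in plan.irrigation}))
        obj_oracle, _ = brute_force_solve(
            TinyInstance(instance=tiny.instance, y_grid=grid), real
        )
        assert obj_oracle == pytest.approx(sol.objective, rel=1e-6, abs=1e-6)

    def test_extracted_profit_reconstructs_objective(self):
        tiny, real = _toy_with_real(5)
        spec = milp.build_deterministic(tiny.instance, real)
        sol = milp.solve(spec)
        _, traj = milp.extract_plan(sol, spec)
        assert traj.profit == pytest.approx(sol.objective, rel=1e-9, abs=1e-6)

    def test_water_balance_at_solution(self):
        tiny, real = _toy_with_real(6)
        inst = tiny.instance
        spec = milp.build_deterministic(inst, real)
        sol = milp.solve(spec)
        plan, traj = milp.extract_plan(sol, spec)
        M = np.append(traj.soil_moisture, np.nan)
        for t in range(inst.n_periods - 1):
            resid = (M[t] + plan.irrigation[t] + real.precipitation[t]
                     - traj.actual_et[t] - traj.leaching[t] - M[t + 1])
            assert resid == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_water_limit_and_price(self):
        tiny, real = _toy_with_real(7)
        inst = tiny.instance
        objs = []
        for f in (0.2, 0.5, 1.0, 2.0):
            r = Realization(price=real.price, water_limit=f * real.water_limit,
                            precipitation=real.precipitation)
            objs.append(milp.solve(milp.build_deterministic(inst, r)).objective)
        assert all(b >= a - 1e-6 for a, b in zip(objs, objs[1:]))
        objs = []
        for f in (0.5, 1.0, 1.5):
            r = Realization(price=f * real.price, water_limit=real.water_limit,
                            precipitation=real.precipitation)
            objs.append(milp.solve(milp.build_deterministic(inst, r)).objective)
        assert all(b >= a - 1e-6 for a, b in zip(objs, objs[1:]))


class TestStochasticModels:
    @pytest.mark.parametrize("build", [milp.build_twostage, milp.build_multistage])
    def test_single_scenario_collapse(self, build):
        tiny, real = _toy_with_real(1)
        det = milp.solve(milp.build_deterministic(tiny.instance, real)).objective
        tree = single_scenario_tree(real)
        sto = milp.solve(build(tiny.instance, tree)).objective
        assert sto == pytest.approx(det, rel=1e-6, abs=1e-6)

    def test_duplicated_scenario_invariance(self):
        tiny, real = _toy_with_real(2)
        inst = tiny.instance
        T = inst.n_periods
        single = single_scenario_tree(real)
        double = construct_tree(ScenarioFan(
            prices=np.array([real.price] * 2),
            water_limits=np.array([real.water_limit] * 2),
            precipitation=np.tile(real.precipitation, (2, 1)),
            probabilities=np.array([0.5, 0.5]),
        ), (1,) * T)
        a = milp.solve(milp.build_multistage(inst, single)).objective
        b = milp.solve(milp.build_multistage(inst, double)).objective
        assert b == pytest.approx(a, rel=1e-6, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_multistage_at_least_twostage(self, seed):
        inst, tree = _toy_tree(seed)
        ts = milp.solve(milp.build_twostage(inst, tree)).objective
        ms = milp.solve(milp.build_multistage(inst, tree)).objective
        assert ms >= ts - 1e-5 * max(1.0, abs(ts))

    @pytest.mark.parametrize("build", [milp.build_twostage, milp.build_multistage])
    @pytest.mark.parametrize("seed", [0, 5])
    def test_node_and_explicit_formulations_agree(self, seed, build):
        inst, tree = _toy_tree(seed, n=8, branching=(2, 2))
        a = milp.solve(build(inst, tree, nonanticipativity="node")).objective
        b = milp.solve(build(inst, tree, nonanticipativity="explicit")).objective
        assert b == pytest.approx(a, rel=1e-6, abs=1e-6)

    def test_twostage_equals_multistage_without_precip_uncertainty(self):
        # singleton price/limit bundles + common precipitation: no residual
        # uncertainty after stage 1, the two decision processes coincide
        tiny, real = _toy_with_real(4)
        inst = tiny.instance
        T = inst.n_periods
        precip = np.tile(real.precipitation, (3, 1))
        fan = ScenarioFan(
            prices=np.array([0.8, 1.0, 1.2]) * real.price,
            water_limits=np.array([0.8, 1.0, 1.2]) * real.water_limit,
            precipitation=precip,
            probabilities=np.full(3, 1 / 3),
        )
        tree = construct_tree(fan, (3,) + (1,) * (T - 1))
        ts = milp.solve(milp.build_twostage(inst, tree)).objective
        ms = milp.solve(milp.build_multistage(inst, tree)).objective
        assert ts == pytest.approx(ms, rel=1e-6, abs=1e-6)

    def test_stochastic_extraction_consistency(self):
        inst, tree = _toy_tree(6)
        spec = milp.build_multistage(inst, tree)
        sol = milp.solve(spec)
        plan = milp.extract_plan(sol, spec)
        assert plan.option_choice.sum() == 1
        # scenario trajectories reconstruct the probability-weighted objective
        assert plan.expected_profit == pytest.approx(sol.objective, rel=1e-6)
        # nonanticipativity: scenarios sharing a stage-t node share y_t
        nas = tree.node_at_stage
        for t in range(1, tree.n_periods + 1):
            for node in np.unique(nas[:, t]):
                members = np.where(nas[:, t] == node)[0]
                ys = {round(float(plan.scenario_plans[w].irrigation[t - 1]), 9)
                      for w in members}
                assert len(ys) == 1

    def test_period_mismatch_rejected(self):
        tiny, real = _toy_with_real(0)
        tree = single_scenario_tree(Realization(
            price=real.price, water_limit=real.water_limit,
            precipitation=np.zeros(len(real.precipitation) + 1),
        ))
        with pytest.raises(ValueError, match="period"):
            milp.build_multistage(tiny.instance, tree)
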
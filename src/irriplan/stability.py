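"""Stability diagnostics for the scenario-generation process.

Sample-average approximation replaces the true distributions by a sampled
tree, so the reported optima are themselves random.  Two diagnostics are
provided:

* **in-sample stability** — regenerate the tree with fresh seeds a number of
  times, re-solve the recourse model each time, and report the spread of the
  optima (small spread = the tree size is adequate);
* **weak out-of-sample stability** (for multiperiod trees, where ordinary
  out-of-sample evaluation is not defined because interior nodes of two
  trees do not coincide) — build two trees, solve each, then re-solve each
  tree with the other's first-stage decision pinned; approximately equal
  cross objectives indicate stability.

Both return a :class:`StabilityResult`; thresholds are reported, not
enforced — a relative spread above ``warn_threshold`` only sets a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import milp
from .evaluation import compute_eev, compute_ev
from .scenarios import (
    PrecipWeekModel,
    PriceModel,
    ScenarioTree,
    WaterLimitModel,
    construct_tree,
    sample_scenario_fan,
)
from .types import FarmInstance

__all__ = ["StabilityResult", "in_sample_stability", "weak_out_of_sample",
           "solve_with_fixed_first_stage"]


@dataclass(frozen=True)
class StabilityResult:
    """Objectives across stability runs.

    ``objectives`` holds one recourse optimum per run (in-sample mode) or the
    two own-tree optima (weak out-of-sample mode); ``cross`` holds the
    cross-evaluated pair (v_treeA_with_xB, v_treeB_with_xA) in the weak test.
    """

    objectives: np.ndarray
    seeds: tuple[int, ...]
    eev_values: np.ndarray | None = None
    cross: tuple[float, float] | None = None
    warn_threshold: float = 0.10
    failures: dict = field(default_factory=dict)

    @property
    def range(self) -> tuple[float, float]:
        return float(np.min(self.objectives)), float(np.max(self.objectives))

    @property
    def spread(self) -> float:
        lo, hi = self.range
        return hi - lo

    @property
    def relative_difference(self) -> float:
        """Relative gap of the cross-evaluated pair (weak test) or of the
        run range (in-sample)."""
        if self.cross is not None:
            a, b = self.cross
            return abs(a - b) / max(abs(a), abs(b), 1e-12)
        lo, hi = self.range
        return (hi - lo) / max(abs(lo), abs(hi), 1e-12)

    @property
    def warning(self) -> bool:
        return self.relative_difference > self.warn_threshold


def in_sample_stability(
    instance: FarmInstance,
    price_model: PriceModel,
    water_model: WaterLimitModel,
    precip_models: Sequence[PrecipWeekModel],
    n_runs: int = 10,
    base_seed: int = 0,
    n_scenarios: int = 200,
    branching: Sequence[int] | None = None,
    mode: str = "twostage",
    with_eev: bool = True,
    gap_tol: float = 1e-6,
    time_limit: float | None = None,
) -> StabilityResult:
    """Regenerate + re-solve ``n_runs`` times with seeds base_seed + r.

    ``mode`` selects the recourse model re-solved per run (``twostage`` or
    ``multistage``); with ``with_eev`` the EV plan (computed once — it does
    not depend on the sample) is also re-evaluated on each run's tree.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    build = milp.build_twostage if mode == "twostage" else milp.build_multistage
    if branching is None:
        branching = _default_branching(instance.n_periods, n_scenarios)
    ev_plan = None
    if with_eev:
        _, ev_plan, _ = compute_ev(
            instance, price_model, water_model, precip_models, gap_tol
        )
    objectives, eevs, seeds = [], [], []
    failures: dict = {}
    for r in range(n_runs):
        seed = base_seed + r
        seeds.append(seed)
        fan = sample_scenario_fan(
            price_model, water_model, precip_models, n_scenarios, seed,
            instance.area,
        )
        tree = construct_tree(fan, branching, seed=seed)
        sol = milp.solve(build(instance, tree), gap_tol=gap_tol,
                         time_limit=time_limit)
        if not sol.ok:
            failures[seed] = sol.status
            objectives.append(np.nan)
        else:
            objectives.append(sol.objective)
        if ev_plan is not None:
            eevs.append(compute_eev(instance, tree, ev_plan)[0])
    return StabilityResult(
        objectives=np.array(objectives),
        seeds=tuple(seeds),
        eev_values=np.array(eevs) if eevs else None,
        failures=failures,
    )


def solve_with_fixed_first_stage(
    instance: FarmInstance,
    tree: ScenarioTree,
    option_index: int,
    mode: str = "multistage",
    gap_tol: float = 1e-6,
    time_limit: float | None = None,
) -> milp.Solution:
    """Re-solve a recourse model with the pre-season option pinned."""
    build = milp.build_twostage if mode == "twostage" else milp.build_multistage
    spec = build(instance, tree)
    for i, idx in enumerate(spec.meta["x"]):
        val = 1.0 if i == option_index else 0.0
        spec.lb[idx] = spec.ub[idx] = val
    return milp.solve(spec, gap_tol=gap_tol, time_limit=time_limit)


def weak_out_of_sample(
    instance: FarmInstance,
    price_model: PriceModel,
    water_model: WaterLimitModel,
    precip_models: Sequence[PrecipWeekModel],
    seed_a: int,
    seed_b: int,
    n_scenarios: int = 200,
    branching: Sequence[int] | None = None,
    mode: str = "multistage",
    gap_tol: float = 1e-6,
    time_limit: float | None = None,
) -> StabilityResult:
    """Weak out-of-sample test: cross-fix first-stage decisions across two
    independently generated trees and compare the objectives."""
    if branching is None:
        branching = _default_branching(instance.n_periods, n_scenarios)
    build = milp.build_twostage if mode == "twostage" else milp.build_multistage
    trees = []
    for seed in (seed_a, seed_b):
        fan = sample_scenario_fan(
            price_model, water_model, precip_models, n_scenarios, seed,
            instance.area,
        )
        trees.append(construct_tree(fan, branching, seed=seed))
    sols, plans = [], []
    for tree in trees:
        spec = build(instance, tree)
        sol = milp.solve(spec, gap_tol=gap_tol, time_limit=time_limit)
        if not sol.ok:
            raise RuntimeError(f"recourse solve failed: {sol.status}")
        sols.append(sol)
        plans.append(milp.extract_plan(sol, spec))
    v_a_with_xb = solve_with_fixed_first_stage(
        instance, trees[0], plans[1].option_index, mode, gap_tol, time_limit
    ).objective
    v_b_with_xa = solve_with_fixed_first_stage(
        instance, trees[1], plans[0].option_index, mode, gap_tol, time_limit
    ).objective
    return StabilityResult(
        objectives=np.array([sols[0].objective, sols[1].objective]),
        seeds=(seed_a, seed_b),
        cross=(float(v_a_with_xb), float(v_b_with_xa)),
    )


def _default_branching(n_periods: int, n_scenarios: int) -> tuple[int, ...]:
    """A moderate default: branch the price/water-limit observation widely,
    early precipitation weeks binary, later weeks unbranched; the leaf count
    never exceeds the fan size."""
    b1 = max(2, min(8, n_scenarios // 8))
    branching = [b1] + [2] * min(3, n_periods - 1)
    while int(np.prod(branching)) > n_scenarios and branching[0] > 2:
        branching[0] -= 1
    while int(np.prod(branching)) > n_scenarios and len(branching) > 1:
        branching.pop()
    return tuple(branching)
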
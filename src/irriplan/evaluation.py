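"""Plan evaluation across scenarios and value-of-information metrics.

The classic stochastic-programming comparison ladder is computed here:

* **EV** — optimum of the deterministic model with every random quantity at
  its mean;
* **EEV** — expected profit when the EV plan is frozen and evaluated in each
  scenario;
* **WS** — wait-and-see: expected value of the per-scenario optima (perfect
  information, not implementable);
* **vfTS / vfMS** — optima of the two-stage and multistage recourse models;
* **EVPI = WS − vfTS**, **VSS = vfTS − EEV**, **VMS = vfMS − vfTS**, with the
  relative versions RVSS = VSS/EEV and RVMS = VMS/vfTS.

For a maximization problem EEV ≤ vfTS ≤ vfMS ≤ WS.

Evaluating a frozen plan in a scenario never declares the scenario
infeasible: if the plan pumps more than the scenario's seasonal allocation
the schedule is truncated (chronologically by default) at the limit, the
yield mandate is dropped, and all violations are reported on the returned
trajectory.  Given the (possibly truncated) schedule, the soil-water states
and the deficit level are resolved by a greedy forward simulation that
maximizes crop water use week by week — provably equivalent to re-solving
the scenario MILP with the decisions frozen, which the test suite checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import milp
from .scenarios import (
    PrecipWeekModel,
    PriceModel,
    ScenarioFan,
    ScenarioTree,
    WaterLimitModel,
    ev_realization,
)
from .types import (
    DecisionPlan,
    FarmInstance,
    Realization,
    Trajectory,
    profit as compute_profit,
)

__all__ = [
    "evaluate_plan",
    "evaluate_plan_milp",
    "truncate_to_limit",
    "compute_ev",
    "compute_eev",
    "compute_ws",
    "voi_report",
    "VoiReport",
    "six_number_summary",
]


def truncate_to_limit(
    instance: FarmInstance,
    plan: DecisionPlan,
    water_limit: float,
    rule: str = "chronological",
) -> tuple[DecisionPlan, float]:
    """Make a frozen schedule respect a scenario's seasonal allocation.

    ``chronological`` keeps early-season irrigation and cuts once the
    cumulative pumped volume hits the limit; ``proportional`` rescales the
    whole schedule.  Returns the adjusted plan and the truncated gross volume
    (m³, zero when the plan already fits).
    """
    gross = instance.area * np.asarray(plan.irrigation) / instance.efficiency
    total = float(np.sum(gross))
    if total <= water_limit + 1e-9:
        return plan, 0.0
    if rule == "chronological":
        cum = np.cumsum(gross)
        allowed_gross = np.minimum(gross, np.maximum(0.0, water_limit - (cum - gross)))
        y = allowed_gross * instance.efficiency / instance.area
    elif rule == "proportional":
        y = plan.irrigation * (water_limit / total)
    else:
        raise ValueError(f"unknown truncation rule {rule!r}")
    new_plan = DecisionPlan(option_choice=plan.option_choice, irrigation=y)
    return new_plan, total - water_limit


def _snap_to_grid(grid: np.ndarray, ratio: float, slack: float = 1e-5) -> int:
    """Nearest deficit level; ties broken toward the higher level, matching
    the MILP's preference for the largest feasible grid value.  ``slack``
    absorbs numerical noise around exact midpoints: an optimal schedule
    typically irrigates exactly to the tolerance edge of a level, so the
    season ratio sits on the tie by construction, perturbed by the MIP
    solver's feasibility tolerance (~1e-7 in depth units).  The slack is
    ≤ 0.2% of the half-step of the default 101-level grid."""
    diffs = np.abs(grid - ratio)
    best = np.min(diffs)
    return int(np.max(np.where(diffs <= best + slack)[0]))


def evaluate_plan(
    instance: FarmInstance,
    realization: Realization,
    plan: DecisionPlan,
    truncation: str = "chronological",
) -> Trajectory:
    """Outcome of a frozen plan in one scenario (always returns a value).

    Greedy forward water balance with a dry-spring start: each week the
    inflow M_t + y_t + R_t first leaches any excess over the holding
    capacity, then crop ET takes as much as possible up to the week's
    unstressed demand; the season ET ratio is snapped to the deficit grid
    (nearest level, half-grid-step rule) and the yield-response function
    gives the yield.  The yield mandate is not enforced; shortfalls and any
    water-limit truncation are reported in ``violations``.
    """
    plan, truncated = truncate_to_limit(
        instance, plan, realization.water_limit, truncation
    )
    T = instance.n_periods
    etm = instance.max_et
    H = instance.holding_capacity
    M = np.zeros(T)
    eta = np.zeros(T)
    lw = np.zeros(T)
    m = 0.0
    for t in range(T):
        M[t] = m
        inflow = m + float(plan.irrigation[t]) + float(realization.precipitation[t])
        lw[t] = max(0.0, inflow - H)
        avail = inflow - lw[t]
        eta[t] = min(float(etm[t]), avail)
        m = avail - eta[t]
    ratio = float(np.sum(eta) / np.sum(etm))
    l_star = _snap_to_grid(instance.deficit_grid, ratio)
    option = instance.options[plan.option_index]
    d_frac = float(instance.deficit_grid[l_star])
    raw_yield = option.yield_at(d_frac, clamp=False)
    actual_yield = max(0.0, raw_yield)
    violations: dict = {}
    if truncated > 0:
        violations["water_limit_excess_m3"] = truncated
    if raw_yield < 0:
        violations["negative_yield_clamped"] = -raw_yield
    if instance.min_yield > 0 and instance.area * actual_yield < instance.min_yield - 1e-9:
        violations["min_yield_shortfall_kg"] = (
            instance.min_yield - instance.area * actual_yield
        )
    prof = compute_profit(instance, option, realization, plan, actual_yield)
    return Trajectory(
        soil_moisture=M,
        actual_et=eta,
        leaching=lw,
        deficit_index=l_star,
        deficit_fraction=d_frac,
        actual_yield=actual_yield,
        profit=prof,
        violations=violations,
    )


def evaluate_plan_milp(
    instance: FarmInstance,
    realization: Realization,
    plan: DecisionPlan,
    truncation: str = "chronological",
    gap_tol: float = 1e-9,
) -> float:
    """Evaluate a frozen plan by re-solving the scenario MILP with the
    decisions fixed (the independent route against the greedy simulation).

    The schedule is first truncated to the scenario's allocation exactly as
    in :func:`evaluate_plan`; x, y and z are then pinned by bounds and the
    yield mandate dropped, leaving the solver free only in the soil states
    and deficit level.  Returns the resulting profit.
    """
    plan, _ = truncate_to_limit(instance, plan, realization.water_limit, truncation)
    inst_eval = replace(instance, min_yield=0.0)
    spec = milp.build_deterministic(inst_eval, realization)
    for i, idx in enumerate(spec.meta["x"]):
        spec.lb[idx] = spec.ub[idx] = float(plan.option_choice[i])
    for t, idx in enumerate(spec.meta["y"]):
        spec.lb[idx] = spec.ub[idx] = float(plan.irrigation[t])
    for t, idx in enumerate(spec.meta["z"]):
        spec.lb[idx] = spec.ub[idx] = float(plan.flags[t])
    sol = milp.solve(spec, gap_tol=gap_tol)
    if not sol.ok:
        raise RuntimeError(f"frozen-plan subproblem came back {sol.status}")
    return sol.objective


def six_number_summary(values: np.ndarray, probabilities: np.ndarray) -> dict:
    """Min / 1st quartile / median / mean / 3rd quartile / max of the
    per-scenario values (quartiles are unweighted inclusive quantiles; the
    mean is probability-weighted)."""
    v = np.asarray(values, dtype=float)
    return {
        "min": float(np.min(v)),
        "q1": float(np.quantile(v, 0.25)),
        "median": float(np.quantile(v, 0.5)),
        "mean": float(np.sum(v * probabilities)),
        "q3": float(np.quantile(v, 0.75)),
        "max": float(np.max(v)),
    }


def _fan_of(scenarios) -> ScenarioFan:
    if isinstance(scenarios, ScenarioTree):
        return scenarios.as_fan()
    return scenarios


def compute_ev(
    instance: FarmInstance,
    price_model: PriceModel,
    water_model: WaterLimitModel,
    precip_models: Sequence[PrecipWeekModel],
    gap_tol: float = 1e-6,
) -> tuple[float, DecisionPlan, Trajectory]:
    """Solve the expected-value problem (all random quantities at their
    means); the returned plan is the all-at-once schedule a deterministic
    planner would commit to during sowing."""
    real = ev_realization(price_model, water_model, precip_models, instance.area)
    spec = milp.build_deterministic(instance, real)
    sol = milp.solve(spec, gap_tol=gap_tol)
    if not sol.ok:
        raise RuntimeError(f"EV problem came back {sol.status}")
    plan, traj = milp.extract_plan(sol, spec)
    return sol.objective, plan, traj


def compute_eev(
    instance: FarmInstance,
    scenarios,
    ev_plan: DecisionPlan,
    truncation: str = "chronological",
) -> tuple[float, np.ndarray]:
    """Probability-weighted mean profit of the frozen EV plan across the
    scenarios (fan or tree); also returns the per-scenario values."""
    fan = _fan_of(scenarios)
    values = np.array([
        evaluate_plan(instance, fan.realization(w), ev_plan, truncation).profit
        for w in range(fan.n_scenarios)
    ])
    return float(np.sum(values * fan.probabilities)), values


def compute_ws(
    instance: FarmInstance,
    scenarios,
    gap_tol: float = 1e-6,
) -> tuple[float, np.ndarray]:
    """Wait-and-see value: deterministic optimum of every scenario,
    probability-weighted.  The per-scenario decisions are hypothetical
    (perfect foresight) and not implementable; only the values are used."""
    fan = _fan_of(scenarios)
    values = np.empty(fan.n_scenarios)
    for w in range(fan.n_scenarios):
        spec = milp.build_deterministic(instance, fan.realization(w))
        sol = milp.solve(spec, gap_tol=gap_tol)
        if not sol.ok:
            raise RuntimeError(f"WS subproblem {w} came back {sol.status}")
        values[w] = sol.objective
    return float(np.sum(values * fan.probabilities)), values


@dataclass(frozen=True)
class VoiReport:
    """Full value-of-information report for one instance and tree."""

    ev: float
    eev: float
    ws: float
    rp_two_stage: float
    rp_multistage: float
    evpi: float
    vss: float
    vms: float
    rvss: float
    rvms: float
    ws_values: np.ndarray
    eev_values: np.ndarray
    ws_summary: dict
    eev_summary: dict

    def check_identities(self, atol: float = 1e-12) -> None:
        """Internal-consistency identities of the derived metrics."""
        assert abs(self.evpi - (self.ws - self.rp_two_stage)) <= atol
        assert abs(self.vss - (self.rp_two_stage - self.eev)) <= atol
        assert abs(self.vms - (self.rp_multistage - self.rp_two_stage)) <= atol
        assert abs(self.rvss - (self.rp_two_stage - self.eev) / self.eev) <= atol
        assert abs(
            self.rvms - (self.rp_multistage - self.rp_two_stage) / self.rp_two_stage
        ) <= atol

    def to_dict(self) -> dict:
        return {
            "EV": self.ev,
            "EEV_TS": self.eev,
            "WS": self.ws,
            "vfTS": self.rp_two_stage,
            "vfMS": self.rp_multistage,
            "EVPI": self.evpi,
            "VSS": self.vss,
            "VMS": self.vms,
            "RVSS": self.rvss,
            "RVMS": self.rvms,
            "WS_summary": self.ws_summary,
            "EEV_summary": self.eev_summary,
        }


def voi_report(
    instance: FarmInstance,
    tree: ScenarioTree,
    price_model: PriceModel,
    water_model: WaterLimitModel,
    precip_models: Sequence[PrecipWeekModel],
    gap_tol: float = 1e-6,
    time_limit: float | None = None,
    truncation: str = "chronological",
) -> VoiReport:
    """Compute EV, EEV, WS, the two recourse optima and every derived
    value-of-information metric on one scenario tree."""
    ev, ev_plan, _ = compute_ev(instance, price_model, water_model, precip_models,
                                gap_tol)
    eev, eev_values = compute_eev(instance, tree, ev_plan, truncation)
    ws, ws_values = compute_ws(instance, tree, gap_tol)
    ts_sol = milp.solve(milp.build_twostage(instance, tree),
                        gap_tol=gap_tol, time_limit=time_limit)
    ms_sol = milp.solve(milp.build_multistage(instance, tree),
                        gap_tol=gap_tol, time_limit=time_limit)
    if not (ts_sol.ok and ms_sol.ok):
        raise RuntimeError(
            f"recourse solves failed: TS={ts_sol.status}, MS={ms_sol.status}"
        )
    vf_ts, vf_ms = ts_sol.objective, ms_sol.objective
    probs = tree.scenario_probs
    return VoiReport(
        ev=ev,
        eev=eev,
        ws=ws,
        rp_two_stage=vf_ts,
        rp_multistage=vf_ms,
        evpi=ws - vf_ts,
        vss=vf_ts - eev,
        vms=vf_ms - vf_ts,
        rvss=(vf_ts - eev) / eev,
        rvms=(vf_ms - vf_ts) / vf_ts,
        ws_values=ws_values,
        eev_values=eev_values,
        ws_summary=six_number_summary(ws_values, probs),
        eev_summary=six_number_summary(eev_values, probs),
    )
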
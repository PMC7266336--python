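"""Synthetic farm instances and a brute-force optimization oracle.

Two kinds of fixtures live here:

* :func:`fixture_paper_instance` — a 150-acre Nebraska sandhills corn farm
  assembled from publicly printed case parameters (area, soil water holding
  capacity, center-pivot efficiency, water price, ET range, yield range,
  price/water/precipitation distributions).  Cost items that are only
  available in the case study's supplementary cost workbook (seed and
  operating costs per option, fixed irrigation cost, overhead, pre-irrigation
  depth, response factors, yield mandate) carry SYNTHETIC stand-in values:
  round numbers of realistic magnitude, clearly marked below, and
  overridable.
* :func:`fixture_toy_instance` — seeded random tiny instances (≤ 3 options,
  ≤ 3 periods, ≤ 5 deficit levels, profit scale ~10³ $) for property tests,
  paired with :func:`fixture_toy_models` for their stochastic environment.

:func:`brute_force_solve` enumerates every (option, grid-restricted
schedule) pair and evaluates it with the greedy simulator, providing an
independent optimum against which the MILP builders are verified.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
import numpy as np

from .evaluation import evaluate_plan
from .scenarios import (
    PrecipWeekModel,
    PriceModel,
    WaterLimitModel,
    default_precip_models,
    default_price_model,
    default_water_limit_model,
)
from .types import (
    DecisionPlan,
    FarmInstance,
    ManagementOption,
    Realization,
    validate_instance,
)
from .units import convert

__all__ = [
    "TinyInstance",
    "brute_force_solve",
    "fixture_paper_instance",
    "fixture_toy_instance",
    "fixture_toy_models",
    "STANDIN_COSTS",
]

MAX_ENUMERATION = 1_000_000


@dataclass(frozen=True)
class TinyInstance:
    """A small instance plus a discrete candidate grid of weekly net
    irrigation depths (m); the grid always contains 0."""

    instance: FarmInstance
    y_grid: tuple[float, ...]

    def __post_init__(self) -> None:
        if 0.0 not in self.y_grid:
            raise ValueError("y_grid must include 0")
        size = self.instance.n_options * len(self.y_grid) ** self.instance.n_periods
        if size > MAX_ENUMERATION:
            raise ValueError(f"enumeration size {size} exceeds {MAX_ENUMERATION}")


def brute_force_solve(
    tiny: TinyInstance, realization: Realization
) -> tuple[float, DecisionPlan]:
    """Enumerate every option × grid schedule; evaluate by greedy simulation.

    Schedules whose pumped volume exceeds the scenario's water limit are
    skipped, as are combinations whose yield-response value is negative (the
    planning model treats those as infeasible) or that miss the yield
    mandate.  Returns the best profit and the maximizing plan.
    """
    inst = tiny.instance
    best = (-np.inf, None)
    limit_net = realization.water_limit * inst.efficiency / inst.area
    for i in range(inst.n_options):
        x = np.zeros(inst.n_options, dtype=int)
        x[i] = 1
        for combo in itertools.product(tiny.y_grid, repeat=inst.n_periods):
            y = np.array(combo)
            if float(np.sum(y)) > limit_net + 1e-12:
                continue
            plan = DecisionPlan(option_choice=x.copy(), irrigation=y)
            traj = evaluate_plan(inst, realization, plan)
            if "negative_yield_clamped" in traj.violations:
                continue
            if "min_yield_shortfall_kg" in traj.violations:
                continue
            if traj.profit > best[0]:
                best = (traj.profit, plan)
    if best[1] is None:
        raise ValueError("no feasible grid schedule (yield mandate too high?)")
    return best


# ---------------------------------------------------------------------------
# Case-study-scale fixture
# ---------------------------------------------------------------------------

#: SYNTHETIC stand-in cost parameters (NOT from any published source): the
#: case study's per-option seed/operating costs, fixed irrigation cost,
#: overhead, pre-irrigation depth, response factors and yield mandate live in
#: a supplementary cost workbook.  These are round numbers whose magnitudes
#: are consistent with the printed farm-total aggregates (production costs of
#: roughly $60k and irrigation costs of roughly $24k for 150 acres).
STANDIN_COSTS = {
    "operating_cost_usd_per_acre": 230.0,
    "overhead_usd": 7_500.0,
    "fixed_irrigation_cost_usd_per_acre_event": 2.0,
    "pre_irrigation_inch": 2.0,
    "min_yield_kg": 0.0,
    # label: (seed cost $/acre, max yield bu/acre, response factor K)
    "options": {
        "high yield / high population": (120.0, 210.0, 1.2),
        "high yield / low population": (95.0, 180.0, 1.2),
        "drought tolerant / high population": (115.0, 195.0, 0.85),
        "drought tolerant / low population": (90.0, 170.0, 0.85),
    },
}


def fixture_paper_instance(
    overrides: dict | None = None,
    n_levels: int = 101,
    et_mm_per_day: float = 6.5,
    persistence: float = 0.0,
) -> tuple[FarmInstance, PriceModel, WaterLimitModel, tuple[PrecipWeekModel, ...]]:
    """The 150-acre Nebraska case-study farm with documented stand-in costs.

    Printed parameters: 150 acres; center-pivot efficiency 0.85; holding
    capacity 8 cm water per m soil over a 91 cm effective root zone; water at
    $12/acre-inch; eight weekly periods with unstressed ET defaulting to the
    midpoint of the printed 5–8 mm/day range; option yields spanning the
    printed 160–210 bu/acre; April price $3.6/bu; seasonal allocation uniform
    on 11.0–14.9 inches/acre; weekly precipitation models calibrated to the
    printed daily moments and integrated weekly averages.

    ``overrides`` replaces any entry of :data:`STANDIN_COSTS` (e.g. with
    values read from the case study's cost workbook via
    :func:`irriplan.io.read_workbook_overrides`).
    """
    costs = {**STANDIN_COSTS, **(overrides or {})}
    area = convert(150.0, "acre", "m2")
    options = tuple(
        ManagementOption(
            index=i,
            seed_cost=convert(seed, "usd_per_acre", "usd_per_m2"),
            operating_cost=convert(
                costs["operating_cost_usd_per_acre"], "usd_per_acre", "usd_per_m2"
            ),
            max_yield=convert(ym, "bushel_per_acre", "kg_per_m2"),
            response_factor=k,
            label=label,
        )
        for i, (label, (seed, ym, k)) in enumerate(costs["options"].items())
    )
    instance = FarmInstance(
        area=area,
        efficiency=0.85,
        holding_capacity=0.08 * 0.91,   # 8 cm water per m soil × 0.91 m root zone
        pre_irrigation=convert(costs["pre_irrigation_inch"], "inch", "m"),
        water_cost=convert(12.0, "usd_per_acre_inch", "usd_per_m3"),
        fixed_irrigation_cost=convert(
            costs["fixed_irrigation_cost_usd_per_acre_event"],
            "usd_per_acre", "usd_per_m2",
        ),
        overhead=costs["overhead_usd"],
        min_yield=costs["min_yield_kg"],
        options=options,
        max_et=np.full(8, convert(et_mm_per_day * 7.0, "mm", "m")),
        deficit_grid=np.linspace(0.0, 1.0, n_levels),
        n_periods=8,
    )
    return (
        validate_instance(instance),
        default_price_model(3.6),
        default_water_limit_model(),
        default_precip_models(persistence),
    )


# ---------------------------------------------------------------------------
# Toy fixtures for property tests
# ---------------------------------------------------------------------------

def fixture_toy_instance(seed: int) -> TinyInstance:
    """Seeded random tiny instance (profit scale ~10³ $), always valid.

    Response factors are kept in [0.3, 1.0] so the yield-response value is
    nonnegative at every deficit level and the ordering theorems of the
    stochastic models hold without clamping.
    """
    rng = np.random.default_rng(seed)
    T = int(rng.integers(2, 4))          # 2 or 3 periods
    I = int(rng.integers(1, 4))          # 1..3 options
    L = int(rng.integers(3, 6))          # 3..5 deficit levels
    area = float(rng.uniform(5_000.0, 15_000.0))            # m² (~1-4 acres)
    etm = rng.uniform(0.02, 0.05, size=T)                   # m/week
    options = tuple(
        ManagementOption(
            index=i,
            seed_cost=float(rng.uniform(0.005, 0.02)),      # $/m²
            operating_cost=float(rng.uniform(0.01, 0.04)),
            max_yield=float(rng.uniform(0.8, 1.4)),         # kg/m²
            response_factor=float(rng.uniform(0.3, 1.0)),
            label=f"toy option {i}",
        )
        for i in range(I)
    )
    instance = FarmInstance(
        area=area,
        efficiency=float(rng.uniform(0.6, 1.0)),
        holding_capacity=float(rng.uniform(0.05, 0.10)),
        pre_irrigation=float(rng.uniform(0.0, 0.03)),
        water_cost=float(rng.uniform(0.05, 0.2)),           # $/m³
        fixed_irrigation_cost=float(rng.uniform(0.0, 0.002)),
        overhead=float(rng.uniform(0.0, 200.0)),
        min_yield=0.0,
        options=options,
        max_et=etm,
        deficit_grid=np.linspace(0.0, 1.0, L),
        n_periods=T,
    )
    instance = validate_instance(instance)
    grid_max = float(np.max(etm))
    y_grid = (0.0,) + tuple(
        float(v) for v in np.round(np.linspace(grid_max / 3, grid_max, 3), 6)
    )
    return TinyInstance(instance=instance, y_grid=y_grid)


def fixture_toy_models(
    tiny: TinyInstance, seed: int
) -> tuple[PriceModel, WaterLimitModel, tuple[PrecipWeekModel, ...]]:
    """A stochastic environment matched to a toy instance's scale."""
    rng = np.random.default_rng(seed + 10_000)
    inst = tiny.instance
    mean_price = float(rng.uniform(0.1, 0.25))              # $/kg
    price = PriceModel(
        april_price=mean_price, mean_shift=0.0, sd=mean_price * float(rng.uniform(0.05, 0.2))
    )
    et_total = float(np.sum(inst.max_et))
    lower = float(rng.uniform(0.2, 0.6)) * et_total / inst.efficiency
    upper = lower * float(rng.uniform(1.2, 2.0))
    water = WaterLimitModel(lower=lower, upper=upper)
    precip = tuple(
        PrecipWeekModel(
            daily_mean=float(rng.uniform(0.002, 0.01)),
            daily_variance=float(rng.uniform(0.5, 2.0)) * (0.005) ** 2,
            wet_prob=float(rng.uniform(0.1, 0.5)),
        )
        for _ in range(inst.n_periods)
    )
    return price, water, precip
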
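"""Domain types for the irrigation-planning models.

All quantities are stored in canonical SI units: areas in m², water depths
(soil moisture, irrigation, precipitation, evapotranspiration, holding
capacity) in metres of water over the effective root zone, volumes in m³,
yields in kg/m², prices in $/kg and $/m³, areal costs in $/m².

The planning horizon is the corn flowering + grain-filling window, split into
``n_periods`` weekly periods (default 8).  Pre-season management options
bundle a seed type and plant population: each option carries its own seed
cost, operating cost, attainable yield under full irrigation and water-stress
response factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

__all__ = [
    "ManagementOption",
    "FarmInstance",
    "Realization",
    "DecisionPlan",
    "Trajectory",
    "default_deficit_grid",
    "validate_instance",
    "profit",
]


def default_deficit_grid(n_levels: int = 101) -> np.ndarray:
    """Equidistant deficit levels D_l from 0 to 1 (default 101 levels).

    Level l holds the fraction of unstressed crop evapotranspiration that is
    actually met; the grid discretizes the continuous ET ratio so that the
    yield-response function can be handled with binary selection variables.
    """
    return np.linspace(0.0, 1.0, n_levels)


@dataclass(frozen=True)
class ManagementOption:
    """A pre-season seed-type / plant-population bundle.

    Parameters
    ----------
    index : position in the instance's option list.
    seed_cost : seed purchase cost, $/m².
    operating_cost : lumped other farm operating cost (labor, machinery,
        chemicals, excluding irrigation), $/m².
    max_yield : attainable yield with no water stress, kg/m².
    response_factor : dimensionless yield response factor to water stress,
        integrated over the flowering and grain-filling stages; relative
        yield loss = response_factor × relative ET deficit.
    label : free-text description (e.g. "high yield / high population").
    """

    index: int
    seed_cost: float
    operating_cost: float
    max_yield: float
    response_factor: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.max_yield <= 0:
            raise ValueError(f"option {self.index}: max_yield must be > 0")
        if self.response_factor < 0:
            raise ValueError(f"option {self.index}: response_factor must be >= 0")
        if self.seed_cost < 0 or self.operating_cost < 0:
            raise ValueError(f"option {self.index}: costs must be >= 0")

    def yield_at(self, deficit_fraction: float, clamp: bool = False) -> float:
        """Yield (kg/m²) when a fraction ``deficit_fraction`` of unstressed ET
        is met: Y = Y_max (1 − K (1 − D)).  With ``clamp`` the result is
        floored at zero (used in evaluation mode where severe stress combined
        with K > 1 would otherwise give a negative yield)."""
        y = self.max_yield * (1.0 - self.response_factor * (1.0 - deficit_fraction))
        return max(0.0, y) if clamp else y


@dataclass(frozen=True)
class FarmInstance:
    """All deterministic parameters of the farm planning MILP (SI units).

    ``big_m_yield`` is the big-M constant coupling deficit-level selection to
    the yield variables; when ``None`` it is validated/defaulted to the yield
    upper bound max_i Y^m_i.  The big-M used in the irrigation-indicator
    constraint has depth dimensions and equals H + max_t ET^m_t (a valid upper
    bound on weekly net irrigation under the capacity constraint).
    """

    area: float                         # m²
    efficiency: float                   # irrigation application efficiency in (0, 1]
    holding_capacity: float             # m of plant-available water in root zone
    pre_irrigation: float               # m, spring profile refill (gross depth)
    water_cost: float                   # $/m³
    fixed_irrigation_cost: float        # $/m² per irrigation event
    overhead: float                     # $, cash + non-cash whole-farm overhead
    min_yield: float                    # kg, farm-total yield mandate (0 = none)
    options: tuple[ManagementOption, ...]
    max_et: np.ndarray                  # m per period, unstressed crop ET
    deficit_grid: np.ndarray = field(default_factory=default_deficit_grid)
    n_periods: int = 8
    big_m_yield: float | None = None    # kg/m²

    @property
    def n_options(self) -> int:
        return len(self.options)

    @property
    def n_levels(self) -> int:
        return len(self.deficit_grid)

    @property
    def big_m_depth(self) -> float:
        """Depth-scale big-M for the irrigation indicator constraint (m)."""
        return self.holding_capacity + float(np.max(self.max_et))

    @property
    def deficit_half_step(self) -> float:
        """Half the deficit-grid spacing; tolerance for snapping the
        continuous ET ratio onto the grid."""
        steps = np.diff(self.deficit_grid)
        return float(np.max(steps)) / 2.0


def validate_instance(instance: FarmInstance) -> FarmInstance:
    """Check all instance invariants; return a copy with big-M defaulted.

    Raises ``ValueError`` on any violation: efficiency outside (0, 1], empty
    option list, non-increasing deficit grid or a grid not spanning [0, 1],
    non-positive holding capacity or ET profile, period-count mismatches.
    """
    inst = instance
    if not (0.0 < inst.efficiency <= 1.0):
        raise ValueError(f"efficiency must be in (0, 1], got {inst.efficiency}")
    if inst.area <= 0:
        raise ValueError("area must be > 0")
    if inst.holding_capacity <= 0:
        raise ValueError("holding_capacity must be > 0")
    if inst.pre_irrigation < 0 or inst.water_cost < 0:
        raise ValueError("pre_irrigation and water_cost must be >= 0")
    if inst.fixed_irrigation_cost < 0 or inst.overhead < 0:
        raise ValueError("fixed_irrigation_cost and overhead must be >= 0")
    if inst.min_yield < 0:
        raise ValueError("min_yield must be >= 0")
    if inst.n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if not inst.options:
        raise ValueError("option list must not be empty")
    for i, opt in enumerate(inst.options):
        if opt.index != i:
            raise ValueError(f"option {i} has index {opt.index}; must match position")
    grid = np.asarray(inst.deficit_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2:
        raise ValueError("deficit_grid must be a 1-D grid with at least 2 levels")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("deficit_grid must be strictly increasing")
    if abs(grid[0]) > 1e-12 or abs(grid[-1] - 1.0) > 1e-12:
        raise ValueError("deficit_grid must run from 0 to 1")
    et = np.asarray(inst.max_et, dtype=float)
    if et.shape != (inst.n_periods,):
        raise ValueError(
            f"max_et has shape {et.shape}, expected ({inst.n_periods},)"
        )
    if not np.all(et > 0):
        raise ValueError("max_et must be positive in every period")
    big_m = inst.big_m_yield
    max_ym = max(opt.max_yield for opt in inst.options)
    if big_m is None:
        big_m = max_ym
    elif big_m < max_ym:
        raise ValueError(
            f"big_m_yield {big_m} is below the yield upper bound {max_ym}"
        )
    return replace(inst, deficit_grid=grid, max_et=et, big_m_yield=float(big_m))


@dataclass(frozen=True)
class Realization:
    """One joint outcome of the uncertain quantities.

    price : $/kg corn price for the post-harvest sales season.
    water_limit : m³, farm-total seasonal irrigation allocation, gross of
        application efficiency (pumped volume).
    precipitation : m per period, weekly totals over the planning horizon.
    """

    price: float
    water_limit: float
    precipitation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "precipitation", np.asarray(self.precipitation, dtype=float)
        )
        if self.price < 0:
            raise ValueError("price must be >= 0")
        if self.water_limit < 0:
            raise ValueError("water_limit must be >= 0")
        if np.any(self.precipitation < 0):
            raise ValueError("precipitation must be >= 0")


@dataclass(frozen=True)
class DecisionPlan:
    """A concrete plan: one management option plus weekly net irrigation.

    ``option_choice`` is a 0/1 vector with exactly one 1; ``irrigation`` holds
    net (crop-available) water depths y_t ≥ 0; ``flags`` marks the periods in
    which an irrigation event takes place (z_t = 1 iff y_t > 0).
    """

    option_choice: np.ndarray
    irrigation: np.ndarray
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.option_choice, dtype=int)
        y = np.asarray(self.irrigation, dtype=float)
        object.__setattr__(self, "option_choice", x)
        object.__setattr__(self, "irrigation", y)
        if x.sum() != 1 or not np.all((x == 0) | (x == 1)):
            raise ValueError("option_choice must be binary with exactly one 1")
        if np.any(y < -1e-12):
            raise ValueError("irrigation depths must be >= 0")
        if self.flags is None:
            object.__setattr__(self, "flags", (y > 1e-9).astype(int))
        else:
            z = np.asarray(self.flags, dtype=int)
            object.__setattr__(self, "flags", z)
            if np.any((y > 1e-9) & (z == 0)):
                raise ValueError("irrigation > 0 requires flag = 1")

    @property
    def option_index(self) -> int:
        return int(np.argmax(self.option_choice))


@dataclass(frozen=True)
class Trajectory:
    """Simulated soil-water trajectory and economic outcome of a plan.

    Depth fields are per-period arrays (soil moisture is the state at the
    START of each period; soil_moisture[0] = 0 by the dry-spring assumption).
    ``violations`` records constraint violations encountered in evaluation
    mode (water-limit truncation amount in m³, unmet minimum yield in kg).
    """

    soil_moisture: np.ndarray       # m, length T (start-of-period state)
    actual_et: np.ndarray           # m, length T
    leaching: np.ndarray            # m, length T
    deficit_index: int              # selected level l* (0-based)
    deficit_fraction: float         # D_{l*}
    actual_yield: float             # kg/m²
    profit: float                   # $
    violations: dict = field(default_factory=dict)

    @property
    def et_ratio(self) -> float:
        """Continuous (unsnapped) ratio Σ ET^a / Σ ET^m is not stored; this
        returns the grid value used for yield."""
        return self.deficit_fraction


def profit(
    instance: FarmInstance,
    option: ManagementOption,
    realization: Realization,
    plan: DecisionPlan,
    yield_per_area: float,
) -> float:
    """Annual net farm profit ($): revenue minus all system costs.

    revenue                G · A · Y^c
    water purchase         A · C^wt · (Σ_t y_t / γ + W^p)
    fixed irrigation       A · C^f · Σ_t z_t
    seed + operating       A · (C^s_i + C^m_i)
    overhead               C^o
    """
    a = instance.area
    rev = realization.price * a * yield_per_area
    water = a * instance.water_cost * (
        float(np.sum(plan.irrigation)) / instance.efficiency + instance.pre_irrigation
    )
    fixed = a * instance.fixed_irrigation_cost * float(np.sum(plan.flags))
    preseason = a * (option.seed_cost + option.operating_cost)
    return rev - water - fixed - preseason - instance.overhead
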
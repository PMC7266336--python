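"""Scenario generation for prices, seasonal water limits and precipitation.

Three independent sources of uncertainty drive the planning problem:

* the post-harvest corn price, normal around the April price minus a fixed
  shift;
* the seasonal irrigation allocation, uniform between a practical lower and
  upper bound;
* weekly precipitation over the eight-week flowering/grain-filling window,
  generated by a two-part daily weather model — a two-state occurrence chain
  (wet/dry day) and gamma-distributed amounts on wet days — aggregated to
  weekly totals.

Scenarios are drawn by plain Monte Carlo (sample-average approximation) into
an equal-probability fan, and the fan is reduced to a staged scenario tree by
stagewise forward clustering so that the stochastic programs can impose
nonanticipativity on the tree's bundle structure.

Information timing: price and water limit are observed at the start of week
1; the week-t precipitation total is observed at the END of week t.  Hence
the week-t irrigation decision may depend on R_1..R_{t-1} but not on R_t.
In the tree, stage-1 nodes branch on (price, water limit), stage-t nodes
(t ≥ 2) branch on R_{t-1}, and the final week's precipitation rides on the
leaves without branching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import Realization
from .units import convert

__all__ = [
    "PrecipWeekModel",
    "PriceModel",
    "WaterLimitModel",
    "ScenarioFan",
    "ScenarioTree",
    "TABLE1_DAILY_MEAN_IN",
    "TABLE1_DAILY_MEDIAN_IN",
    "TABLE1_DAILY_VARIANCE_IN2",
    "TABLE1_WEEKLY_MEAN_IN",
    "default_precip_models",
    "default_price_model",
    "default_water_limit_model",
    "fit_gamma_moments",
    "calibrate_wet_probability",
    "simulate_weekly_precipitation",
    "sample_price",
    "sample_water_limit",
    "sample_scenario_fan",
    "construct_tree",
    "tree_from_fan",
    "single_scenario_tree",
    "ev_realization",
]

# Weekly statistics of daily precipitation (inches) and the integrated weekly
# totals for the eight flowering/grain-filling weeks at the Cherry County,
# Nebraska study site.
TABLE1_DAILY_MEAN_IN = (0.44, 0.46, 0.47, 0.40, 0.46, 0.44, 0.41, 0.34)
TABLE1_DAILY_MEDIAN_IN = (0.33, 0.34, 0.35, 0.28, 0.34, 0.34, 0.30, 0.26)
TABLE1_DAILY_VARIANCE_IN2 = (0.15, 0.19, 0.17, 0.16, 0.18, 0.15, 0.15, 0.08)
TABLE1_WEEKLY_MEAN_IN = (0.73, 0.69, 0.65, 0.52, 0.70, 0.65, 0.56, 0.38)

DAYS_PER_WEEK = 7


def fit_gamma_moments(mean: float, variance: float) -> tuple[float, float]:
    """Moment-matched gamma parameters (shape k, scale θ) for wet-day amounts.

    k = mean²/variance, θ = variance/mean; the fitted gamma reproduces the
    input mean and variance exactly.
    """
    if mean <= 0 or variance <= 0:
        raise ValueError("mean and variance must be positive")
    shape = mean * mean / variance
    scale = variance / mean
    return shape, scale


def calibrate_wet_probability(daily_mean: float, weekly_integrated_mean: float) -> float:
    """Wet-day probability such that E[weekly total] = 7 p μ_daily matches the
    integrated weekly average, clipped to [0, 1]."""
    if daily_mean <= 0:
        raise ValueError("daily_mean must be positive")
    if weekly_integrated_mean < 0:
        raise ValueError("weekly_integrated_mean must be >= 0")
    return min(1.0, weekly_integrated_mean / (DAYS_PER_WEEK * daily_mean))


@dataclass(frozen=True)
class PrecipWeekModel:
    """Daily precipitation model for one week of the horizon.

    Amount on a wet day ~ Gamma(shape, scale) with parameters moment-matched
    to (daily_mean, daily_variance); occurrence follows a two-state chain with
    stationary wet probability ``wet_prob`` and optional lag-1 persistence
    ``persistence`` = ρ (ρ = 0 gives i.i.d. Bernoulli occurrence).  All depths
    in metres.
    """

    daily_mean: float
    daily_variance: float
    wet_prob: float
    persistence: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.wet_prob <= 1.0):
            raise ValueError("wet_prob must be in [0, 1]")
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must be in [0, 1)")
        if self.wet_prob > 0:
            fit_gamma_moments(self.daily_mean, self.daily_variance)

    @property
    def gamma_shape(self) -> float:
        return fit_gamma_moments(self.daily_mean, self.daily_variance)[0]

    @property
    def gamma_scale(self) -> float:
        return fit_gamma_moments(self.daily_mean, self.daily_variance)[1]

    @property
    def weekly_mean(self) -> float:
        """Expected weekly total = 7 p μ_daily (m)."""
        return DAYS_PER_WEEK * self.wet_prob * self.daily_mean

    @property
    def transition_probs(self) -> tuple[float, float]:
        """(p01, p11): wet-given-dry and wet-given-wet probabilities, solved
        from the stationary wet probability and the persistence ρ."""
        p = self.wet_prob
        rho = self.persistence
        p11 = p + rho * (1.0 - p)
        p01 = p * (1.0 - rho) if p < 1.0 else 1.0
        return p01, p11

    @classmethod
    def from_weekly_stats(
        cls,
        daily_mean: float,
        daily_variance: float,
        weekly_integrated_mean: float,
        persistence: float = 0.0,
    ) -> "PrecipWeekModel":
        """Build from the printed weekly statistics (any consistent depth
        unit); the wet probability is calibrated so the expected weekly total
        matches the integrated average."""
        p = calibrate_wet_probability(daily_mean, weekly_integrated_mean)
        return cls(daily_mean, daily_variance, p, persistence)


def default_precip_models(persistence: float = 0.0) -> tuple[PrecipWeekModel, ...]:
    """The eight weekly models calibrated to the study site's statistics,
    converted from inches to metres."""
    models = []
    for mu_in, var_in2, wk_in in zip(
        TABLE1_DAILY_MEAN_IN, TABLE1_DAILY_VARIANCE_IN2, TABLE1_WEEKLY_MEAN_IN
    ):
        mu = convert(mu_in, "inch", "m")
        var = var_in2 * convert(1.0, "inch", "m") ** 2
        wk = convert(wk_in, "inch", "m")
        models.append(PrecipWeekModel.from_weekly_stats(mu, var, wk, persistence))
    return tuple(models)


@dataclass(frozen=True)
class PriceModel:
    """Post-harvest corn price ~ Normal(april_price + mean_shift, sd²), $/kg,
    truncated at zero (negative draws are floored)."""

    april_price: float
    mean_shift: float = convert(-0.15, "usd_per_bushel", "usd_per_kg")
    sd: float = convert(0.34, "usd_per_bushel", "usd_per_kg")

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def mean(self) -> float:
        return self.april_price + self.mean_shift


def default_price_model(april_price_usd_per_bushel: float = 3.6) -> PriceModel:
    return PriceModel(convert(april_price_usd_per_bushel, "usd_per_bushel", "usd_per_kg"))


@dataclass(frozen=True)
class WaterLimitModel:
    """Seasonal irrigation allocation ~ Uniform(lower, upper), expressed as a
    gross depth per unit area (m); multiplied by farm area to give a volume."""

    lower: float = convert(11.0, "inch", "m")
    upper: float = convert(14.9, "inch", "m")

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper):
            raise ValueError("need 0 <= lower <= upper")

    @property
    def mean(self) -> float:
        return 0.5 * (self.lower + self.upper)


def default_water_limit_model() -> WaterLimitModel:
    return WaterLimitModel()


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_weekly_precipitation(
    models: Sequence[PrecipWeekModel], n: int, seed
) -> np.ndarray:
    """Simulate ``n`` seasons of weekly precipitation totals (m).

    For each week: 7 daily occurrence draws from the two-state chain started
    at its stationary distribution; wet days receive independent gamma
    amounts; the week's total is the sum.  Returns an (n, n_weeks) array.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    out = np.zeros((n, len(models)))
    for w, m in enumerate(models):
        if m.wet_prob == 0.0:
            continue
        p01, p11 = m.transition_probs
        u = rng.random((n, DAYS_PER_WEEK))
        wet = np.zeros((n, DAYS_PER_WEEK), dtype=bool)
        wet[:, 0] = u[:, 0] < m.wet_prob
        for d in range(1, DAYS_PER_WEEK):
            thresh = np.where(wet[:, d - 1], p11, p01)
            wet[:, d] = u[:, d] < thresh
        amounts = rng.gamma(m.gamma_shape, m.gamma_scale, size=(n, DAYS_PER_WEEK))
        out[:, w] = np.sum(amounts * wet, axis=1)
    return out


def sample_price(model: PriceModel, n: int, seed) -> np.ndarray:
    """Draw ``n`` prices ($/kg); negative normal draws are floored at 0."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    return np.maximum(0.0, rng.normal(model.mean, model.sd, size=n))


def sample_water_limit(model: WaterLimitModel, n: int, seed, area: float) -> np.ndarray:
    """Draw ``n`` farm-total seasonal water volumes (m³) for a farm of
    ``area`` m²."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    return rng.uniform(model.lower, model.upper, size=n) * area


@dataclass(frozen=True)
class ScenarioFan:
    """An equal- (or explicitly-) weighted set of sampled scenario paths."""

    prices: np.ndarray          # (n,) $/kg
    water_limits: np.ndarray    # (n,) m³
    precipitation: np.ndarray   # (n, T) m
    probabilities: np.ndarray   # (n,), sums to 1

    def __post_init__(self) -> None:
        n = len(self.prices)
        if not (len(self.water_limits) == len(self.probabilities)
                == self.precipitation.shape[0] == n):
            raise ValueError("inconsistent fan dimensions")
        if abs(float(np.sum(self.probabilities)) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def n_scenarios(self) -> int:
        return len(self.prices)

    @property
    def n_periods(self) -> int:
        return self.precipitation.shape[1]

    def realization(self, w: int) -> Realization:
        return Realization(
            price=float(self.prices[w]),
            water_limit=float(self.water_limits[w]),
            precipitation=self.precipitation[w].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"probability": self.probabilities,
                "price": self.prices, "water_limit": self.water_limits}
        for t in range(self.n_periods):
            cols[f"precip_{t + 1}"] = self.precipitation[:, t]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScenarioFan":
        pcols = sorted(
            (c for c in df.columns if c.startswith("precip_")),
            key=lambda c: int(c.split("_")[1]),
        )
        return cls(
            prices=df["price"].to_numpy(float),
            water_limits=df["water_limit"].to_numpy(float),
            precipitation=df[pcols].to_numpy(float),
            probabilities=df["probability"].to_numpy(float),
        )


def sample_scenario_fan(
    price_model: PriceModel,
    water_model: WaterLimitModel,
    precip_models: Sequence[PrecipWeekModel],
    n: int,
    seed,
    area: float,
) -> ScenarioFan:
    """Monte-Carlo fan of ``n`` equal-probability scenarios, the three
    components drawn independently."""
    rng = _as_rng(seed)
    prices = sample_price(price_model, n, rng)
    limits = sample_water_limit(water_model, n, rng, area)
    precip = simulate_weekly_precipitation(precip_models, n, rng)
    return ScenarioFan(
        prices=prices,
        water_limits=limits,
        precipitation=precip,
        probabilities=np.full(n, 1.0 / n),
    )


def ev_realization(
    price_model: PriceModel,
    water_model: WaterLimitModel,
    precip_models: Sequence[PrecipWeekModel],
    area: float,
) -> Realization:
    """The expected-value realization: every random quantity replaced by its
    mean (price mean, uniform midpoint × area, calibrated weekly precipitation
    means)."""
    return Realization(
        price=price_model.mean,
        water_limit=water_model.mean * area,
        precipitation=np.array([m.weekly_mean for m in precip_models]),
    )


# ---------------------------------------------------------------------------
# Scenario trees
# ---------------------------------------------------------------------------

@dataclass
class ScenarioTree:
    """Staged observation tree over (price, water limit, weekly precipitation).

    Node arrays are parallel; node 0 is the root (stage 0).  Stage-1 nodes
    carry the (price, water_limit) observation; stage-t nodes (2 ≤ t ≤ T)
    carry the precipitation total of week t−1; leaf nodes (stage T)
    additionally carry the final week's precipitation ``terminal_precip``
    (observed after the last decision, so it never branches).  Leaves are the
    scenarios; ``node_at_stage[w, t]`` gives scenario w's ancestor node at
    stage t and defines the nonanticipativity bundles.
    """

    parent: np.ndarray          # (N,) int, -1 at root
    stage: np.ndarray           # (N,) int
    cond_prob: np.ndarray       # (N,) conditional probability given parent
    price: np.ndarray           # (N,) nan except stage-1 nodes
    water_limit: np.ndarray     # (N,) m³, nan except stage-1 nodes
    precip: np.ndarray          # (N,) m, nan except stage >= 2 nodes
    terminal_precip: np.ndarray  # (N,) m, nan except leaves
    branching: tuple = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_stages(self) -> int:
        """Number of stages including the root stage 0 (= T + 1)."""
        return int(np.max(self.stage)) + 1

    @property
    def n_periods(self) -> int:
        return self.n_stages - 1

    @property
    def leaves(self) -> np.ndarray:
        return np.where(self.stage == self.n_periods)[0]

    @property
    def n_scenarios(self) -> int:
        return len(self.leaves)

    def children(self, node: int) -> np.ndarray:
        return np.where(self.parent == node)[0]

    @property
    def path_prob(self) -> np.ndarray:
        """Unconditional probability of each node."""
        p = np.ones(self.n_nodes)
        order = np.argsort(self.stage, kind="stable")
        for i in order:
            if self.parent[i] >= 0:
                p[i] = p[self.parent[i]] * self.cond_prob[i]
        return p

    @property
    def scenario_probs(self) -> np.ndarray:
        return self.path_prob[self.leaves]

    @property
    def node_at_stage(self) -> np.ndarray:
        """(n_scenarios, T+1) ancestor-node matrix; column t partitions the
        scenarios into the stage-t information bundles."""
        T = self.n_periods
        out = np.empty((self.n_scenarios, T + 1), dtype=int)
        for w, leaf in enumerate(self.leaves):
            node = int(leaf)
            for t in range(T, -1, -1):
                out[w, t] = node
                node = int(self.parent[node])
        return out

    def bundles(self, t: int) -> list[np.ndarray]:
        """Partition of scenario indices sharing history through stage t."""
        col = self.node_at_stage[:, t]
        return [np.where(col == node)[0] for node in np.unique(col)]

    def scenario_realization(self, w: int) -> Realization:
        """Full (price, water limit, R_1..R_T) path of scenario w."""
        T = self.n_periods
        path = self.node_at_stage[w]
        precip = np.empty(T)
        for t in range(2, T + 1):
            precip[t - 2] = self.precip[path[t]]
        precip[T - 1] = self.terminal_precip[path[T]]
        return Realization(
            price=float(self.price[path[1]]),
            water_limit=float(self.water_limit[path[1]]),
            precipitation=precip,
        )

    def as_fan(self) -> ScenarioFan:
        reals = [self.scenario_realization(w) for w in range(self.n_scenarios)]
        return ScenarioFan(
            prices=np.array([r.price for r in reals]),
            water_limits=np.array([r.water_limit for r in reals]),
            precipitation=np.array([r.precipitation for r in reals]),
            probabilities=self.scenario_probs,
        )

    def validate(self) -> None:
        if self.parent[0] != -1 or self.stage[0] != 0:
            raise ValueError("node 0 must be the root at stage 0")
        for i in range(1, self.n_nodes):
            p = self.parent[i]
            if p < 0 or self.stage[i] != self.stage[p] + 1:
                raise ValueError(f"node {i}: bad parent/stage structure")
        T = self.n_periods
        internal = np.where(self.stage < T)[0]
        for node in internal:
            kids = self.children(node)
            if len(kids) == 0:
                raise ValueError(f"non-leaf node {node} at stage {self.stage[node]}"
                                 " has no children (unbalanced tree)")
            s = float(np.sum(self.cond_prob[kids]))
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"children of node {node} have probs summing to {s}")
        if abs(float(np.sum(self.scenario_probs)) - 1.0) > 1e-9:
            raise ValueError("scenario probabilities do not sum to 1")

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node_id": np.arange(self.n_nodes),
            "parent_id": self.parent,
            "stage": self.stage,
            "cond_prob": self.cond_prob,
            "price": self.price,
            "water_limit": self.water_limit,
            "precip": self.precip,
            "terminal_precip": self.terminal_precip,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, branching=(), seed=None) -> "ScenarioTree":
        df = df.sort_values("node_id").reset_index(drop=True)
        return cls(
            parent=df["parent_id"].to_numpy(int),
            stage=df["stage"].to_numpy(int),
            cond_prob=df["cond_prob"].to_numpy(float),
            price=df["price"].to_numpy(float),
            water_limit=df["water_limit"].to_numpy(float),
            precip=df["precip"].to_numpy(float),
            terminal_precip=df["terminal_precip"].to_numpy(float),
            branching=tuple(branching),
            seed=seed,
        )


def _forward_medoids(
    values: np.ndarray, weights: np.ndarray, k: int
) -> tuple[list[int], np.ndarray]:
    """Greedy forward selection of k medoids minimizing the probability-
    weighted L1 transport distance to the selected set; returns (medoid
    positions, assignment of each point to a medoid position index)."""
    m = len(weights)
    vals = values.reshape(m, -1)
    if k >= m:
        return list(range(m)), np.arange(m)
    # pairwise weighted L1 distances, features standardized to comparable scale
    scale = np.std(vals, axis=0)
    scale[scale == 0] = 1.0
    v = vals / scale
    dist = np.sum(np.abs(v[:, None, :] - v[None, :, :]), axis=2)
    chosen: list[int] = []
    dmin = np.full(m, np.inf)
    for _ in range(k):
        # cost of adding candidate j: total weighted distance after inclusion
        cand_cost = np.array([
            np.sum(weights * np.minimum(dmin, dist[:, j])) for j in range(m)
        ])
        cand_cost[chosen] = np.inf
        j = int(np.argmin(cand_cost))
        chosen.append(j)
        dmin = np.minimum(dmin, dist[:, j])
    assign = np.argmin(dist[:, chosen], axis=1)
    return chosen, assign


def construct_tree(
    fan: ScenarioFan, branching: Sequence[int], seed: int | None = None
) -> ScenarioTree:
    """Reduce a Monte-Carlo fan to a staged scenario tree.

    ``branching[0]`` clusters the scenarios on the standardized (price,
    water-limit) pair; ``branching[t-1]`` for t = 2..T clusters each bundle on
    the week-(t−1) precipitation total.  Cluster representatives are medoids
    under the probability-weighted L1 distance, so every tree path is an
    actually-sampled path; cluster probability is the summed member weight.
    The product of branching factors (the leaf count) must not exceed the fan
    size.  The construction is deterministic given the fan.
    """
    T = fan.n_periods
    branching = tuple(int(b) for b in branching)
    if len(branching) > T:
        raise ValueError(f"branching vector longer than the {T}-period horizon")
    branching = branching + (1,) * (T - len(branching))
    if any(b < 1 for b in branching):
        raise ValueError("branching factors must be >= 1")
    if int(np.prod(branching)) > fan.n_scenarios:
        raise ValueError(
            f"requested {int(np.prod(branching))} leaves from a fan of "
            f"{fan.n_scenarios} scenarios"
        )

    parent = [-1]
    stage = [0]
    cond_prob = [1.0]
    price = [np.nan]
    wl = [np.nan]
    precip = [np.nan]
    term = [np.nan]

    def add_node(par, stg, prob, pr=np.nan, w=np.nan, r=np.nan, tr=np.nan) -> int:
        parent.append(par)
        stage.append(stg)
        cond_prob.append(prob)
        price.append(pr)
        wl.append(w)
        precip.append(r)
        term.append(tr)
        return len(parent) - 1

    # groups at the frontier: (node_id, member indices into the fan)
    weights = fan.probabilities
    stage1_vals = np.column_stack([fan.prices, fan.water_limits])
    medoids, assign = _forward_medoids(stage1_vals, weights, branching[0])
    frontier: list[tuple[int, np.ndarray]] = []
    total_w = {}
    for ci, med in enumerate(medoids):
        members = np.where(assign == ci)[0]
        if len(members) == 0:
            continue
        wsum = float(np.sum(weights[members]))
        node = add_node(0, 1, wsum, pr=float(fan.prices[med]),
                        w=float(fan.water_limits[med]))
        frontier.append((node, members, med))
        total_w[node] = wsum

    for t in range(2, T + 1):
        new_frontier = []
        for node, members, _ in frontier:
            vals = fan.precipitation[members, t - 2]
            sub_w = weights[members]
            medoids, assign = _forward_medoids(vals, sub_w, branching[t - 1])
            parent_w = total_w[node]
            for ci, med in enumerate(medoids):
                sub = members[assign == ci]
                if len(sub) == 0:
                    continue
                wsum = float(np.sum(weights[sub]))
                child = add_node(node, t, wsum / parent_w,
                                 r=float(fan.precipitation[members[med], t - 2]))
                new_frontier.append((child, sub, members[med]))
                total_w[child] = wsum
        frontier = new_frontier

    # leaves: attach the final week's precipitation of the leaf medoid path
    term_arr = np.array(term)
    for node, members, med in frontier:
        term_arr[node] = fan.precipitation[med, T - 1]

    return ScenarioTree(
        parent=np.array(parent, dtype=int),
        stage=np.array(stage, dtype=int),
        cond_prob=np.array(cond_prob),
        price=np.array(price),
        water_limit=np.array(wl),
        precip=np.array(precip),
        terminal_precip=term_arr,
        branching=branching,
        seed=seed,
    )


def tree_from_fan(fan: ScenarioFan, seed: int | None = None) -> ScenarioTree:
    """Lossless tree: every fan scenario becomes its own branch at stage 1
    (distinct price/water-limit observation) with a single chain below it."""
    branching = (fan.n_scenarios,) + (1,) * (fan.n_periods - 1)
    return construct_tree(fan, branching, seed=seed)


def single_scenario_tree(realization: Realization) -> ScenarioTree:
    """Degenerate one-scenario tree for collapse/consistency checks."""
    T = len(realization.precipitation)
    fan = ScenarioFan(
        prices=np.array([realization.price]),
        water_limits=np.array([realization.water_limit]),
        precipitation=realization.precipitation.reshape(1, T),
        probabilities=np.array([1.0]),
    )
    return construct_tree(fan, (1,) * T)
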
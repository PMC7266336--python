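"""Mixed-integer linear programs for irrigation planning.

Three models share one core:

* **deterministic** — all parameters known; chooses one pre-season management
  option x_i, weekly net irrigation y_t with event indicators z_t, and a
  deficit level d_l on a discrete grid that ties the season ET ratio to the
  yield-response function through big-M coupling constraints.
* **multistage stochastic** — scenario-indexed copy of the deterministic
  constraints on a scenario tree; x is shared by all scenarios and the y_t
  are nonanticipative: equal across scenarios that share the stage-t
  information bundle (price and water limit known from the start of week 1,
  week-t precipitation only after week t).
* **two-stage stochastic** — identical except the whole irrigation schedule
  y_1..y_T is committed once the price and water limit are observed; the
  precipitation still differentiates the soil-water states and yields per
  scenario when the objective is evaluated.

The deficit-level equality ties (Σ_t ET^a_t)/(Σ_t ET^m_t) to the selected
grid value Σ_l d_l D_l within half a grid step (a continuous ratio cannot hit
the 0.01 grid exactly).  Two big-M constants with distinct physical
dimensions are used: a yield-scale bound (max_i Y^m_i) in the yield-coupling
constraints and a depth-scale bound (H + max_t ET^m_t) in the irrigation
event indicator.  The per-period physical cap ET^a_t ≤ ET^m_t is enforced so
that a week's crop water use can never exceed its unstressed demand.

Solving goes through :func:`solve`, whose default backend is HiGHS via
``scipy.optimize.milp``; a self-contained branch-and-bound over the HiGHS LP
relaxation (`backend="branch-and-bound"`) is provided as an independent
cross-check for small models.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog
from scipy.optimize import milp as _scipy_milp

from .scenarios import ScenarioTree
from .types import (
    DecisionPlan,
    FarmInstance,
    Realization,
    Trajectory,
    profit as compute_profit,
)

__all__ = [
    "ModelSpec",
    "Solution",
    "build_deterministic",
    "build_multistage",
    "build_twostage",
    "solve",
    "extract_plan",
    "StochasticPlan",
]

_INF = np.inf


@dataclass
class ModelSpec:
    """A solver-agnostic mixed-integer linear program (maximization)."""

    var_names: list[str] = field(default_factory=list)
    lb: list[float] = field(default_factory=list)
    ub: list[float] = field(default_factory=list)
    integer: list[bool] = field(default_factory=list)
    objective: dict[int, float] = field(default_factory=dict)
    objective_constant: float = 0.0
    # constraints as (name, {var: coef}, lower, upper)
    constraints: list[tuple[str, dict[int, float], float, float]] = field(
        default_factory=list
    )
    meta: dict = field(default_factory=dict)

    # -- building -----------------------------------------------------------
    def add_var(
        self, name: str, lb: float = 0.0, ub: float = _INF, binary: bool = False
    ) -> int:
        self.var_names.append(name)
        self.lb.append(0.0 if binary else lb)
        self.ub.append(1.0 if binary else ub)
        self.integer.append(binary)
        return len(self.var_names) - 1

    def add_constr(
        self,
        name: str,
        terms: dict[int, float],
        lb: float = -_INF,
        ub: float = _INF,
    ) -> None:
        self.constraints.append((name, dict(terms), lb, ub))

    def add_objective_terms(self, terms: dict[int, float]) -> None:
        for idx, coef in terms.items():
            self.objective[idx] = self.objective.get(idx, 0.0) + coef

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    @property
    def n_binaries(self) -> int:
        return int(np.sum(self.integer))

    # -- matrix form --------------------------------------------------------
    def matrices(self):
        n = self.n_vars
        c = np.zeros(n)
        for idx, coef in self.objective.items():
            c[idx] = coef
        rows, cols, vals = [], [], []
        clb, cub = [], []
        for r, (_, terms, lo, hi) in enumerate(self.constraints):
            for idx, coef in terms.items():
                rows.append(r)
                cols.append(idx)
                vals.append(coef)
            clb.append(lo)
            cub.append(hi)
        A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.constraints), n)
        )
        return c, A, np.array(clb), np.array(cub)

    def constraint_violation(self, x: np.ndarray) -> float:
        """Largest absolute violation of any constraint or bound at x."""
        _, A, clb, cub = self.matrices()
        ax = A @ x
        viol = max(
            float(np.max(np.maximum(clb - ax, 0.0), initial=0.0)),
            float(np.max(np.maximum(ax - cub, 0.0), initial=0.0)),
            float(np.max(np.maximum(np.array(self.lb) - x, 0.0), initial=0.0)),
            float(np.max(np.maximum(x - np.array(self.ub), 0.0), initial=0.0)),
        )
        return viol

    def objective_value(self, x: np.ndarray) -> float:
        c, *_ = self.matrices()
        return float(c @ x) + self.objective_constant

    # -- debugging ----------------------------------------------------------
    def to_lp_string(self) -> str:
        """CPLEX-LP-format text dump of the model (for inspection)."""
        def term_str(terms: dict[int, float]) -> str:
            parts = []
            for idx in sorted(terms):
                coef = terms[idx]
                sign = "+" if coef >= 0 else "-"
                parts.append(f"{sign} {abs(coef):.12g} {self.var_names[idx]}")
            return " ".join(parts) if parts else "0"

        lines = ["Maximize", f" obj: {term_str(self.objective)}", "Subject To"]
        for name, terms, lo, hi in self.constraints:
            if lo == hi:
                lines.append(f" {name}: {term_str(terms)} = {lo:.12g}")
            else:
                if np.isfinite(hi):
                    lines.append(f" {name}_u: {term_str(terms)} <= {hi:.12g}")
                if np.isfinite(lo):
                    lines.append(f" {name}_l: {term_str(terms)} >= {lo:.12g}")
        lines.append("Bounds")
        for i, nm in enumerate(self.var_names):
            if not self.integer[i]:
                ub = f"{self.ub[i]:.12g}" if np.isfinite(self.ub[i]) else "+inf"
                lines.append(f" {self.lb[i]:.12g} <= {nm} <= {ub}")
        lines.append("Binaries")
        lines.append(" " + " ".join(
            nm for i, nm in enumerate(self.var_names) if self.integer[i]
        ))
        lines.append("End")
        return "\n".join(lines)


@dataclass
class Solution:
    """Result of solving a :class:`ModelSpec`."""

    status: str                 # optimal | gap_limited | infeasible | unbounded | error
    objective: float
    x: np.ndarray | None
    gap: float
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status in ("optimal", "gap_limited") and self.x is not None

    def value(self, spec: ModelSpec, name: str) -> float:
        return float(self.x[spec.var_names.index(name)])


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------

def _yield_coef(instance: FarmInstance, i: int, l: int) -> float:
    """Y^m_i (1 − K_i (1 − D_l)): yield of option i at deficit level l."""
    opt = instance.options[i]
    return opt.max_yield * (1.0 - opt.response_factor * (1.0 - instance.deficit_grid[l]))


def _add_scenario_block(
    spec: ModelSpec,
    instance: FarmInstance,
    realization: Realization,
    x_idx: Sequence[int],
    y_idx: Sequence[int],
    z_idx: Sequence[int],
    tag: str,
    min_yield: float | None = None,
) -> dict[str, list[int]]:
    """Add the per-scenario state variables and physical/yield constraints
    (soil-water balance, capacity, ET cap, deficit link, yield coupling,
    water limit, minimum yield) for one realization, wiring them to the given
    decision variables.  Returns the indices of the created state variables.
    """
    T = instance.n_periods
    L = instance.n_levels
    H = instance.holding_capacity
    mb = instance.big_m_yield
    R = realization.precipitation
    etm = instance.max_et
    if min_yield is None:
        min_yield = instance.min_yield

    m_idx = [spec.add_var(f"M[{tag}{t}]", 0.0, H) for t in range(1, T + 1)]
    eta_idx = [spec.add_var(f"ETa[{tag}{t}]", 0.0, float(etm[t - 1]))
               for t in range(1, T + 1)]
    lw_idx = [spec.add_var(f"LW[{tag}{t}]", 0.0) for t in range(1, T + 1)]
    d_idx = [spec.add_var(f"d[{tag}{l}]", binary=True) for l in range(L)]
    # per-level yield upper bound max_i Y^m_i (1-K_i(1-D_l)): a valid bound
    # for binary x/d that greatly tightens the LP relaxation of the big-M
    # coupling (without it the relaxation pretends full yield at any deficit)
    yc_ub = [
        max(0.0, max(_yield_coef(instance, i, l) for i in range(instance.n_options)))
        for l in range(L)
    ]
    yc_idx = [spec.add_var(f"Yc[{tag}{l}]", 0.0, min(mb, yc_ub[l]))
              for l in range(L)]

    # dry spring: no stored soil water at the start of week 1
    spec.ub[m_idx[0]] = 0.0

    for t in range(T):
        # water balance: M_t + y_t + R_t - ETa_t - LW_t (= M_{t+1} | >= 0)
        terms = {m_idx[t]: 1.0, y_idx[t]: 1.0, eta_idx[t]: -1.0, lw_idx[t]: -1.0}
        if t < T - 1:
            terms[m_idx[t + 1]] = -1.0
            spec.add_constr(f"balance[{tag}{t + 1}]", terms,
                            lb=-float(R[t]), ub=-float(R[t]))
        else:
            spec.add_constr(f"balance[{tag}{t + 1}]", terms, lb=-float(R[t]))
        # capacity: inflow net of leaching fits in the root zone
        spec.add_constr(
            f"capacity[{tag}{t + 1}]",
            {m_idx[t]: 1.0, y_idx[t]: 1.0, lw_idx[t]: -1.0},
            ub=H - float(R[t]),
        )

    # deficit-level definition: season ET ratio snapped to the grid
    et_total = float(np.sum(etm))
    tol = instance.deficit_half_step * et_total
    terms = {idx: 1.0 for idx in eta_idx}
    for l in range(L):
        terms[d_idx[l]] = -et_total * float(instance.deficit_grid[l])
    spec.add_constr(f"deficit_link[{tag}]", terms, lb=-tol, ub=tol)

    # exactly one deficit level
    spec.add_constr(f"one_level[{tag}]", {idx: 1.0 for idx in d_idx}, lb=1.0, ub=1.0)

    # yield response coupling (big-M): Yc_l = Σ_i x_i Ym_i (1-K_i(1-D_l))
    # when d_l = 1; slack otherwise; unselected levels forced to zero yield
    for l in range(L):
        base = {yc_idx[l]: 1.0}
        for i in range(instance.n_options):
            base[x_idx[i]] = -_yield_coef(instance, i, l)
        up = dict(base)
        up[d_idx[l]] = mb
        spec.add_constr(f"yield_ub[{tag}{l}]", up, ub=mb)
        lo = dict(base)
        lo[d_idx[l]] = -mb
        spec.add_constr(f"yield_lb[{tag}{l}]", lo, lb=-mb)
        # "as small as possible" big-M: the level-specific yield bound
        spec.add_constr(f"yield_sel[{tag}{l}]",
                        {yc_idx[l]: 1.0, d_idx[l]: -min(mb, yc_ub[l])}, ub=0.0)
        # valid strengthening: the selected option caps the level's yield
        cap = {yc_idx[l]: 1.0}
        for i in range(instance.n_options):
            cap[x_idx[i]] = -max(0.0, _yield_coef(instance, i, l))
        spec.add_constr(f"yield_cap[{tag}{l}]", cap, ub=0.0)

    # seasonal water limit (gross of application efficiency)
    spec.add_constr(
        f"water_limit[{tag}]",
        {idx: instance.area / instance.efficiency for idx in y_idx},
        ub=float(realization.water_limit),
    )

    # minimum total yield mandate
    if min_yield > 0:
        spec.add_constr(
            f"min_yield[{tag}]",
            {idx: instance.area for idx in yc_idx},
            lb=float(min_yield),
        )

    # irrigation event indicator: y_t <= (H + max ET) z_t
    md = instance.big_m_depth
    for t in range(T):
        spec.add_constr(f"event[{tag}{t + 1}]",
                        {y_idx[t]: 1.0, z_idx[t]: -md}, ub=0.0)

    return {"M": m_idx, "ETa": eta_idx, "LW": lw_idx, "d": d_idx, "Yc": yc_idx}


def _add_first_stage(spec: ModelSpec, instance: FarmInstance) -> list[int]:
    x_idx = [spec.add_var(f"x[{i}]", binary=True) for i in range(instance.n_options)]
    spec.add_constr("one_option", {idx: 1.0 for idx in x_idx}, lb=1.0, ub=1.0)
    spec.add_objective_terms({
        x_idx[i]: -instance.area
        * (instance.options[i].seed_cost + instance.options[i].operating_cost)
        for i in range(instance.n_options)
    })
    spec.objective_constant -= (
        instance.overhead
        + instance.area * instance.water_cost * instance.pre_irrigation
    )
    return x_idx


def build_deterministic(instance: FarmInstance, realization: Realization) -> ModelSpec:
    """Deterministic planning MILP for a single known realization."""
    T = instance.n_periods
    if len(realization.precipitation) != T:
        raise ValueError("realization horizon does not match the instance")
    spec = ModelSpec(meta={"kind": "deterministic", "instance": instance,
                           "realization": realization})
    x_idx = _add_first_stage(spec, instance)
    y_idx = [spec.add_var(f"y[{t}]", 0.0, instance.big_m_depth)
             for t in range(1, T + 1)]
    z_idx = [spec.add_var(f"z[{t}]", binary=True) for t in range(1, T + 1)]
    state = _add_scenario_block(spec, instance, realization, x_idx, y_idx, z_idx, "")
    a = instance.area
    spec.add_objective_terms({idx: realization.price * a for idx in state["Yc"]})
    spec.add_objective_terms({
        idx: -a * instance.water_cost / instance.efficiency for idx in y_idx
    })
    spec.add_objective_terms({idx: -a * instance.fixed_irrigation_cost
                              for idx in z_idx})
    spec.meta.update(x=x_idx, y=y_idx, z=z_idx, state=state)
    return spec


def _build_stochastic(
    instance: FarmInstance,
    tree: ScenarioTree,
    mode: str,
    nonanticipativity: str = "node",
) -> ModelSpec:
    T = instance.n_periods
    if tree.n_periods != T:
        raise ValueError(
            f"tree has {tree.n_periods} periods, instance has {T}"
        )
    spec = ModelSpec(meta={"kind": mode, "instance": instance, "tree": tree})
    x_idx = _add_first_stage(spec, instance)

    node_at_stage = tree.node_at_stage
    probs = tree.scenario_probs
    n_scen = tree.n_scenarios

    # decision keys: which scenarios share the week-t irrigation decision.
    # multistage: the stage-t tree node (knows price, limit, R_1..R_{t-1});
    # two-stage: the stage-1 node for every week (whole schedule committed
    # once price and water limit are seen).
    def decision_key(w: int, t: int):
        if mode == "multistage":
            return int(node_at_stage[w, t])
        return (int(node_at_stage[w, 1]), t)

    a = instance.area
    y_of: dict = {}
    z_of: dict = {}
    scen_y: list[list[int]] = []
    scen_z: list[list[int]] = []
    if nonanticipativity == "node":
        for w in range(n_scen):
            ys, zs = [], []
            for t in range(1, T + 1):
                key = decision_key(w, t)
                if key not in y_of:
                    y_of[key] = spec.add_var(f"y[{key}]", 0.0, instance.big_m_depth)
                    z_of[key] = spec.add_var(f"z[{key}]", binary=True)
                ys.append(y_of[key])
                zs.append(z_of[key])
            scen_y.append(ys)
            scen_z.append(zs)
    elif nonanticipativity == "explicit":
        for w in range(n_scen):
            scen_y.append([
                spec.add_var(f"y[w{w},{t}]", 0.0, instance.big_m_depth)
                for t in range(1, T + 1)
            ])
            scen_z.append([
                spec.add_var(f"z[w{w},{t}]", binary=True) for t in range(1, T + 1)
            ])
        groups: dict = {}
        for w in range(n_scen):
            for t in range(1, T + 1):
                groups.setdefault(decision_key(w, t), []).append((w, t))
        for key, members in groups.items():
            w0, t0 = members[0]
            for w, t in members[1:]:
                spec.add_constr(
                    f"nonant_y[{key},w{w}]",
                    {scen_y[w0][t0 - 1]: 1.0, scen_y[w][t - 1]: -1.0},
                    lb=0.0, ub=0.0,
                )
                spec.add_constr(
                    f"nonant_z[{key},w{w}]",
                    {scen_z[w0][t0 - 1]: 1.0, scen_z[w][t - 1]: -1.0},
                    lb=0.0, ub=0.0,
                )
    else:
        raise ValueError("nonanticipativity must be 'node' or 'explicit'")

    states = []
    for w in range(n_scen):
        real = tree.scenario_realization(w)
        state = _add_scenario_block(
            spec, instance, real, x_idx, scen_y[w], scen_z[w], f"w{w},"
        )
        states.append(state)
        pw = float(probs[w])
        spec.add_objective_terms({idx: pw * real.price * a for idx in state["Yc"]})
        spec.add_objective_terms({
            idx: -pw * a * instance.water_cost / instance.efficiency
            for idx in scen_y[w]
        })
        spec.add_objective_terms({
            idx: -pw * a * instance.fixed_irrigation_cost for idx in scen_z[w]
        })
    spec.meta.update(x=x_idx, scen_y=scen_y, scen_z=scen_z, states=states,
                     probs=probs)
    return spec


def build_multistage(
    instance: FarmInstance, tree: ScenarioTree, nonanticipativity: str = "node"
) -> ModelSpec:
    """Multistage stochastic MILP: week-t irrigation adapts to the price,
    the water limit and the precipitation observed through week t−1."""
    return _build_stochastic(instance, tree, "multistage", nonanticipativity)


def build_twostage(
    instance: FarmInstance, tree: ScenarioTree, nonanticipativity: str = "node"
) -> ModelSpec:
    """Two-stage stochastic MILP: the whole irrigation schedule is committed
    after observing price and water limit; precipitation uncertainty only
    enters the evaluation of soil states and yields."""
    return _build_stochastic(instance, tree, "twostage", nonanticipativity)


# ---------------------------------------------------------------------------
# Solving
# ---------------------------------------------------------------------------

def solve(
    spec: ModelSpec,
    gap_tol: float = 1e-6,
    time_limit: float | None = None,
    seed: int | None = None,
    backend: str = "highs",
) -> Solution:
    """Solve a model spec to proven optimality (relative gap ≤ ``gap_tol``).

    ``backend="highs"`` uses scipy's HiGHS branch-and-cut; ``backend=
    "branch-and-bound"`` uses the package's own best-first branch-and-bound
    over the HiGHS LP relaxation (intended for small cross-check models).
    ``seed`` is recorded for provenance; the backends are deterministic.
    """
    if backend == "highs":
        return _solve_highs(spec, gap_tol, time_limit)
    if backend == "branch-and-bound":
        return _solve_bnb(spec, gap_tol)
    raise ValueError(f"unknown backend {backend!r}")


def _solve_highs(spec: ModelSpec, gap_tol: float, time_limit: float | None) -> Solution:
    c, A, clb, cub = spec.matrices()
    options: dict = {"mip_rel_gap": gap_tol}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = _scipy_milp(
        c=-c,
        constraints=LinearConstraint(A, clb, cub),
        integrality=np.array(spec.integer, dtype=int),
        bounds=Bounds(np.array(spec.lb), np.array(spec.ub)),
        options=options,
    )
    if res.status == 2:
        return Solution("infeasible", np.nan, None, np.nan, res.message)
    if res.status == 3:
        return Solution("unbounded", np.nan, None, np.nan, res.message)
    if res.x is None:
        return Solution("error", np.nan, None, np.nan, res.message)
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    status = "optimal" if res.status == 0 else "gap_limited"
    obj = -float(res.fun) + spec.objective_constant
    return Solution(status, obj, np.asarray(res.x, dtype=float), gap, res.message)


def _solve_bnb(spec: ModelSpec, gap_tol: float, max_nodes: int = 200_000) -> Solution:
    """Best-first branch-and-bound on the LP relaxation (maximization)."""
    c, A, clb, cub = spec.matrices()
    eq = clb == cub
    A_eq = A[eq] if np.any(eq) else None
    b_eq = clb[eq] if np.any(eq) else None
    ineq = ~eq
    rows_ub, rhs_ub = [], []
    if np.any(ineq):
        Ai, lo, hi = A[ineq], clb[ineq], cub[ineq]
        fin_hi = np.isfinite(hi)
        if np.any(fin_hi):
            rows_ub.append(Ai[fin_hi])
            rhs_ub.append(hi[fin_hi])
        fin_lo = np.isfinite(lo)
        if np.any(fin_lo):
            rows_ub.append(-Ai[fin_lo])
            rhs_ub.append(-lo[fin_lo])
    A_ub = sparse.vstack(rows_ub) if rows_ub else None
    b_ub = np.concatenate(rhs_ub) if rhs_ub else None
    int_idx = np.where(spec.integer)[0]

    def lp(lo: np.ndarray, hi: np.ndarray):
        res = linprog(-c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=np.column_stack([lo, hi]), method="highs")
        if res.status != 0:
            return None, None
        return -float(res.fun), np.asarray(res.x)

    lo0, hi0 = np.array(spec.lb, float), np.array(spec.ub, float)
    bound, x0 = lp(lo0, hi0)
    if bound is None:
        return Solution("infeasible", np.nan, None, np.nan, "root LP infeasible")
    best_obj, best_x = -np.inf, None
    counter = itertools.count()
    heap = [(-bound, next(counter), lo0, hi0, x0)]
    nodes = 0
    while heap and nodes < max_nodes:
        neg_bound, _, lo, hi, x = heapq.heappop(heap)
        nodes += 1
        if -neg_bound <= best_obj + abs(best_obj) * gap_tol + 1e-12:
            break
        frac = np.abs(x[int_idx] - np.round(x[int_idx]))
        if len(int_idx) == 0 or np.all(frac < 1e-7):
            obj = float(c @ x)
            if obj > best_obj:
                best_obj, best_x = obj, x.copy()
                if best_x is not None:
                    best_x[int_idx] = np.round(best_x[int_idx])
            continue
        j = int(int_idx[np.argmax(frac)])
        floor = np.floor(x[j])
        for new_lo, new_hi in (
            (None, floor), (floor + 1.0, None)
        ):
            l2, h2 = lo.copy(), hi.copy()
            if new_hi is not None:
                h2[j] = min(h2[j], new_hi)
            if new_lo is not None:
                l2[j] = max(l2[j], new_lo)
            if l2[j] > h2[j]:
                continue
            b2, x2 = lp(l2, h2)
            if b2 is None or b2 <= best_obj + 1e-12:
                continue
            heapq.heappush(heap, (-b2, next(counter), l2, h2, x2))
    if best_x is None:
        return Solution("infeasible", np.nan, None, np.nan,
                        "no integer-feasible point found")
    remaining = max((-h[0] for h in heap), default=best_obj)
    gap = max(0.0, (remaining - best_obj) / max(1.0, abs(best_obj)))
    status = "optimal" if gap <= gap_tol else "gap_limited"
    return Solution(status, best_obj + spec.objective_constant, best_x, gap)


# ---------------------------------------------------------------------------
# Plan extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StochasticPlan:
    """First-stage option choice plus the per-scenario irrigation schedules
    and trajectories of a stochastic solution."""

    option_choice: np.ndarray
    scenario_plans: tuple[DecisionPlan, ...]
    scenario_trajectories: tuple[Trajectory, ...]
    probabilities: np.ndarray

    @property
    def option_index(self) -> int:
        return int(np.argmax(self.option_choice))

    @property
    def mean_weekly_irrigation(self) -> np.ndarray:
        """Probability-weighted average irrigation depth per week (m)."""
        ys = np.array([p.irrigation for p in self.scenario_plans])
        return self.probabilities @ ys

    @property
    def expected_profit(self) -> float:
        return float(self.probabilities
                     @ np.array([tr.profit for tr in self.scenario_trajectories]))


def _round_binary(value: float, what: str) -> int:
    if abs(value - round(value)) > 1e-4:
        raise ValueError(f"{what} = {value} is not integral")
    return int(round(value))


def _extract_block(
    spec: ModelSpec,
    x: np.ndarray,
    instance: FarmInstance,
    realization: Realization,
    y_idx: Sequence[int],
    z_idx: Sequence[int],
    state: dict,
) -> tuple[DecisionPlan, Trajectory]:
    xvec = np.array([_round_binary(x[i], spec.var_names[i])
                     for i in spec.meta["x"]])
    if xvec.sum() != 1:
        raise ValueError("inconsistent option choice after rounding")
    y = np.maximum(0.0, np.array([x[i] for i in y_idx]))
    z = np.array([_round_binary(x[i], spec.var_names[i]) for i in z_idx])
    plan = DecisionPlan(option_choice=xvec, irrigation=y, flags=z)
    d = np.array([_round_binary(x[i], spec.var_names[i]) for i in state["d"]])
    if d.sum() != 1:
        raise ValueError("inconsistent deficit-level selection after rounding")
    l_star = int(np.argmax(d))
    yc = float(sum(x[i] for i in state["Yc"]))
    option = instance.options[plan.option_index]
    traj = Trajectory(
        soil_moisture=np.array([x[i] for i in state["M"]]),
        actual_et=np.array([x[i] for i in state["ETa"]]),
        leaching=np.array([x[i] for i in state["LW"]]),
        deficit_index=l_star,
        deficit_fraction=float(instance.deficit_grid[l_star]),
        actual_yield=yc,
        profit=compute_profit(instance, option, realization, plan, yc),
    )
    return plan, traj


def extract_plan(solution: Solution, spec: ModelSpec):
    """Recover the decision plan (and trajectories) from a solved model.

    Deterministic specs return ``(DecisionPlan, Trajectory)``; stochastic
    specs return a :class:`StochasticPlan`.  Binaries are rounded at 0.5 and
    re-checked for consistency (one option, one deficit level per scenario).
    """
    if not solution.ok:
        raise ValueError(f"cannot extract a plan from a {solution.status} solution")
    x = solution.x
    kind = spec.meta.get("kind")
    instance: FarmInstance = spec.meta["instance"]
    if kind == "deterministic":
        return _extract_block(
            spec, x, instance, spec.meta["realization"],
            spec.meta["y"], spec.meta["z"], spec.meta["state"],
        )
    tree: ScenarioTree = spec.meta["tree"]
    plans, trajs = [], []
    for w in range(tree.n_scenarios):
        real = tree.scenario_realization(w)
        plan, traj = _extract_block(
            spec, x, instance, real,
            spec.meta["scen_y"][w], spec.meta["scen_z"][w],
            spec.meta["states"][w],
        )
        plans.append(plan)
        trajs.append(traj)
    xvec = np.array([_round_binary(x[i], spec.var_names[i])
                     for i in spec.meta["x"]])
    return StochasticPlan(
        option_choice=xvec,
        scenario_plans=tuple(plans),
        scenario_trajectories=tuple(trajs),
        probabilities=np.asarray(spec.meta["probs"], dtype=float),
    )
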
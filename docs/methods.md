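# Methods

`irriplan` models a single season of irrigated corn on one farm. The planner
makes one pre-season decision — which seed-type / plant-population bundle to
buy — and then schedules weekly net irrigation over the eight-week flowering
and grain-filling window, the stage in which corn is most sensitive to water
stress. Profit is revenue minus water purchases (gross of application
efficiency, including a spring pre-irrigation), per-event fixed irrigation
costs, seed and operating costs, and whole-farm overhead.

## The planning model

All depths (soil moisture, irrigation, rain, evapotranspiration) are metres
of water over the effective root zone; the internal unit system is SI, with
field units (acres, inches, $/acre-inch, bu/acre) converted exactly at the
I/O boundary.

**Water balance.** With soil moisture M_t at the start of week t (M_1 = 0 —
a deliberately conservative dry-spring assumption), net irrigation y_t,
rain R_t, actual crop evapotranspiration ETa_t and leaching L_t:

    M_t + y_t + R_t − ETa_t − L_t = M_{t+1},    M_t + y_t + R_t − L_t ≤ H,

so any inflow beyond the holding capacity H leaches and is lost. ETa_t is
additionally capped at the week's unstressed demand ETm_t. This per-week cap
is implicit in the definition of the seasonal deficit (a ratio of actual to
unstressed ET cannot exceed one week-by-week) and is required for the greedy
plan evaluator (below) to be the exact optimizer of the frozen-decision
subproblem; it is enforced as a variable bound.

**Yield response.** The season deficit ratio r = Σ_t ETa_t / Σ_t ETm_t is
snapped to a discrete grid D_1 = 0 < … < D_L = 1 (default 101 equidistant
levels) by binary level indicators d_l with Σ_l d_l = 1, and the yield of
the chosen option i follows the classic water-stress response

    Y = Ym_i (1 − K_i (1 − D_l)),

where Ym_i is the option's unstressed yield and K_i its integrated response
factor for the flowering + grain-filling stage. The link between r and the
selected grid value is enforced as a two-sided inequality with tolerance of
half a grid step (±0.005 at the default grid): a continuous ratio cannot hit
the grid exactly, and the half-step band makes every ratio feasible for
exactly its nearest level (ties going to the higher level). A consequence
worth knowing: an optimal schedule typically irrigates *exactly* to the
lower tolerance edge of its deficit level, so post-hoc re-evaluations of an
optimal plan must resolve the resulting knife-edge consistently (the
evaluator breaks near-ties upward with a 1e-5 slack, well below the
scientific resolution of the grid but above solver feasibility noise).

**Big-M structure.** The level/option/yield coupling uses indicator
constraints linearized with big-M constants. Two physically distinct
constants are used: a yield-scale bound (max_i Ym_i) in the yield coupling
and a depth-scale bound (H + max_t ETm_t, a valid upper bound on any useful
weekly application) in the irrigation-event indicator y_t ≤ M z_t. The raw
big-M relaxation is numerically valid but weak — its LP bound pretends full
yield at any water level — so the builder adds strengthening that preserves
every integer-feasible point: per-level upper bounds Yc_l ≤ max_i
coef(i, l), level-specific big-M in the selection constraint, and the valid
inequality Yc_l ≤ Σ_i x_i · max(0, coef(i, l)). On a 16-scenario two-stage
model this cuts solve time by roughly an order of magnitude.

**Stochastic extensions.** Price G and the seasonal allocation W are
observed at the start of week 1; the week-t rain total is observed at the
*end* of week t. A scenario tree encodes this: stage-1 nodes branch on
(G, W), stage-t nodes (t ≥ 2) branch on R_{t−1}, and the final week's rain
rides on the leaves without branching (nothing is decided after it). The
multistage model attaches one irrigation variable to each tree node
(node-variable nonanticipativity; an explicit scenario-variable + equality
formulation is also provided and gives identical optima). The two-stage
variant commits the whole schedule at the stage-1 node — precipitation then
only differentiates the soil states and yields used to evaluate the
objective. The pre-season choice x is shared by all scenarios in both. Since
the two-stage information pattern is a restriction of the multistage one,
and perfect information relaxes both, the ladder

    EEV ≤ vfTS ≤ vfMS ≤ WS

holds at optimality up to solver tolerance; the test suite asserts it on 50
random fixtures.

## Scenario generation

Three independent uncertainty sources, with defaults calibrated to the
Nebraska sandhills study conditions:

* **Price** ($/kg): normal with mean = April price − 0.15 $/bu and
  sd = 0.34 $/bu; negative draws are floored at zero (the floor is ~10 sd
  below the mean at the default April price of 3.6 $/bu, so the truncation
  is immaterial there).
* **Seasonal allocation**: uniform between 11.0 and 14.9 inches/acre,
  multiplied by farm area into a pumped volume.
* **Weekly rain**: for each of the 8 weeks, 7 daily draws from a two-state
  occurrence chain whose stationary wet probability p is calibrated so that
  7 · p · μ_daily equals the week's integrated average; wet-day amounts are
  gamma with shape μ²/σ² and scale σ²/μ moment-matched to the week's daily
  mean and variance. The published weekly tables identify p but not the
  chain's persistence, so occurrence defaults to i.i.d. (ρ = 0) with an
  optional persistence parameter (p11 = p + ρ(1 − p), p01 solved from
  stationarity). Moment matching reproduces the daily mean/variance exactly
  and the printed medians to within 0.01 (week 1: fitted 0.333 vs printed
  0.33).

Monte-Carlo sampling (sample-average approximation) produces an
equal-probability fan; stagewise forward clustering reduces it to a tree.
Clusters are built by greedy forward selection of medoids under the
probability-weighted L1 distance (features standardized per stage), so every
tree path is an actually-sampled path and total probability is conserved
exactly. The leaf count can fall short of the product of branching factors
when an outlier cluster holds fewer members than its downstream branching
requires; probability conservation and bundle refinement always hold. The
published case does not state its tree's branching, so branching is a user
parameter; the worked example uses (5, 2, 2) — five price/allocation
branches, binary branching on the first two weeks of rain — on a 200-path
fan.

## Plan evaluation and the information metrics

Evaluating a frozen plan in a scenario never declares the scenario
infeasible. If the plan pumps more than the scenario's allocation, the
schedule is truncated — chronologically by default (early-season water is
kept, consistent with agronomic advice to secure early stress avoidance), or
proportionally on request — and the truncated volume is reported. The yield
mandate is dropped in evaluation and shortfalls reported. Given the (possibly
truncated) schedule, states are resolved by greedy forward simulation: each
week leach the overflow, then take as much ET as the week's demand allows.
Taking maximal ET each week is optimal for the frozen subproblem (saved
water can only leach or serve later ET, never more of it), and the test
suite verifies greedy = frozen-MILP profit to 1e-6 on random plans. Severe
stress with a response factor K > 1 would drive the printed yield expression
negative; evaluation floors the yield at zero and flags the event (the
optimizing models treat such level/option pairs as infeasible instead).

The report computes EV (deterministic optimum at the means), EEV (mean of
the frozen EV plan across scenarios), WS (mean of per-scenario perfect-
information optima — reported but not implementable), the two recourse
optima vfTS and vfMS, and the derived metrics EVPI = WS − vfTS,
VSS = vfTS − EEV, VMS = vfMS − vfTS, RVSS = VSS/EEV, RVMS = VMS/vfTS.
Scenario-value distributions are summarized min/Q1/median/mean/Q3/max with
inclusive quartiles (unweighted; the mean is probability-weighted).

## Stability diagnostics

In-sample: regenerate the fan and tree with seeds base+r, re-solve the
recourse model, report the spread of optima (and the EEV per tree). Weak
out-of-sample (for multiperiod trees, whose interior nodes do not coincide
across trees): build two trees, solve both, re-solve each with the other's
first-stage option pinned, and report the cross pair. Fixing the other
tree's first-stage decision can never improve a tree's own optimum, and with
degenerate distributions the cross difference is zero — both are asserted in
tests. Thresholds are advisory: a relative difference above 10% sets a
warning flag, nothing fails.

## Solver

Models are built as solver-agnostic specs (variables, bounds, integrality,
ranged linear constraints, maximization objective, LP-format export for
debugging) and solved with HiGHS branch-and-cut via `scipy.optimize.milp`
at a default relative MIP gap of 1e-6. A self-contained best-first
branch-and-bound over the HiGHS LP relaxation serves as an independent
second backend for small cross-check models; the suite asserts agreement to
1e-5 relative on fixtures. Extraction rounds binaries at 0.5 and re-checks
consistency (one option, one deficit level per scenario); reported
trajectories reconstruct the solver objective through the profit function to
1e-6. Acceptance comparisons use objective values only — alternate optima
with different decision vectors are expected and harmless.

## Fixtures, problem sizes and limitations

The case-study-scale fixture uses the printed farm parameters (150 acres,
85% efficiency, 8 cm/m holding capacity over a 91 cm root zone, $12/acre-
inch water, 5–8 mm/day unstressed ET defaulting to the 6.5 mm/day midpoint,
yields spanning 160–210 bu/acre, the price/allocation/rain models above).
Cost items that are not printed anywhere — per-option seed and operating
costs, fixed per-event cost, overhead, pre-irrigation depth, per-option
response factors, yield mandate — are synthetic stand-ins: round numbers
whose farm-total magnitudes are consistent with the printed aggregate cost
table, overridable from a cost workbook through a declared cell mapping.
Dollar results on this fixture are therefore indicative, not a reproduction
of the published case; the ordering ladder, the identities among the
metrics, and the qualitative contrasts between the models (lumpy
deterministic schedules vs smoother, more conservative stochastic ones; the
deterministic planner's preference for the highest-yield option when average
conditions imply no stress) are the reproducible content. Which seed type
the *stochastic* models prefer depends on the stand-in response factors and
cost spreads, and is not asserted.

Toy property-test fixtures keep K ≤ 1 so yields stay nonnegative at every
deficit level and the ordering theorems hold without clamping; the brute-
force oracle (complete enumeration of option × grid-restricted schedules,
greedy evaluation) is the independent optimum on those instances.

Problem sizes were chosen for single-CPU practicality: the property suite
uses 2–3 periods, ≤5 levels and ≤12-scenario trees; the case-study pipeline
in the test suite uses an 80-path fan reduced to 20 leaves; the worked
example uses a 200-path fan reduced to 20 leaves (~1.5 min end-to-end).
Larger trees solve correctly but MIP time grows quickly with
scenarios × deficit levels (a 64-leaf two-stage model at 101 levels runs for
tens of minutes).

Known limitations: single crop, single season, no rotation; no spatial
heterogeneity; ET demand is deterministic; the three uncertainty sources are
independent by assumption; no risk measures (expectation only); scenario
reduction is a heuristic (greedy forward selection), not the exact
transport-optimal reduction.
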
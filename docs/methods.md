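# Methods

## Model

A long, narrow space is discretized into `n` unit cells, indexed 1..n from
the left. Transport of an AED between cells takes `τ` minutes per cell
(default 1), or, in the generalized mode, a per-cell minute cost summed over
each cell entered along the path. Acquisition time for a cell is the one-way
travel time from the unit's cell, halved for a summonable unit (it is
delivered on call, so the round trip collapses to a single leg), and then
rounded **up** once to the whole minute. The single final round-up — applied
after halving — keeps zone labels and the 1/t warm weights mutually
consistent; at every boundary distance appearing in the worked examples the
raw-time and rounded-time conventions agree.

Each cell is labelled by its best (minimum) acquisition time `t` over the
deployed units:

* hot if `t ≤ t_hot` (default 1 min, the window for maximal survival
  benefit),
* cold if `t > t_ems` (default 8 min, the average EMS response: past that,
  waiting for the ambulance dominates),
* warm otherwise, weighted `1/t`.

Taking the per-cell minimum implements the union rule for hot zones and the
intersection rule for cold zones. The rescue-benefit triple is

    A_H = Σ_hot p(i)·dA,   A_C = Σ_cold p(i)·dA,   A_W = Σ_warm p(i)·dA / t_i,

with `p` the per-cell OHCA probability mass (default uniform 1) and `dA`
the cell area (default 1). Triples are ordered lexicographically (max A_H,
min A_C, max A_W); ties in all three are genuine equalities.

A patrolling unit is modelled as a summonable unit whose position is
uniformly distributed over its patrol range: the deployment's triple is the
plain average of the static triples over every patrol position (joint
Cartesian product if several patrollers are evaluated; the search and rules
restrict themselves to one patroller covering the whole corridor). No
dwell-time weighting is applied — the patroller spends equal time
everywhere on its round.

## Exact arithmetic

All public results are `fractions.Fraction`s. This is not cosmetic: the
comparison is lexicographic with exact tie-breaks, and the optimal plateaus
(several cells tying to the same triple) are part of the model's output. A
float pipeline would split or merge plateaus at machine precision. An
optional absolute tolerance exists on `compare_benefit` for callers with
float densities; it is off by default.

The exhaustive search evaluates up to ~10⁵–10⁶ deployments, so it uses an
integer encoding internally: rounded times are capped at `⌊t_ems⌋ + 1`
(anything beyond is cold), and with `D` the lcm of the warm minutes
`1..⌊t_ems⌋` and of the denominators of `p(i)·dA`, every per-cell
contribution is an integer multiple of `1/D`. Zone sizes become int64 dot
products (numpy) and comparisons exact integer comparisons. The encoding is
validated two ways: a fallback pure-Fraction enumeration is used whenever
`D` would overflow int64 (e.g. enormous EMS thresholds), and the test suite
re-evaluates every reported optimum through the independent Fraction path
and asserts exact equality.

## Placement rules

* **No patroller (Rule NP).** The corridor of real length `L = n` is split
  into `n_F` segments of length `x` and `n_S` segments of length `2x`,
  `x = L/(n_F + 2 n_S)` — a summonable unit covers twice the reach of a
  fixed one. Fixed units take the short segments, summonable the long, each
  at the cell containing its segment's real midpoint. Canonically short
  segments come first; any order gives the same triple (tested, not
  assumed). A midpoint falling on a cell boundary resolves to the left
  cell; the mirrored choice is equally optimal and is reachable through the
  search's tie list.
* **With one whole-corridor patroller (Rule WP).** The patroller supplies
  averaged central coverage, so the one or two units with the smallest
  individual hot zones (fixed before summonable) are pushed flush against
  the ends: a unit with hot radius `r` (`r = ⌊t_hot/τ⌋` fixed,
  `⌊2 t_hot/τ⌋` summonable) sits `r` cells in, its hot zone exactly filling
  the corner. Remaining units are placed by Rule NP on the interior cells
  between the two edge hot zones. If the interior is empty the remaining
  units fall back to the central cells with a warning — that configuration
  is outside the rule's regime.

`verify_rules` is the arbiter of both rules: it constructs the rule
deployment, evaluates it exactly, runs the exhaustive search, and reports
equality row by row.

## Verification results and a known limitation

Sweeping all corridor lengths divisible by `n_F + 2 n_S` in [20, 40] for
the eight inventory pairs (n_F, n_S) ∈ {(1,0), (0,1), (2,0), (0,2), (1,1),
(2,1), (1,2), (2,2)}:

* Rule NP matches the exhaustive optimum exactly on **every** row.
* Rule WP matches A_H and A_C on every row, but on five rows —
  (2,1)+P at L=32; (1,2)+P at L=30, 35, 40; (2,2)+P at L=36 — the
  exhaustive optimum attains a very slightly larger warm-zone score A_W
  (differences of order 10⁻³ on values near 6) by off-centering the
  interior unit toward the fixed-AED side. Example at L=30, (1,2)+P: the
  rule yields `F@2,S@28,S@14,P` with A_W = 1039/180 while `F@2,S@28,S@12,P`
  attains 231/40. Every step of the rule (edge radii, interior midpoints,
  patrol averaging) is forced up to the midpoint tie direction, and the gap
  exceeds any tie, so this is a genuine property of the rule at those
  lengths, not a discretization choice. The verification harness reports
  these rows as unequal rather than hiding them; the corresponding sweep
  test fails on exactly those five rows by design.

The worked 22-cell examples carry one further caveat: for the two-unit
configuration {F@7, F@19} the minimum-time evaluation gives
A_W = 4214/840, and the qualitative claim (it beats {F@9, F@19}, whose
A_W = 4131/840) holds and is tested; a published warm-zone tally for that
single configuration appears to have counted the left warm zone without
edge truncation and is not used as a reference value.

## Synthetic scenarios

`scenario_gen` produces corridors for property sweeps. Density shapes:
`uniform` (the baseline assumption — no location in a public corridor is a
priori OHCA-enriched), `step` (left half weight 2, right half 1 — a crowded
car adjoining an empty one), `triangular` (linear peak at the center), and
`random-rational` (i.i.d. tenths in {1/10..1}). Transport shapes: `uniform`
(τ = 1) or `random-rational` per-cell minutes. Draws are exact small
rationals, never floats, so generated scenarios exercise the same exact
comparison semantics as the defaults; a fixed seed reproduces a scenario
bit for bit. The generator emulates density and speed heterogeneity only —
it does not model obstruction dynamics, time-varying crowding, or
2-D geometry, so passing property sweeps support the model's internal
consistency, not its fidelity to any particular real corridor.

## Problem sizes

The defaults keep every computation interactive: worked examples are
22-cell corridors; the center-rule check runs lengths 17–40; the
verification sweep covers all divisible lengths in [20, 40] for up to five
units with at most one patroller (about 140 rule-vs-search rows, the
largest single search enumerating ~4.4·10⁵ static placements × 36 patrol
positions); randomized property sweeps use 200 scenarios of 4–24 cells per
invariant. These sizes match the scale at which the placement rules were
originally machine-verified while keeping the full suite in the
minutes range.

## Limitations

* One-dimensional geometry only; the benefit formulas generalize to
  grids, but no 2-D/3-D search is provided.
* Transport times are deterministic; no stochastic delays, device failure,
  or bystander-behaviour modelling.
* The 1/t warm weighting is the only survival model; no calibrated
  survival curves.
* Patrolling is position-averaged; no schedules or dwell times.
* The closed-form rules claim optimality only under uniform density and
  uniform speed, and Rule WP additionally misses the final A_W tie-break
  at the lengths listed above.
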
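"""Closed-form optimal placement rules and their verification harness.

Two families of rules give optimal deployments on a uniform corridor
without running the exhaustive search:

* **Rule NP** (no patroller): split the corridor into ``n_F`` short segments
  and ``n_S`` long segments with a 1-to-2 length ratio (a summonable unit
  covers twice the reach of a fixed one), then put each fixed unit at the
  center of a short segment and each summonable unit at the center of a
  long segment.
* **Rule WP** (with a whole-corridor patroller): the patroller already
  supplies center coverage on average, so the one or two non-patrolling
  units with the smallest individual hot zones go flush against the ends —
  each hot zone fully inside the corridor with its edge on the corridor
  edge — and any remaining units are placed by Rule NP on the interior
  between the two edge hot zones.

``verify_rules`` replays the numerical verification: for each corridor
length and inventory it builds the rule deployment, evaluates its benefit,
runs the exhaustive search, and reports whether the two benefits are
exactly equal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .benefit import (
    BenefitTriple,
    Ordering,
    compare_benefit,
    deployment_benefit,
)
from .corridor import (
    AEDKind,
    AEDPlacement,
    Corridor,
    Deployment,
    Inventory,
)
from .search import SearchTooLarge, exhaustive_optimal

__all__ = [
    "VerificationReport",
    "VerificationRow",
    "rule_np",
    "rule_wp",
    "verify_rules",
]


def _midpoint_cell(p: Fraction, n_cells: int) -> int:
    """Cell containing real position ``p``; boundary positions go left."""
    if p <= 0:
        return 1
    cell = int(p) if p.denominator == 1 else math.ceil(p)
    return min(cell, n_cells)


def _check_uniform(corridor: Corridor, rule: str) -> None:
    uniform_density = len(set(corridor.density)) == 1
    if not (corridor.uniform_tau and uniform_density):
        warnings.warn(
            f"{rule} is only claimed optimal for uniform density and uniform "
            "transport time; the construction proceeds but may be suboptimal",
            RuntimeWarning,
            stacklevel=3,
        )


def rule_np(
    corridor: Corridor,
    n_fixed: int,
    n_summonable: int,
    order: Sequence[AEDKind] | None = None,
) -> Deployment:
    """Rule NP deployment for ``n_fixed`` + ``n_summonable`` units.

    Segments of length ``x`` (fixed) and ``2x`` (summonable), with
    ``x = L / (n_fixed + 2 * n_summonable)``, are laid left to right —
    canonically all short segments first; ``order`` overrides the segment
    sequence (any permutation gives the same benefit on a uniform
    corridor). Each unit sits in the cell containing its segment's real
    midpoint, boundary midpoints resolving to the left cell.
    """
    if n_fixed < 0 or n_summonable < 0 or n_fixed + n_summonable < 1:
        raise ValueError("rule NP needs at least one non-patrolling unit")
    _check_uniform(corridor, "rule NP")
    if order is None:
        order = [AEDKind.FIXED] * n_fixed + [AEDKind.SUMMONABLE] * n_summonable
    else:
        order = list(order)
        if sorted(k.value for k in order) != sorted(
            [AEDKind.FIXED.value] * n_fixed
            + [AEDKind.SUMMONABLE.value] * n_summonable
        ):
            raise ValueError("order must contain exactly the inventory's units")
    cells = _rule_np_cells(corridor.n_cells, order, offset=0)
    return Deployment(
        tuple(AEDPlacement(kind, cell=cell) for kind, cell in cells)
    )


def _rule_np_cells(
    length: int, order: Sequence[AEDKind], offset: int
) -> list[tuple[AEDKind, int]]:
    n_fixed = sum(1 for k in order if k is AEDKind.FIXED)
    n_summonable = len(order) - n_fixed
    x = Fraction(length, n_fixed + 2 * n_summonable)
    placements = []
    left = Fraction(0)
    for kind in order:
        seg = x if kind is AEDKind.FIXED else 2 * x
        mid = left + seg / 2
        local = _midpoint_cell(mid, length)
        placements.append((kind, offset + local))
        left += seg
    return placements


def _hot_radius(kind: AEDKind, corridor: Corridor) -> int:
    """Cells on each side of a unit whose rounded time stays within t_hot."""
    tau = corridor.minutes_per_cell
    if kind is AEDKind.FIXED:
        return math.floor(corridor.t_hot / tau)
    return math.floor(2 * corridor.t_hot / tau)


def rule_wp(
    corridor: Corridor,
    n_fixed: int,
    n_summonable: int,
    n_patrol: int = 1,
) -> Deployment:
    """Rule WP deployment: edge units flanking a whole-corridor patroller.

    The units with the smallest hot zones (fixed before summonable) are
    pushed to the two ends, each at distance ``r`` from its end so the hot
    zone of radius ``r`` exactly fills the corner; remaining units follow
    Rule NP on the interior cells between the two edge hot zones. With a
    single non-patrolling unit only the left end is used.
    """
    if n_patrol != 1:
        raise ValueError("rule WP is defined for exactly one patrolling unit")
    if n_fixed + n_summonable < 1:
        raise ValueError("rule WP needs at least one non-patrolling unit")
    if not corridor.uniform_tau:
        raise ValueError(
            "rule WP's edge-placement radii require a uniform transport time"
        )
    _check_uniform(corridor, "rule WP")

    n = corridor.n_cells
    # fixed units have the smaller hot radius, so they are chosen first
    pool = [AEDKind.FIXED] * n_fixed + [AEDKind.SUMMONABLE] * n_summonable
    edge_kinds = pool[: min(2, len(pool))]
    remaining = pool[len(edge_kinds):]

    units: list[AEDPlacement] = []
    left_kind = edge_kinds[0]
    r_left = _hot_radius(left_kind, corridor)
    units.append(AEDPlacement(left_kind, cell=min(r_left + 1, n)))
    if len(edge_kinds) == 2:
        right_kind = edge_kinds[1]
        r_right = _hot_radius(right_kind, corridor)
        units.append(AEDPlacement(right_kind, cell=max(n - r_right, 1)))
    else:
        r_right = -1  # no right edge unit; no excluded zone on the right

    if remaining:
        lo = 2 * r_left + 2
        hi = n - (2 * r_right + 1)
        n_rem_f = sum(1 for k in remaining if k is AEDKind.FIXED)
        n_rem_s = len(remaining) - n_rem_f
        if lo > hi:
            warnings.warn(
                "corridor too short to host the interior units outside the "
                "edge hot zones; placing them at the central cells instead "
                "(outside the rule's stated regime)",
                RuntimeWarning,
                stacklevel=2,
            )
            center = (n + 1) // 2
            for kind in remaining:
                units.append(AEDPlacement(kind, cell=center))
        else:
            order = [AEDKind.FIXED] * n_rem_f + [AEDKind.SUMMONABLE] * n_rem_s
            for kind, cell in _rule_np_cells(hi - lo + 1, order, offset=lo - 1):
                units.append(AEDPlacement(kind, cell=cell))

    units.append(AEDPlacement(AEDKind.PATROL))
    return Deployment(tuple(units))


@dataclass(frozen=True)
class VerificationRow:
    """One rule-vs-search comparison."""

    n_cells: int
    inventory: Inventory
    rule_deployment: Deployment | None
    rule_benefit: BenefitTriple | None
    optimal_benefit: BenefitTriple | None
    equal: bool | None
    note: str = ""


@dataclass(frozen=True)
class VerificationReport:
    rows: tuple

    @property
    def all_equal(self) -> bool:
        return all(row.equal for row in self.rows)

    def failures(self) -> tuple:
        return tuple(row for row in self.rows if not row.equal)

    def __str__(self) -> str:
        n_eq = sum(1 for r in self.rows if r.equal)
        return f"{n_eq}/{len(self.rows)} rule deployments match the exhaustive optimum"


def _coerce_inventory(inv) -> Inventory:
    if isinstance(inv, Inventory):
        return inv
    n_f, n_s, n_p = inv
    return Inventory(n_fixed=n_f, n_summonable=n_s, n_patrol=n_p)


def rule_deployment(corridor: Corridor, inventory: Inventory) -> Deployment:
    """Dispatch to the applicable rule for the inventory."""
    if inventory.n_patrol == 0:
        return rule_np(corridor, inventory.n_fixed, inventory.n_summonable)
    if inventory.n_fixed + inventory.n_summonable == 0:
        return Deployment((AEDPlacement(AEDKind.PATROL),) * inventory.n_patrol)
    return rule_wp(
        corridor, inventory.n_fixed, inventory.n_summonable, inventory.n_patrol
    )


def verify_rules(
    corridor_lengths: Iterable[int],
    inventories: Iterable,
    make_corridor_fn=None,
) -> VerificationReport:
    """Compare rule deployments with the exhaustive optimum.

    ``make_corridor_fn(length)`` builds the corridor for each length
    (defaults to the uniform corridor with the standard thresholds).
    Search refusals become annotated rows with ``equal=None``.
    """
    from .corridor import make_corridor

    if make_corridor_fn is None:
        make_corridor_fn = make_corridor
    rows = []
    for length in corridor_lengths:
        corridor = make_corridor_fn(length)
        for raw_inv in inventories:
            inventory = _coerce_inventory(raw_inv)
            try:
                deployment = rule_deployment(corridor, inventory)
            except ValueError as exc:
                rows.append(
                    VerificationRow(length, inventory, None, None, None, None, str(exc))
                )
                continue
            rule_triple = deployment_benefit(deployment, corridor)
            try:
                optimal = exhaustive_optimal(corridor, inventory)
            except SearchTooLarge as exc:
                rows.append(
                    VerificationRow(
                        length, inventory, deployment, rule_triple, None, None, str(exc)
                    )
                )
                continue
            equal = compare_benefit(rule_triple, optimal.best) is Ordering.EQUAL
            note = "" if equal else "rule deployment is not optimal"
            rows.append(
                VerificationRow(
                    length,
                    inventory,
                    deployment,
                    rule_triple,
                    optimal.best,
                    equal,
                    note,
                )
            )
    return VerificationReport(rows=tuple(rows))
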
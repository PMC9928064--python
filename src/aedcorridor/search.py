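"""Exhaustive search for optimal AED deployments.

Given an inventory (so many fixed units, so many summonable units, at most
one patrolling unit covering the whole corridor), every placement of the
units on the corridor's cells is enumerated and ranked with the
lexicographic benefit comparison. Units of the same kind are interchangeable,
so placements are multisets (combinations with repetition) — the main
combinatorial saver. All ties for the optimum are collected.

Internally the enumeration uses a scaled-integer evaluator: with rounded
acquisition times capped just above the EMS threshold, every per-cell weight
``density * dA`` and warm weight ``density * dA / t`` is an integer multiple
of ``1/D`` for a common denominator ``D`` (the lcm of the warm minutes and
of the density denominators). Zone sizes are then exact int64 sums, and the
lexicographic comparison is exact integer comparison. The same quantities
recomputed through :func:`aedcorridor.benefit.deployment_benefit` (pure
Fraction arithmetic, cell by cell) agree exactly; that slower path is the
fallback whenever the integer encoding would overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations_with_replacement
from typing import Iterator

import numpy as np

from .benefit import BenefitTriple, Ordering, compare_benefit, deployment_benefit
from .corridor import (
    AEDKind,
    AEDPlacement,
    Corridor,
    Deployment,
    Inventory,
    acquisition_time,
)

__all__ = ["OptimalResult", "enumerate_deployments", "exhaustive_optimal"]

#: Search scope matching the numerical-verification setting: at most five
#: units in total and at most one patrolling unit.
DEFAULT_MAX_UNITS = 5
DEFAULT_ARGMAX_CAP = 10_000

_INT64_SAFE = 2**60


@dataclass(frozen=True)
class OptimalResult:
    """Outcome of an exhaustive search."""

    best: BenefitTriple
    argmax: tuple
    n_evaluated: int
    argmax_overflow: bool = False

    def __str__(self) -> str:
        deps = "; ".join(str(d) for d in self.argmax)
        return f"best {self.best} attained by {len(self.argmax)} deployment(s): {deps}"


class SearchTooLarge(ValueError):
    """Raised when an enumeration would exceed the configured caps."""


def _enumeration_size(n_cells: int, inventory: Inventory) -> int:
    return math.comb(n_cells + inventory.n_fixed - 1, inventory.n_fixed) * math.comb(
        n_cells + inventory.n_summonable - 1, inventory.n_summonable
    )


def _check_inventory(corridor: Corridor, inventory: Inventory, max_units: int) -> None:
    if inventory.n_patrol > 1:
        raise SearchTooLarge(
            "search supports at most one patrolling unit "
            f"(got {inventory.n_patrol})"
        )
    if inventory.total > max_units:
        raise SearchTooLarge(
            f"inventory of {inventory.total} units exceeds the cap of "
            f"{max_units} (estimated enumeration size "
            f"{_enumeration_size(corridor.n_cells, inventory)})"
        )


def enumerate_deployments(
    corridor: Corridor,
    inventory: Inventory,
    max_units: int = DEFAULT_MAX_UNITS,
) -> Iterator[Deployment]:
    """Yield every distinct placement of the inventory on the corridor.

    Fixed cells and summonable cells each range over multisets of cells;
    the patrolling unit, if present, always patrols the whole corridor.
    """
    _check_inventory(corridor, inventory, max_units)
    cells = range(1, corridor.n_cells + 1)
    patrol_units = (AEDPlacement(AEDKind.PATROL),) * inventory.n_patrol
    for f_cells in combinations_with_replacement(cells, inventory.n_fixed):
        f_units = tuple(AEDPlacement(AEDKind.FIXED, cell=c) for c in f_cells)
        for s_cells in combinations_with_replacement(cells, inventory.n_summonable):
            s_units = tuple(AEDPlacement(AEDKind.SUMMONABLE, cell=c) for c in s_cells)
            yield Deployment(f_units + s_units + patrol_units)


class _ScaleOverflow(Exception):
    pass


class _ScaledEvaluator:
    """Exact integer-arithmetic benefit evaluation over a common denominator."""

    def __init__(self, corridor: Corridor):
        self.corridor = corridor
        n = corridor.n_cells
        self.h_int = math.floor(corridor.t_hot)
        self.e_int = math.floor(corridor.t_ems)
        self.cap = self.e_int + 1  # any time >= cap is cold

        if self.e_int > 64:
            # lcm(1..e) explodes; not worth the integer encoding
            raise _ScaleOverflow
        d0 = math.lcm(*range(1, max(self.e_int, 1) + 1))
        masses = [d * corridor.cell_area for d in corridor.density]
        m = math.lcm(*(mass.denominator for mass in masses))
        self.denom = d0 * m
        if self.denom > _INT64_SAFE // max(n, 1):
            raise _ScaleOverflow
        scaled = [mass * self.denom for mass in masses]
        assert all(s.denominator == 1 for s in scaled)
        self.dens_scaled = np.array([int(s) for s in scaled], dtype=np.int64)
        if int(self.dens_scaled.sum()) * n >= _INT64_SAFE:
            raise _ScaleOverflow

        self.times_fixed = self._time_table(AEDKind.FIXED)
        self.times_summonable = self._time_table(AEDKind.SUMMONABLE)
        self.empty_times = np.full(n, self.cap, dtype=np.int64)

    def _time_table(self, kind: AEDKind) -> np.ndarray:
        n = self.corridor.n_cells
        table = np.empty((n, n), dtype=np.int64)
        for pos in range(1, n + 1):
            unit = AEDPlacement(kind, cell=pos)
            for cell in range(1, n + 1):
                t = acquisition_time(unit, cell, self.corridor)
                table[pos - 1, cell - 1] = min(t, self.cap)
        return table

    def eval_times(self, times: np.ndarray) -> tuple[int, int, int]:
        """Integer (A_H, A_C, A_W) * denom, summed over all leading axes."""
        dens = self.dens_scaled
        hot = times <= self.h_int
        cold = times >= self.cap
        warm = ~hot & ~cold
        a_h = int((dens * hot).sum())
        a_c = int((dens * cold).sum())
        safe_t = np.where(warm, times, 1)
        a_w = int(((dens // safe_t) * warm).sum())
        return a_h, a_c, a_w


def _mirror_key(f_cells, s_cells, n):
    mf = tuple(sorted(n + 1 - c for c in f_cells))
    ms = tuple(sorted(n + 1 - c for c in s_cells))
    return (mf, ms)


def _build_deployment(f_cells, s_cells, n_patrol) -> Deployment:
    units = tuple(AEDPlacement(AEDKind.FIXED, cell=c) for c in f_cells)
    units += tuple(AEDPlacement(AEDKind.SUMMONABLE, cell=c) for c in s_cells)
    units += (AEDPlacement(AEDKind.PATROL),) * n_patrol
    return Deployment(units)


def exhaustive_optimal(
    corridor: Corridor,
    inventory: Inventory,
    max_units: int = DEFAULT_MAX_UNITS,
    argmax_cap: int = DEFAULT_ARGMAX_CAP,
    dedup_mirror: bool = False,
) -> OptimalResult:
    """Best benefit over all placements of ``inventory``, with all ties.

    ``dedup_mirror`` drops, from the reported ties only, any deployment
    whose mirror image about the corridor midpoint is also reported and
    lexicographically smaller; it never affects the best triple.
    """
    _check_inventory(corridor, inventory, max_units)
    try:
        evaluator = _ScaledEvaluator(corridor)
    except _ScaleOverflow:
        return _exhaustive_optimal_slow(
            corridor, inventory, max_units, argmax_cap, dedup_mirror
        )
    n = corridor.n_cells
    cells = range(1, n + 1)
    has_patrol = inventory.n_patrol == 1
    summon_table = evaluator.times_summonable

    best_key = None
    argmax: list[tuple[tuple, tuple]] = []
    overflow = False
    n_evaluated = 0

    for f_cells in combinations_with_replacement(cells, inventory.n_fixed):
        if f_cells:
            t_fixed = np.min(
                evaluator.times_fixed[[c - 1 for c in f_cells]], axis=0
            )
        else:
            t_fixed = evaluator.empty_times
        for s_cells in combinations_with_replacement(cells, inventory.n_summonable):
            if s_cells:
                t_static = np.minimum(
                    t_fixed,
                    np.min(summon_table[[c - 1 for c in s_cells]], axis=0),
                )
            else:
                t_static = t_fixed
            if has_patrol:
                combined = np.minimum(t_static[np.newaxis, :], summon_table)
                a_h, a_c, a_w = evaluator.eval_times(combined)
            else:
                a_h, a_c, a_w = evaluator.eval_times(t_static)
            n_evaluated += 1
            key = (a_h, -a_c, a_w)
            if best_key is None or key > best_key:
                best_key = key
                argmax = [(f_cells, s_cells)]
                overflow = False
            elif key == best_key:
                if len(argmax) < argmax_cap:
                    argmax.append((f_cells, s_cells))
                else:
                    overflow = True

    a_h, neg_a_c, a_w = best_key
    denom = evaluator.denom * (n if has_patrol else 1)
    best = BenefitTriple(
        hot=Fraction(a_h, denom),
        cold=Fraction(-neg_a_c, denom),
        warm=Fraction(a_w, denom),
    )
    if dedup_mirror:
        kept = set(argmax)
        argmax = [
            rep
            for rep in argmax
            if _mirror_key(*rep, n) not in kept or rep <= _mirror_key(*rep, n)
        ]
    deployments = tuple(
        _build_deployment(f, s, inventory.n_patrol) for f, s in argmax
    )
    return OptimalResult(
        best=best,
        argmax=deployments,
        n_evaluated=n_evaluated,
        argmax_overflow=overflow,
    )


def _exhaustive_optimal_slow(
    corridor: Corridor,
    inventory: Inventory,
    max_units: int,
    argmax_cap: int,
    dedup_mirror: bool,
) -> OptimalResult:
    """Fraction-arithmetic enumeration; used when integer scaling overflows."""
    best = None
    argmax: list[Deployment] = []
    overflow = False
    n_evaluated = 0
    for deployment in enumerate_deployments(corridor, inventory, max_units):
        triple = deployment_benefit(deployment, corridor)
        n_evaluated += 1
        if best is None or compare_benefit(triple, best) is Ordering.A_BETTER:
            best = triple
            argmax = [deployment]
            overflow = False
        elif compare_benefit(triple, best) is Ordering.EQUAL:
            if len(argmax) < argmax_cap:
                argmax.append(deployment)
            else:
                overflow = True
    n = corridor.n_cells
    if dedup_mirror:
        reps = []
        for dep in argmax:
            f = tuple(sorted(u.cell for u in dep.units if u.kind is AEDKind.FIXED))
            s = tuple(
                sorted(u.cell for u in dep.units if u.kind is AEDKind.SUMMONABLE)
            )
            reps.append((f, s))
        kept = set(reps)
        argmax = [
            dep
            for dep, rep in zip(argmax, reps)
            if _mirror_key(*rep, n) not in kept or rep <= _mirror_key(*rep, n)
        ]
    return OptimalResult(
        best=best,
        argmax=tuple(argmax),
        n_evaluated=n_evaluated,
        argmax_overflow=overflow,
    )
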
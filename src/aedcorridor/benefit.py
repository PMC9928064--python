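"""Rescue-benefit evaluation: zone combination, weighting, and comparison.

The rescue benefit of a set of AEDs is the triple ``(A_H, A_C, A_W)``:

* ``A_H`` — weighted size of the combined hot zone, the union of the units'
  hot zones (any one unit arriving in time is enough);
* ``A_C`` — weighted size of the combined cold zone, the intersection of the
  units' cold zones (every unit must be too far);
* ``A_W`` — weighted size of the combined warm zone, where each cell counts
  ``1/t`` for ``t`` the best (smallest, rounded-up) acquisition time in
  minutes — the benefit of a late defibrillator decays roughly inversely
  with time.

Weights are the per-cell OHCA density times the cell area, so under the
uniform defaults the hot and cold sizes are plain cell counts.

Deployments are ranked lexicographically: larger ``A_H`` first, then smaller
``A_C``, then larger ``A_W``; exact ties in all three make the benefits
equal. A patrolling unit is evaluated as a summonable unit averaged uniformly
over every cell of its patrol range.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass
from fractions import Fraction

from .corridor import (
    AEDKind,
    AEDPlacement,
    Corridor,
    Deployment,
    ZoneLabel,
    acquisition_time,
    classify_time,
)

__all__ = [
    "BenefitTriple",
    "Ordering",
    "ZoneProfile",
    "compare_benefit",
    "deployment_benefit",
    "zone_profile",
    "weighted_sizes",
]

#: Soft cap on the number of joint patrol assignments before warning.
DEFAULT_PATROL_BUDGET = 200_000


@dataclass(frozen=True)
class ZoneProfile:
    """Per-cell minimum acquisition times and zone labels.

    ``times[i]`` is the smallest rounded acquisition minute over the static
    units, or ``None`` when no unit exists (the cell is then cold).
    """

    times: tuple
    labels: tuple

    @property
    def n_cells(self) -> int:
        return len(self.times)

    def count(self, label: ZoneLabel) -> int:
        return sum(1 for lab in self.labels if lab is label)


@dataclass(frozen=True, order=False)
class BenefitTriple:
    """Weighted sizes (A_H, A_C, A_W) of the hot, cold, and warm zones."""

    hot: Fraction
    cold: Fraction
    warm: Fraction

    def as_tuple(self) -> tuple[Fraction, Fraction, Fraction]:
        return (self.hot, self.cold, self.warm)

    def __str__(self) -> str:
        return f"(A_H={self.hot}, A_C={self.cold}, A_W={self.warm})"


class Ordering(enum.Enum):
    A_BETTER = "a_better"
    B_BETTER = "b_better"
    EQUAL = "equal"


def zone_profile(deployment: Deployment, corridor: Corridor) -> ZoneProfile:
    """Combined zone profile of a deployment of fixed/summonable units.

    Each cell takes the minimum rounded acquisition time over all units
    (union of hot zones, intersection of cold zones follows from the
    minimum). An empty deployment leaves every cell cold.
    """
    if any(u.kind is AEDKind.PATROL for u in deployment.units):
        raise ValueError(
            "zone_profile is defined for static deployments; expand "
            "patrolling units through deployment_benefit"
        )
    deployment.validate(corridor)
    times = []
    labels = []
    for cell in range(1, corridor.n_cells + 1):
        if deployment.units:
            t = min(acquisition_time(u, cell, corridor) for u in deployment.units)
            times.append(t)
            labels.append(classify_time(t, corridor))
        else:
            times.append(None)
            labels.append(ZoneLabel.COLD)
    return ZoneProfile(times=tuple(times), labels=tuple(labels))


def weighted_sizes(profile: ZoneProfile, corridor: Corridor) -> BenefitTriple:
    """Weighted zone sizes of a profile under the corridor's density."""
    if profile.n_cells != corridor.n_cells:
        raise ValueError("profile length does not match corridor")
    hot = Fraction(0)
    cold = Fraction(0)
    warm = Fraction(0)
    dA = corridor.cell_area
    for t, label, dens in zip(profile.times, profile.labels, corridor.density):
        mass = dens * dA
        if label is ZoneLabel.HOT:
            hot += mass
        elif label is ZoneLabel.COLD:
            cold += mass
        else:
            warm += mass / t
    return BenefitTriple(hot=hot, cold=cold, warm=warm)


def _patrol_assignments(deployment: Deployment, corridor: Corridor):
    """Iterate joint patrol-position assignments as tuples of cells."""
    ranges = []
    for unit in deployment.patrol_units:
        lo, hi = unit.resolved_range(corridor)
        ranges.append(range(lo, hi + 1))
    return itertools.product(*ranges)


def deployment_benefit(
    deployment: Deployment,
    corridor: Corridor,
    patrol_budget: int = DEFAULT_PATROL_BUDGET,
) -> BenefitTriple:
    """Benefit triple of a deployment, averaging patrolling units.

    Every joint assignment of the patrolling units to cells of their patrol
    ranges is weighted equally: the patroller spends the same fraction of
    its round in each cell and responds as a summonable unit from wherever
    it happens to be. Without patrolling units this reduces to
    ``weighted_sizes(zone_profile(...))``.
    """
    deployment.validate(corridor)
    patrols = deployment.patrol_units
    if not patrols:
        return weighted_sizes(zone_profile(deployment, corridor), corridor)

    n_assignments = 1
    for unit in patrols:
        lo, hi = unit.resolved_range(corridor)
        n_assignments *= hi - lo + 1
    if n_assignments > patrol_budget:
        warnings.warn(
            f"averaging over {n_assignments} joint patrol assignments "
            f"exceeds the budget of {patrol_budget}; this may be slow",
            RuntimeWarning,
            stacklevel=2,
        )

    static = deployment.static_units
    tot_hot = Fraction(0)
    tot_cold = Fraction(0)
    tot_warm = Fraction(0)
    count = 0
    for cells in _patrol_assignments(deployment, corridor):
        units = static + tuple(
            AEDPlacement(AEDKind.SUMMONABLE, cell=c) for c in cells
        )
        triple = weighted_sizes(zone_profile(Deployment(units), corridor), corridor)
        tot_hot += triple.hot
        tot_cold += triple.cold
        tot_warm += triple.warm
        count += 1
    return BenefitTriple(
        hot=tot_hot / count, cold=tot_cold / count, warm=tot_warm / count
    )


def compare_benefit(
    a: BenefitTriple,
    b: BenefitTriple,
    tolerance: Fraction | float | None = None,
) -> Ordering:
    """Lexicographic comparison of two benefit triples.

    Larger hot size wins; hot ties are broken by smaller cold size, then by
    larger warm size; full ties are equal. Comparison is exact by default.
    ``tolerance`` (absolute, per component) is intended only for triples
    derived from float densities and must be enabled explicitly.
    """

    def cmp(x, y):
        if tolerance is not None and abs(x - y) <= tolerance:
            return 0
        return (x > y) - (x < y)

    c = cmp(a.hot, b.hot)
    if c == 0:
        c = -cmp(a.cold, b.cold)
    if c == 0:
        c = cmp(a.warm, b.warm)
    if c > 0:
        return Ordering.A_BETTER
    if c < 0:
        return Ordering.B_BETTER
    return Ordering.EQUAL
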
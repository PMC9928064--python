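"""Domain types for the one-dimensional corridor model.

A long, narrow public space (a train, a platform, a tunnel) is discretized
into ``n_cells`` unit cells. An automated external defibrillator (AED) placed
somewhere in the corridor covers each cell with one of three service levels,
determined by the time needed to bring the device to a collapse in that cell:

* **hot** — the AED arrives within the hot threshold (default 1 minute),
  the window in which defibrillation gives the best survival chance;
* **warm** — the AED arrives after the hot threshold but no later than the
  average emergency-medical-services (EMS) response time (default 8 minutes);
* **cold** — waiting for EMS is faster than fetching the AED, so the device
  contributes nothing there.

Three device types differ only in acquisition time: a *fixed* AED must be
fetched (one-way travel at the corridor's uniform speed), a *summonable* AED
is delivered on call in half that time, and a *patrolling* AED is carried
along a range of cells and is modelled as a summonable unit averaged over its
patrol range (the averaging lives in :mod:`aedcorridor.benefit`).

All quantities are exact rationals (:class:`fractions.Fraction`) so that zone
sizes and benefit comparisons are free of floating-point ties.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence, Union

RationalLike = Union[int, str, Fraction]

__all__ = [
    "AEDKind",
    "AEDPlacement",
    "Corridor",
    "Deployment",
    "Inventory",
    "ZoneLabel",
    "acquisition_time",
    "classify_time",
    "make_corridor",
]


def _as_fraction(value: RationalLike, name: str) -> Fraction:
    try:
        frac = Fraction(value)
    except (ValueError, ZeroDivisionError, TypeError) as exc:
        raise ValueError(f"{name} is not a valid rational: {value!r}") from exc
    return frac


class ZoneLabel(enum.Enum):
    """Service level of one cell under a deployment."""

    HOT = "hot"
    WARM = "warm"
    COLD = "cold"


class AEDKind(enum.Enum):
    """Accessibility class of an AED unit."""

    FIXED = "F"
    SUMMONABLE = "S"
    PATROL = "P"


@dataclass(frozen=True)
class Corridor:
    """A validated 1-D corridor.

    Attributes
    ----------
    n_cells:
        Number of unit cells (1-based indexing everywhere).
    minutes_per_cell:
        Transport time tau through one cell. Either a single Fraction
        (uniform-speed mode) or a tuple of per-cell Fractions (generalized
        mode, e.g. an obstructed section of a platform).
    t_hot, t_ems:
        Hot-zone and EMS-arrival thresholds, in minutes.
    density:
        Per-cell probability mass of an out-of-hospital cardiac arrest
        occurring there. Uniform 1 reproduces the unweighted-area model.
    cell_area:
        Physical size dA of one cell; a plain scale factor on all zone sizes.
    """

    n_cells: int
    minutes_per_cell: Union[Fraction, tuple]
    t_hot: Fraction
    t_ems: Fraction
    density: tuple
    cell_area: Fraction

    @property
    def uniform_tau(self) -> bool:
        return isinstance(self.minutes_per_cell, Fraction)

    def tau_at(self, cell: int) -> Fraction:
        if self.uniform_tau:
            return self.minutes_per_cell
        return self.minutes_per_cell[cell - 1]

    def travel_minutes(self, a: int, b: int) -> Fraction:
        """Raw transport time from cell ``a`` to cell ``b``.

        Uniform mode: ``tau * |a - b|``. Generalized mode: the sum of
        ``minutes_per_cell`` over each successive cell entered along the
        path (``|a - b|`` terms, excluding the starting cell).
        """
        if a == b:
            return Fraction(0)
        if self.uniform_tau:
            return self.minutes_per_cell * abs(a - b)
        if a < b:
            cells = range(a + 1, b + 1)
        else:
            cells = range(b, a)
        return sum((self.minutes_per_cell[c - 1] for c in cells), Fraction(0))

    @property
    def total_mass(self) -> Fraction:
        """Total density mass times dA (the conserved weighted area)."""
        return sum(self.density, Fraction(0)) * self.cell_area


@dataclass(frozen=True)
class AEDPlacement:
    """One AED unit: kind plus a cell (F/S) or a patrol range (P)."""

    kind: AEDKind
    cell: int | None = None
    patrol_range: tuple[int, int] | None = None

    def validate(self, corridor: Corridor) -> None:
        n = corridor.n_cells
        if self.kind is AEDKind.PATROL:
            if self.cell is not None:
                raise ValueError("a patrolling unit has a range, not a cell")
            lo, hi = self.patrol_range if self.patrol_range else (1, n)
            if not (1 <= lo <= hi <= n):
                raise ValueError(f"patrol range {self.patrol_range} outside [1, {n}]")
        else:
            if self.cell is None:
                raise ValueError(f"{self.kind.name} unit requires a cell")
            if not (1 <= self.cell <= n):
                raise ValueError(f"cell {self.cell} outside [1, {n}]")

    def resolved_range(self, corridor: Corridor) -> tuple[int, int]:
        if self.kind is not AEDKind.PATROL:
            raise ValueError("only patrolling units have a patrol range")
        return self.patrol_range if self.patrol_range else (1, corridor.n_cells)

    def __str__(self) -> str:
        if self.kind is AEDKind.PATROL:
            if self.patrol_range is None:
                return "P"
            return f"P@{self.patrol_range[0]}-{self.patrol_range[1]}"
        return f"{self.kind.value}@{self.cell}"


def fixed_at(cell: int) -> AEDPlacement:
    return AEDPlacement(AEDKind.FIXED, cell=cell)


def summonable_at(cell: int) -> AEDPlacement:
    return AEDPlacement(AEDKind.SUMMONABLE, cell=cell)


def patrol(start: int | None = None, end: int | None = None) -> AEDPlacement:
    if (start is None) != (end is None):
        raise ValueError("patrol range needs both endpoints or neither")
    rng = None if start is None else (start, end)
    return AEDPlacement(AEDKind.PATROL, patrol_range=rng)


@dataclass(frozen=True)
class Deployment:
    """An ordered collection of AED units; may be empty, cells may repeat."""

    units: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "units", tuple(self.units))

    def validate(self, corridor: Corridor) -> None:
        for unit in self.units:
            unit.validate(corridor)

    @property
    def static_units(self) -> tuple:
        return tuple(u for u in self.units if u.kind is not AEDKind.PATROL)

    @property
    def patrol_units(self) -> tuple:
        return tuple(u for u in self.units if u.kind is AEDKind.PATROL)

    def __str__(self) -> str:
        return ",".join(str(u) for u in self.units) if self.units else "(empty)"

    def __len__(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class Inventory:
    """Counts of available units by kind."""

    n_fixed: int = 0
    n_summonable: int = 0
    n_patrol: int = 0

    def __post_init__(self):
        if min(self.n_fixed, self.n_summonable, self.n_patrol) < 0:
            raise ValueError("unit counts must be non-negative")
        if self.total == 0:
            raise ValueError("inventory must contain at least one unit")

    @property
    def total(self) -> int:
        return self.n_fixed + self.n_summonable + self.n_patrol


def make_corridor(
    n_cells: int,
    minutes_per_cell: RationalLike | Sequence[RationalLike] = 1,
    t_hot: RationalLike = 1,
    t_ems: RationalLike = 8,
    density: Sequence[RationalLike] | None = None,
    cell_area: RationalLike = 1,
) -> Corridor:
    """Build and validate a corridor.

    Defaults reproduce the baseline model: one minute to traverse one cell,
    a 1-minute hot threshold, an 8-minute EMS response, uniform unit density,
    and unit cell area.
    """
    if not isinstance(n_cells, int) or n_cells < 1:
        raise ValueError(f"n_cells must be a positive integer, got {n_cells!r}")

    if isinstance(minutes_per_cell, (int, str, Fraction)):
        tau: Union[Fraction, tuple] = _as_fraction(minutes_per_cell, "minutes_per_cell")
        if tau <= 0:
            raise ValueError("minutes_per_cell must be positive")
    else:
        taus = tuple(_as_fraction(t, "minutes_per_cell entry") for t in minutes_per_cell)
        if len(taus) != n_cells:
            raise ValueError(
                f"per-cell minutes length {len(taus)} != n_cells {n_cells}"
            )
        if any(t <= 0 for t in taus):
            raise ValueError("every per-cell transport time must be positive")
        tau = taus

    hot = _as_fraction(t_hot, "t_hot")
    ems = _as_fraction(t_ems, "t_ems")
    if hot <= 0:
        raise ValueError("t_hot must be positive")
    if not hot < ems:
        raise ValueError(f"t_hot must be strictly below t_ems (got {hot} >= {ems})")

    if density is None:
        dens = tuple([Fraction(1)] * n_cells)
    else:
        dens = tuple(_as_fraction(d, "density entry") for d in density)
        if len(dens) != n_cells:
            raise ValueError(f"density length {len(dens)} != n_cells {n_cells}")
        if any(d < 0 for d in dens):
            raise ValueError("density entries must be non-negative")
        if all(d == 0 for d in dens):
            raise ValueError("at least one density entry must be positive")

    area = _as_fraction(cell_area, "cell_area")
    if area <= 0:
        raise ValueError("cell_area must be positive")

    return Corridor(
        n_cells=n_cells,
        minutes_per_cell=tau,
        t_hot=hot,
        t_ems=ems,
        density=dens,
        cell_area=area,
    )


def acquisition_time(aed: AEDPlacement, cell: int, corridor: Corridor) -> int:
    """Minutes (rounded up) to bring a fixed or summonable AED to ``cell``.

    The raw transport time from the unit's cell is halved for a summonable
    unit (it is delivered on call rather than fetched), then a single
    round-up to the next whole minute is applied. Zero distance is zero
    minutes.
    """
    if aed.kind is AEDKind.PATROL:
        raise ValueError(
            "patrolling units have no single acquisition time; "
            "they are averaged over their patrol range by the benefit engine"
        )
    if not 1 <= cell <= corridor.n_cells:
        raise ValueError(f"cell {cell} outside [1, {corridor.n_cells}]")
    raw = corridor.travel_minutes(aed.cell, cell)
    if aed.kind is AEDKind.SUMMONABLE:
        raw = raw / 2
    return math.ceil(raw)


def classify_time(t: int | Fraction, corridor: Corridor) -> ZoneLabel:
    """Zone label for a (rounded) acquisition time of ``t`` minutes."""
    if t < 0:
        raise ValueError("acquisition time cannot be negative")
    if t <= corridor.t_hot:
        return ZoneLabel.HOT
    if t > corridor.t_ems:
        return ZoneLabel.COLD
    return ZoneLabel.WARM
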
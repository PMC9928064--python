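"""Synthetic scenario generation for tests and property sweeps.

Scenarios bundle a corridor (length, per-cell cardiac-arrest density,
per-cell transport time) with an AED inventory. The ``uniform`` shapes
reproduce the baseline modelling assumptions — identical transport speed
everywhere and identical OHCA probability everywhere — under which the
closed-form placement rules are claimed optimal. The non-uniform shapes
(a step, a triangular peak, small random rationals) exercise the general
density- and speed-aware evaluation mode that the benefit formulas support.

Random draws are small exact rationals (tenths between 1/10 and 1), never
floats, so every downstream comparison stays exact; a fixed seed yields a
bit-identical scenario.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction

from .corridor import (
    AEDKind,
    AEDPlacement,
    Corridor,
    Deployment,
    Inventory,
    make_corridor,
)

__all__ = ["ScenarioSpec", "fixture_corridor22", "generate_scenario"]

DENSITY_SHAPES = ("uniform", "step", "triangular", "random-rational")
TAU_SHAPES = ("uniform", "random-rational")


@dataclass(frozen=True)
class ScenarioSpec:
    """Deterministic recipe for one synthetic scenario."""

    seed: int
    n_cells: int
    density_shape: str = "uniform"
    tau_shape: str = "uniform"
    inventory: Inventory = Inventory(n_fixed=1)

    def __post_init__(self):
        if self.density_shape not in DENSITY_SHAPES:
            raise ValueError(
                f"unknown density shape {self.density_shape!r}; "
                f"choose from {DENSITY_SHAPES}"
            )
        if self.tau_shape not in TAU_SHAPES:
            raise ValueError(
                f"unknown tau shape {self.tau_shape!r}; choose from {TAU_SHAPES}"
            )
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")


def _density(shape: str, n: int, rng: random.Random) -> list | None:
    if shape == "uniform":
        return None
    if shape == "step":
        # left half twice as likely as the right half
        half = (n + 1) // 2
        return [Fraction(2)] * half + [Fraction(1)] * (n - half)
    if shape == "triangular":
        # linear peak at the center cell, never zero at the edges
        mid = Fraction(n + 1, 2)
        return [1 + (mid - abs(Fraction(i) - mid)) / n for i in range(1, n + 1)]
    return [Fraction(rng.randint(1, 10), 10) for _ in range(n)]


def _tau(shape: str, n: int, rng: random.Random):
    if shape == "uniform":
        return 1
    return [Fraction(rng.randint(1, 10), 10) for _ in range(n)]


def generate_scenario(spec: ScenarioSpec) -> tuple[Corridor, Inventory]:
    """Materialize a scenario; identical specs give identical corridors."""
    rng = random.Random(spec.seed)
    density = _density(spec.density_shape, spec.n_cells, rng)
    tau = _tau(spec.tau_shape, spec.n_cells, rng)
    corridor = make_corridor(
        spec.n_cells, minutes_per_cell=tau, density=density
    )
    return corridor, spec.inventory


def fixture_corridor22() -> tuple[Corridor, dict[str, Deployment]]:
    """The 22-cell uniform worked example and its named deployments.

    One minute per cell, 1-minute hot threshold, 8-minute EMS threshold.
    The deployments are the four illustrated single- and two-unit fixed
    configurations: a unit at cell 11 (center), the equal-benefit shift to
    cell 9, the pair {9, 19}, and the improved pair {7, 19}.
    """
    corridor = make_corridor(22)

    def dep(*cells: int) -> Deployment:
        return Deployment(
            tuple(AEDPlacement(AEDKind.FIXED, cell=c) for c in cells)
        )

    deployments = {
        "center": dep(11),
        "shifted": dep(9),
        "pair": dep(9, 19),
        "pair_improved": dep(7, 19),
    }
    return corridor, deployments
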
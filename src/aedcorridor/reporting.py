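"""Config parsing, deployment grammar, zone rendering, report writing.

Deployment grammar: comma-separated unit tokens — ``F@11`` (fixed at cell
11), ``S@5`` (summonable), ``P`` (patrolling the whole corridor) or
``P@3-8`` (patrolling cells 3..8).

Reports serialize every rational exactly as a ``"numerator/denominator"``
string with a float rendition alongside; zone tables are CSV with one row
per cell. Output is deterministic: same input, byte-identical file.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Any

import yaml

from .benefit import BenefitTriple, ZoneProfile, zone_profile
from .corridor import (
    AEDKind,
    AEDPlacement,
    Corridor,
    Deployment,
    Inventory,
    ZoneLabel,
    make_corridor,
)
from .rules import VerificationReport
from .search import OptimalResult

__all__ = [
    "EvaluationResult",
    "RunConfig",
    "load_config",
    "parse_deployment",
    "render_zone_map",
    "write_report",
]

_TOKEN_RE = re.compile(r"^(?P<kind>[FSP])(?:@(?P<a>\d+)(?:-(?P<b>\d+))?)?$")


class ParseError(ValueError):
    pass


def parse_deployment(text: str, corridor: Corridor | None = None) -> Deployment:
    """Parse the ``KIND@cell`` grammar into a :class:`Deployment`."""
    units = []
    for raw in text.split(","):
        token = raw.strip()
        if not token:
            raise ParseError(f"empty deployment token in {text!r}")
        m = _TOKEN_RE.match(token)
        if not m:
            raise ParseError(
                f"malformed deployment token {token!r} "
                "(expected F@cell, S@cell, P, or P@start-end)"
            )
        kind = AEDKind(m.group("kind"))
        a = m.group("a")
        b = m.group("b")
        if kind is AEDKind.PATROL:
            if a is None:
                unit = AEDPlacement(kind)
            else:
                lo = int(a)
                hi = int(b) if b is not None else lo
                if lo > hi:
                    raise ParseError(f"patrol range start > end in {token!r}")
                unit = AEDPlacement(kind, patrol_range=(lo, hi))
        else:
            if a is None or b is not None:
                raise ParseError(f"{token!r}: {kind.value}-type units need one cell")
            unit = AEDPlacement(kind, cell=int(a))
        if corridor is not None:
            try:
                unit.validate(corridor)
            except ValueError as exc:
                raise ParseError(f"token {token!r}: {exc}") from exc
        units.append(unit)
    return Deployment(tuple(units))


_ZONE_CHAR = {"hot": "H", "warm": "W", "cold": "C"}


def render_zone_map(profile: ZoneProfile, deployment: Deployment) -> str:
    """Two-line ASCII map: zone letters above static-unit markers."""
    zones = "".join(_ZONE_CHAR[lab.value] for lab in profile.labels)
    markers = ["."] * profile.n_cells
    for unit in deployment.units:
        if unit.kind is AEDKind.PATROL:
            lo, hi = unit.patrol_range or (1, profile.n_cells)
            for c in range(lo, hi + 1):
                if markers[c - 1] == ".":
                    markers[c - 1] = "p"
        else:
            markers[unit.cell - 1] = unit.kind.value
    return zones + "\n" + "".join(markers)


# ---------------------------------------------------------------------------
# serialization helpers

def _frac_str(x: Fraction) -> str:
    return f"{x.numerator}/{x.denominator}" if x.denominator != 1 else str(x.numerator)


def _triple_fields(prefix: str, triple: BenefitTriple) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name, value in (
        ("A_H", triple.hot),
        ("A_C", triple.cold),
        ("A_W", triple.warm),
    ):
        out[f"{prefix}{name}"] = _frac_str(value)
        out[f"{prefix}{name}_float"] = float(value)
    return out


@dataclass(frozen=True)
class EvaluationResult:
    """A deployment together with its benefit and (static) zone profile."""

    corridor: Corridor
    deployment: Deployment
    benefit: BenefitTriple
    profile: ZoneProfile | None  # None when the deployment patrols

    @property
    def zone_map(self) -> str | None:
        if self.profile is None:
            return None
        return render_zone_map(self.profile, self.deployment)


def _evaluation_json(result: EvaluationResult) -> dict:
    doc: dict[str, Any] = {
        "n_cells": result.corridor.n_cells,
        "deployment": str(result.deployment),
    }
    doc.update(_triple_fields("", result.benefit))
    if result.profile is not None:
        doc["zone_counts"] = {
            "hot": result.profile.count(ZoneLabel.HOT),
            "warm": result.profile.count(ZoneLabel.WARM),
            "cold": result.profile.count(ZoneLabel.COLD),
        }
        doc["zone_map"] = result.zone_map
    return doc


def _evaluation_csv(result: EvaluationResult, stream) -> None:
    if result.profile is None:
        raise ValueError(
            "zone tables are defined for static deployments; patrolling "
            "benefits are averages without a single zone profile"
        )
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(["cell", "min_time", "zone", "density", "warm_weight_contribution"])
    corridor = result.corridor
    for i, (t, lab) in enumerate(zip(result.profile.times, result.profile.labels)):
        dens = corridor.density[i]
        if lab.value == "warm":
            contrib = dens * corridor.cell_area / t
        else:
            contrib = Fraction(0)
        writer.writerow(
            [
                i + 1,
                "" if t is None else t,
                lab.value,
                _frac_str(dens),
                _frac_str(contrib),
            ]
        )


def _optimal_json(result: OptimalResult) -> dict:
    doc: dict[str, Any] = {}
    doc.update(_triple_fields("best_", result.best))
    doc["argmax"] = [str(d) for d in result.argmax]
    doc["n_evaluated"] = result.n_evaluated
    doc["argmax_overflow"] = result.argmax_overflow
    return doc


def _verification_json(report: VerificationReport) -> dict:
    rows = []
    for row in report.rows:
        entry: dict[str, Any] = {
            "n_cells": row.n_cells,
            "inventory": [
                row.inventory.n_fixed,
                row.inventory.n_summonable,
                row.inventory.n_patrol,
            ],
            "rule_deployment": None
            if row.rule_deployment is None
            else str(row.rule_deployment),
            "equal": row.equal,
            "note": row.note,
        }
        if row.rule_benefit is not None:
            entry.update(_triple_fields("rule_", row.rule_benefit))
        if row.optimal_benefit is not None:
            entry.update(_triple_fields("optimal_", row.optimal_benefit))
        rows.append(entry)
    return {"rows": rows, "all_equal": report.all_equal}


def _verification_csv(report: VerificationReport, stream) -> None:
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(
        [
            "n_cells",
            "n_fixed",
            "n_summonable",
            "n_patrol",
            "rule_deployment",
            "rule_A_H",
            "rule_A_C",
            "rule_A_W",
            "optimal_A_H",
            "optimal_A_C",
            "optimal_A_W",
            "equal",
            "note",
        ]
    )
    for row in report.rows:
        rb = row.rule_benefit
        ob = row.optimal_benefit
        writer.writerow(
            [
                row.n_cells,
                row.inventory.n_fixed,
                row.inventory.n_summonable,
                row.inventory.n_patrol,
                "" if row.rule_deployment is None else str(row.rule_deployment),
                *( ["", "", ""] if rb is None
                   else [_frac_str(rb.hot), _frac_str(rb.cold), _frac_str(rb.warm)] ),
                *( ["", "", ""] if ob is None
                   else [_frac_str(ob.hot), _frac_str(ob.cold), _frac_str(ob.warm)] ),
                "" if row.equal is None else str(row.equal).lower(),
                row.note,
            ]
        )


def _optimal_csv(result: OptimalResult, stream) -> None:
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(["deployment", "A_H", "A_C", "A_W"])
    b = result.best
    for dep in result.argmax:
        writer.writerow(
            [str(dep), _frac_str(b.hot), _frac_str(b.cold), _frac_str(b.warm)]
        )


def write_report(result, path, format: str = "json") -> None:
    """Serialize a result to ``path``; the file is written atomically enough
    that a failed serialization never leaves a partial report."""
    if format not in ("json", "csv"):
        raise ValueError(f"unknown report format {format!r}")
    buffer = io.StringIO()
    if format == "json":
        if isinstance(result, EvaluationResult):
            doc = _evaluation_json(result)
        elif isinstance(result, OptimalResult):
            doc = _optimal_json(result)
        elif isinstance(result, VerificationReport):
            doc = _verification_json(result)
        else:
            raise TypeError(f"cannot report a {type(result).__name__}")
        json.dump(doc, buffer, indent=2)
        buffer.write("\n")
    else:
        if isinstance(result, EvaluationResult):
            _evaluation_csv(result, buffer)
        elif isinstance(result, OptimalResult):
            _optimal_csv(result, buffer)
        elif isinstance(result, VerificationReport):
            _verification_csv(result, buffer)
        else:
            raise TypeError(f"cannot report a {type(result).__name__}")
    Path(path).write_text(buffer.getvalue())


# ---------------------------------------------------------------------------
# config files

@dataclass
class RunConfig:
    """A structured run description loadable from YAML or JSON."""

    corridor_kwargs: dict = field(default_factory=dict)
    deployment: str | None = None
    inventory: Inventory | None = None
    options: dict = field(default_factory=dict)
    verify_lengths: list[int] = field(default_factory=list)
    verify_inventories: list = field(default_factory=list)

    def build_corridor(self) -> Corridor:
        return make_corridor(**self.corridor_kwargs)


def _parse_rational_field(value):
    if isinstance(value, (list, tuple)):
        return [Fraction(str(v)) for v in value]
    return Fraction(str(value))


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run config (YAML parses both)."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ParseError(f"config root must be a mapping, got {type(raw).__name__}")

    kwargs: dict[str, Any] = {}
    cor = raw.get("corridor", {})
    if "length" not in cor:
        raise ParseError("config corridor section requires 'length'")
    kwargs["n_cells"] = int(cor["length"])
    for src, dst in (
        ("minutes_per_cell", "minutes_per_cell"),
        ("t_hot", "t_hot"),
        ("t_ems", "t_ems"),
        ("cell_area", "cell_area"),
    ):
        if src in cor:
            kwargs[dst] = _parse_rational_field(cor[src])
    density = cor.get("density", "uniform")
    if density != "uniform":
        kwargs["density"] = _parse_rational_field(density)

    inventory = None
    if "inventory" in raw:
        inv = raw["inventory"]
        inventory = Inventory(
            n_fixed=int(inv.get("fixed", 0)),
            n_summonable=int(inv.get("summonable", 0)),
            n_patrol=int(inv.get("patrolling", 0)),
        )

    verify = raw.get("verify", {})
    return RunConfig(
        corridor_kwargs=kwargs,
        deployment=raw.get("deployment"),
        inventory=inventory,
        options=dict(raw.get("options", {})),
        verify_lengths=[int(x) for x in verify.get("lengths", [])],
        verify_inventories=[tuple(x) for x in verify.get("inventories", [])],
    )


def evaluate_deployment(corridor: Corridor, deployment: Deployment) -> EvaluationResult:
    """Bundle a deployment's benefit and, when static, its zone profile."""
    from .benefit import deployment_benefit

    benefit = deployment_benefit(deployment, corridor)
    profile = None
    if not deployment.patrol_units:
        profile = zone_profile(deployment, corridor)
    return EvaluationResult(
        corridor=corridor, deployment=deployment, benefit=benefit, profile=profile
    )
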
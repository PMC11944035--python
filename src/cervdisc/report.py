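"""Scenario bundles and pairwise contrast tables.

The reporting stage assembles, per posture scenario, the per-level disc
loads, the disc geometric/water states and the per-ligament force totals,
and compares two scenarios metric by metric: value_a, value_b, absolute
delta, relative percent change (and the ratio in percent, since published
tables use both conventions), with a direction-change flag on shear rows
whose sign flips.

Two modes:

* ``paper`` (default): values come from the packaged reference tables, so
  the contrasts reproduce the published report cell for cell. Volumes are
  recomputed as height x area; cells whose shipped value disagrees with the
  recomputation, or whose published contrast cannot be recomputed at all,
  carry a flag with both numbers — they are never silently corrected.
* ``forward``: loads come from the quasi-static posture model and states
  from the swelling solver; clearly labeled experimental in the metadata.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from . import swelling
from .disc import (
    LEVELS,
    DiscLevel,
    DiscLoad,
    DiscReference,
    DiscState,
    data_path,
    disc_volume,
    load_known_discrepancies,
    load_reference_table,
    make_state,
    percent_change,
    round_to_print,
)
from .ligaments import (
    Ligament,
    Region,
    failure_margins,
    load_ligament_table,
    total_ligament_force,
)
from .loading import Anthropometry, PostureScenario, disc_loads, packaged_scenario

SCENARIOS = ("nbp1g", "sm0g", "nbp0g")

METRICS = ("compression", "shear", "height", "area", "volume", "phi_NP", "phi_AF", "ligament_force")


@dataclass
class ScenarioBundle:
    """Everything the report stage knows about one scenario."""

    name: str
    loads: list[DiscLoad]
    states: list[DiscState]
    ligament_totals: dict[Ligament, float]
    metadata: dict = field(default_factory=dict)


class ComparisonRow(BaseModel):
    """One cell family of a pairwise contrast table.

    ``percent`` is the relative change 100*(b-a)/a, ``ratio_pct`` the plain
    ratio 100*b/a; ``delta`` = value_b - value_a. ``level`` holds the disc
    level for disc metrics and the ligament name for ligament rows.
    """

    model_config = ConfigDict(frozen=True)

    level: str
    metric: str
    scenario_a: str
    value_a: float
    scenario_b: str
    value_b: float
    delta: float
    percent: Optional[float]
    ratio_pct: Optional[float]
    direction_change: bool = False
    flag: Optional[str] = None
    printed_value: Optional[float] = None

    @model_validator(mode="after")
    def _consistent(self) -> "ComparisonRow":
        if abs(self.delta - (self.value_b - self.value_a)) > 1e-9:
            raise ValueError("delta inconsistent with values")
        if self.percent is not None:
            expect = percent_change(self.value_a, self.value_b)
            if abs(self.percent - expect) > 1e-9 * max(1.0, abs(expect)):
                raise ValueError("percent inconsistent with values")
        return self


def _read_loads_csv(path: Path, scenario: str) -> list[DiscLoad]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return [
        DiscLoad(
            level=DiscLevel(row["level"]),
            scenario=scenario,
            compression=float(row["compression_N"]),
            shear=float(row["shear_N"]),
        )
        for row in rows
    ]


def _read_states_csv(path: Path, scenario: str) -> tuple[list[DiscState], dict]:
    """States from a packaged table; volume recomputed, shipped value checked."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    states, volume_flags = [], {}
    for row in rows:
        level = DiscLevel(row["level"])
        h, a = float(row["h_mm"]), float(row["A_mm2"])
        v_printed = float(row["V_printed_mm3"])
        v = disc_volume(h, a)
        if abs(v - v_printed) > 0.05:  # disagrees at the shipped 1-decimal precision
            volume_flags[level.value] = {"printed": v_printed, "recomputed": round(v, 1)}
        states.append(
            make_state(
                level=level,
                scenario=scenario,
                h=h,
                A=a,
                phi_NP=float(row["phi_np"]),
                phi_AF=float(row["phi_af"]),
            )
        )
    return states, volume_flags


def _ligament_totals_csv(scenario: str) -> dict[Ligament, float]:
    with open(data_path("ligament_forces.csv"), newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return {
        Ligament(row["ligament"]): float(row["force_N"])
        for row in rows
        if row["scenario"] == scenario
    }


def run_scenario(
    scenario: str | PostureScenario,
    mode: str = "paper",
    refs: list[DiscReference] | None = None,
    constants: swelling.OsmoticConstants | None = None,
    anthro: Anthropometry | None = None,
    muscle_cocontraction: float = 30.0,
) -> ScenarioBundle:
    """Assemble the load/state/ligament bundle for one scenario.

    ``paper`` mode reads the packaged reference tables (scenario must be one
    of nbp1g/sm0g/nbp0g); ``forward`` mode computes loads from the posture
    model and states from the swelling solver, and is labeled experimental.
    """
    if mode not in ("paper", "forward"):
        raise ValueError(f"mode must be 'paper' or 'forward', got {mode!r}")
    name = scenario if isinstance(scenario, str) else scenario.name
    if mode == "paper":
        if name not in SCENARIOS:
            raise ValueError(f"no packaged tables for scenario {name!r}; expected one of {SCENARIOS}")
        loads_path = data_path(f"disc_loads_{name}.csv")
        states_path = data_path(f"disc_states_{name}.csv")
        for p in (loads_path, states_path):
            if not p.exists():
                raise FileNotFoundError(f"expected packaged fixture {p}")
        loads = _read_loads_csv(loads_path, name)
        states, volume_flags = _read_states_csv(states_path, name)
        return ScenarioBundle(
            name=name,
            loads=loads,
            states=states,
            ligament_totals=_ligament_totals_csv(name),
            metadata={
                "mode": "paper",
                "provenance": "packaged reference tables",
                "volume_flags": volume_flags,
            },
        )

    posture = packaged_scenario(name) if isinstance(scenario, str) else scenario
    refs = refs or load_reference_table()
    constants = constants or swelling.OsmoticConstants()
    loads = disc_loads(posture, anthro, muscle_cocontraction=muscle_cocontraction)
    states = []
    for ref, load in zip(refs, loads):
        sol = swelling.solve_equilibrium(load.compression, ref, constants)
        phi_np, phi_af, _ = swelling.partition_water_content(sol.r, ref)
        states.append(
            make_state(
                level=ref.level,
                scenario=name,
                h=sol.r * ref.h0,
                A=ref.A0,
                phi_NP=phi_np,
                phi_AF=phi_af,
                np_area_fraction=ref.np_area_fraction,
                r=sol.r,
                Fs=sol.Fs,
            )
        )
    strains = ligament_strains_from_states(states, refs)
    return ScenarioBundle(
        name=name,
        loads=loads,
        states=states,
        ligament_totals=total_ligament_force(strains, load_ligament_table()),
        metadata={
            "mode": "forward",
            "provenance": "experimental: quasi-static posture model + swelling solver",
        },
    )


#: Disc levels spanned by each ligament reporting region.
REGION_LEVELS = {
    Region.C2C5: (DiscLevel.C2C3, DiscLevel.C3C4, DiscLevel.C4C5),
    Region.C5T1: (DiscLevel.C5C6, DiscLevel.C6C7, DiscLevel.C7T1),
}


def ligament_strains_from_states(
    states: list[DiscState],
    refs: list[DiscReference],
    reference_length: float = 20.0,
) -> dict[tuple[Ligament, Region], float]:
    """Regional ligament strains (%) from disc height changes.

    A simple kinematic coupling for forward experiments: the summed height
    change of a region's discs, over the ligament reference length, loads
    all three ligaments of that region equally; net compression leaves the
    ligaments slack (strain clamped at zero). This is an explicit modeling
    choice, not a reproduction of any published strain mapping.
    """
    h_by_level = {s.level: s.h for s in states}
    h0_by_level = {r.level: r.h0 for r in refs}
    strains = {}
    for region, levels in REGION_LEVELS.items():
        dh = sum(h_by_level[lv] - h0_by_level[lv] for lv in levels)
        strain = max(0.0, 100.0 * dh / reference_length)
        for lig in Ligament:
            strains[(lig, region)] = strain
    return strains


def _discrepancy_index() -> dict[tuple[str, str, str, str], dict]:
    idx = {}
    for entry in load_known_discrepancies():
        if entry.get("kind") == "contrast_cell":
            key = (entry["scenario_ref"], entry["scenario_new"], entry["metric"], entry["level"])
            idx[key] = entry
    return idx


def compare_scenarios(bundle_a: ScenarioBundle, bundle_b: ScenarioBundle) -> list[ComparisonRow]:
    """Pairwise contrast rows, bundle_a as the reference scenario.

    Shear rows carry a direction-change flag when the sign flips between
    scenarios; cells listed in the packaged known-discrepancy table carry a
    flag and the published value alongside the recomputed one.
    """
    flags = _discrepancy_index()

    def level_map(items):
        return {item.level: item for item in items}

    rows: list[ComparisonRow] = []
    loads_a, loads_b = level_map(bundle_a.loads), level_map(bundle_b.loads)
    states_a, states_b = level_map(bundle_a.states), level_map(bundle_b.states)
    if set(loads_a) != set(loads_b) or set(states_a) != set(states_b):
        raise ValueError("scenario bundles cover different disc levels")

    def add(level: str, metric: str, va: float, vb: float, direction: bool = False):
        entry = flags.get((bundle_a.name, bundle_b.name, metric, level))
        pct = percent_change(va, vb) if va != 0 else None
        rows.append(
            ComparisonRow(
                level=level,
                metric=metric,
                scenario_a=bundle_a.name,
                value_a=va,
                scenario_b=bundle_b.name,
                value_b=vb,
                delta=vb - va,
                percent=pct,
                ratio_pct=None if pct is None else pct + 100.0,
                direction_change=direction,
                flag=entry["note"] if entry else None,
                printed_value=entry.get("printed_pct") if entry else None,
            )
        )

    for level in LEVELS:
        la, lb = loads_a[level], loads_b[level]
        add(level.value, "compression", la.compression, lb.compression)
        add(level.value, "shear", la.shear, lb.shear, direction=(la.shear * lb.shear < 0))
        sa, sb = states_a[level], states_b[level]
        add(level.value, "height", sa.h, sb.h)
        add(level.value, "area", sa.A, sb.A)
        add(level.value, "volume", sa.V, sb.V)
        add(level.value, "phi_NP", sa.phi_NP, sb.phi_NP)
        add(level.value, "phi_AF", sa.phi_AF, sb.phi_AF)
    for lig in Ligament:
        if lig in bundle_a.ligament_totals and lig in bundle_b.ligament_totals:
            add(lig.value, "ligament_force", bundle_a.ligament_totals[lig], bundle_b.ligament_totals[lig])
    return rows


def annotate_ligament_failure(bundle: ScenarioBundle) -> dict:
    """Failure-threshold annotation for a bundle's ligament totals."""
    return {
        lig.value: info for lig, info in failure_margins(bundle.ligament_totals).items()
    }


def comparison_csv(rows: list[ComparisonRow]) -> str:
    """Deterministic CSV rendering of contrast rows (same input, same bytes).

    Raw values are written with repr-level precision; the rounded percent
    column uses the 1-decimal printing convention of the reference report.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        [
            "level",
            "metric",
            "scenario_a",
            "value_a",
            "scenario_b",
            "value_b",
            "delta",
            "percent",
            "percent_rounded",
            "ratio_pct",
            "direction_change",
            "flag",
            "printed_value",
        ]
    )
    for row in rows:
        writer.writerow(
            [
                row.level,
                row.metric,
                row.scenario_a,
                repr(row.value_a),
                row.scenario_b,
                repr(row.value_b),
                repr(row.delta),
                "" if row.percent is None else repr(row.percent),
                "" if row.percent is None else round_to_print(row.percent),
                "" if row.ratio_pct is None else repr(row.ratio_pct),
                int(row.direction_change),
                row.flag or "",
                "" if row.printed_value is None else row.printed_value,
            ]
        )
    return buf.getvalue()


def write_comparison(rows: list[ComparisonRow], path: str | Path) -> None:
    Path(path).write_text(comparison_csv(rows), encoding="utf-8")
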
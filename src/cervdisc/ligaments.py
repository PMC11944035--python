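"""Piecewise-linear cervical ligament model.

Three spinal ligaments are modeled — anterior longitudinal (ALL), posterior
longitudinal (PLL) and ligamentum flavum (LF) — each in two cervical regions
(C2-C5 and C5-T1) with region-specific stiffness taken from cadaveric data.
Stiffness is a function of strain: inside a tabulated segment the segment's
stiffness applies, between segments it is linearly interpolated, and beyond
the first/last segment it is clamped. Force is stiffness times elongation
(strain minus slack, over the reference length), so it is continuous and
non-decreasing in strain.

The packaged stiffness table carries one segment per (ligament, region);
the machinery accepts multi-segment ligaments for generality.
"""

from __future__ import annotations

import csv
import enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, ConfigDict, field_validator

from .disc import DomainError, data_path


class Ligament(str, enum.Enum):
    ALL = "ALL"  #: anterior longitudinal ligament
    PLL = "PLL"  #: posterior longitudinal ligament
    LF = "LF"  #: ligamentum flavum


class Region(str, enum.Enum):
    C2C5 = "C2C5"
    C5T1 = "C5T1"


#: Cadaveric tensile failure loads (N) used for the safety-margin annotation.
FAILURE_THRESHOLDS_N: dict[Ligament, float] = {
    Ligament.ALL: 494.0,
    Ligament.PLL: 462.9,
    Ligament.LF: 315.8,
}


class LigamentSpec(BaseModel):
    """One stiffness segment of a regional ligament.

    stiffness: N/mm over the strain validity range [strain_lo, strain_hi] (%).
    slack_strain: strain (%) below which the ligament carries no force.
    reference_length: mm; converts strain to elongation.
    """

    model_config = ConfigDict(frozen=True)

    ligament: Ligament
    region: Region
    stiffness: float
    strain_lo: float
    strain_hi: float
    slack_strain: float = 0.0
    reference_length: float = 20.0

    @field_validator("stiffness", "reference_length")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    def model_post_init(self, __context) -> None:
        if not self.strain_lo < self.strain_hi:
            raise ValueError(
                f"strain bounds must be ordered, got ({self.strain_lo}, {self.strain_hi})"
            )


_LIGAMENT_COLUMNS = [
    "ligament",
    "region",
    "stiffness_N_per_mm",
    "strain_lo_pct",
    "strain_hi_pct",
    "slack_strain_pct",
    "reference_length_mm",
]


def load_ligament_table(source: str | Path | None = None) -> list[LigamentSpec]:
    """Load ligament stiffness segments from CSV (packaged table by default).

    Note the packaged LF C5-T1 strain range is stored in ascending order;
    the source table prints it reversed.
    """
    path = data_path("ligaments.csv") if source is None else Path(source)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _LIGAMENT_COLUMNS:
            raise ValueError(f"expected columns {_LIGAMENT_COLUMNS}, got {reader.fieldnames}")
        specs = [
            LigamentSpec(
                ligament=Ligament(row["ligament"]),
                region=Region(row["region"]),
                stiffness=float(row["stiffness_N_per_mm"]),
                strain_lo=float(row["strain_lo_pct"]),
                strain_hi=float(row["strain_hi_pct"]),
                slack_strain=float(row["slack_strain_pct"]),
                reference_length=float(row["reference_length_mm"]),
            )
            for row in reader
        ]
    return specs


def stiffness_at(strain: float, segments: Sequence[LigamentSpec]) -> float:
    """Strain-dependent stiffness (N/mm) over a set of segments.

    Below the first segment and above the last the edge stiffness applies;
    in the gap between consecutive segments the stiffness is interpolated
    linearly in strain, keeping the force continuous.
    """
    segs = sorted(segments, key=lambda s: s.strain_lo)
    if strain <= segs[0].strain_lo:
        return segs[0].stiffness
    for seg in segs:
        if seg.strain_lo <= strain <= seg.strain_hi:
            return seg.stiffness
    for a, b in zip(segs, segs[1:]):
        if a.strain_hi < strain < b.strain_lo:
            t = (strain - a.strain_hi) / (b.strain_lo - a.strain_hi)
            return (1.0 - t) * a.stiffness + t * b.stiffness
    return segs[-1].stiffness


def ligament_force(strain: float, spec: LigamentSpec | Sequence[LigamentSpec]) -> float:
    """Tensile force (N) of a regional ligament at the given strain (%).

    Elongation is (strain - slack)/100 * reference_length, clamped at zero;
    the multiplying stiffness is :func:`stiffness_at` evaluated at the strain.
    """
    segments = [spec] if isinstance(spec, LigamentSpec) else list(spec)
    if strain < 0:
        raise DomainError(f"strain must be nonnegative, got {strain}")
    first = segments[0]
    elongation = max(0.0, (strain - first.slack_strain) / 100.0) * first.reference_length
    return stiffness_at(strain, segments) * elongation


def total_ligament_force(
    strains: Mapping[tuple[Ligament, Region], float],
    specs: Iterable[LigamentSpec] | None = None,
) -> dict[Ligament, float]:
    """Sum regional ligament forces into per-ligament totals (N).

    ``strains`` maps (ligament, region) to strain in percent; every region of
    every modeled ligament must be supplied.
    """
    specs = list(specs) if specs is not None else load_ligament_table()
    by_key: dict[tuple[Ligament, Region], list[LigamentSpec]] = {}
    for spec in specs:
        by_key.setdefault((spec.ligament, spec.region), []).append(spec)
    missing = [k for k in by_key if k not in strains]
    if missing:
        raise ValueError(f"missing strain for regions: {sorted((l.value, r.value) for l, r in missing)}")
    totals: dict[Ligament, float] = {lig: 0.0 for lig in Ligament if any(k[0] == lig for k in by_key)}
    for (lig, region), segs in by_key.items():
        totals[lig] += ligament_force(strains[(lig, region)], segs)
    return totals


def calibrate_uniform_strain(
    ligament: Ligament,
    target_total: float,
    specs: Iterable[LigamentSpec] | None = None,
    strain_hi: float = 400.0,
) -> float:
    """Strain (%) applied equally to both regions that reproduces a total force.

    Used to express reported per-ligament totals as an equivalent operating
    strain of the model (a calibration, not a forward prediction).
    """
    from scipy.optimize import brentq

    specs = list(specs) if specs is not None else load_ligament_table()
    segs = [s for s in specs if s.ligament == ligament]
    if not segs:
        raise ValueError(f"no segments for ligament {ligament}")
    regions = {s.region for s in segs}

    def total(strain: float) -> float:
        strains = {(ligament, region): strain for region in regions}
        return total_ligament_force(strains, segs)[ligament]

    if target_total <= 0:
        return min(s.slack_strain for s in segs)
    return float(brentq(lambda s: total(s) - target_total, 0.0, strain_hi, xtol=1e-10))


def failure_margins(
    totals: Mapping[Ligament, float],
    thresholds: Mapping[Ligament, float] | None = None,
) -> dict[Ligament, dict[str, float | bool]]:
    """Annotate per-ligament totals with cadaveric failure thresholds.

    Returns, per ligament: the force, the threshold, the margin (threshold
    minus force, N) and whether the force stays below failure.
    """
    thresholds = thresholds or FAILURE_THRESHOLDS_N
    out: dict[Ligament, dict[str, float | bool]] = {}
    for lig, force in totals.items():
        thr = thresholds[lig]
        out[lig] = {
            "force_N": float(force),
            "threshold_N": float(thr),
            "margin_N": float(thr - force),
            "below_failure": bool(force < thr),
        }
    return out
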
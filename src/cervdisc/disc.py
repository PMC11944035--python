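"""Domain types, packaged reference tables, and shared geometry helpers.

The disc is treated as a lumped element: a cross-sectional area ``A`` (mm^2)
times a height ``h`` (mm) gives its volume, and the nucleus pulposus (NP)
occupies a fixed fraction of the area, the annulus fibrosus (AF) the rest.
All interface units are mm / mm^2 / mm^3 / kPa / mol m^-3 (numerically equal
to mM); internal osmotic arithmetic is SI (see :mod:`cervdisc.swelling`).
"""

from __future__ import annotations

import csv
import enum
import json
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DiscLevel(str, enum.Enum):
    """Cervical disc levels, ordered cranio-caudally (C2-C3 down to C7-T1)."""

    C2C3 = "C2C3"
    C3C4 = "C3C4"
    C4C5 = "C4C5"
    C5C6 = "C5C6"
    C6C7 = "C6C7"
    C7T1 = "C7T1"

    @property
    def index(self) -> int:
        return list(DiscLevel).index(self)

    def __lt__(self, other: "DiscLevel") -> bool:  # type: ignore[override]
        return self.index < other.index


LEVELS = tuple(DiscLevel)

#: NP occupies 40% of the disc cross-section (cadaveric data assumption).
DEFAULT_NP_AREA_FRACTION = 0.40
#: AF reference fixed charge density is 80% of the NP value.
DEFAULT_FCD_RATIO_AF_NP = 0.80
#: NP reference fixed charge density, mol/m^3. No measured value accompanies
#: the reference geometry; 250 mol/m^3 is a typical healthy-disc magnitude
#: and is exposed in every API that consumes it.
DEFAULT_C0F_NP = 250.0


class DiscReference(BaseModel):
    """Per-level geometric and osmotic reference parameters.

    ``A0``/``h0`` are the reference (1 g, loaded) cross-sectional area and
    height; ``phi0_NP``/``phi0_AF`` the reference water fractions of nucleus
    pulposus and annulus fibrosus.
    """

    model_config = ConfigDict(frozen=True)

    level: DiscLevel
    A0: float  # mm^2
    h0: float  # mm
    phi0_NP: float
    phi0_AF: float
    np_area_fraction: float = DEFAULT_NP_AREA_FRACTION
    fcd_ratio_AF_NP: float = DEFAULT_FCD_RATIO_AF_NP
    c0F_NP: float = DEFAULT_C0F_NP  # mol/m^3

    @field_validator("A0", "h0", "c0F_NP")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator("np_area_fraction")
    @classmethod
    def _frac_open(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError(f"np_area_fraction must lie in (0, 1), got {v}")
        return v

    @field_validator("fcd_ratio_AF_NP")
    @classmethod
    def _ratio(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError(f"fcd_ratio_AF_NP must lie in (0, 1], got {v}")
        return v

    @model_validator(mode="after")
    def _water_fractions(self) -> "DiscReference":
        if not (0 < self.phi0_AF <= self.phi0_NP < 1):
            raise ValueError(
                "water fractions must satisfy 0 < phi0_AF <= phi0_NP < 1, "
                f"got phi0_NP={self.phi0_NP}, phi0_AF={self.phi0_AF}"
            )
        return self

    @property
    def phi0_combined(self) -> float:
        """Area-weighted reference water fraction (0.4*NP + 0.6*AF by default)."""
        f = self.np_area_fraction
        return f * self.phi0_NP + (1.0 - f) * self.phi0_AF


class DiscState(BaseModel):
    """A deformed disc under one scenario.

    ``r`` (height ratio h/h0) and ``Fs`` (swelling pressure, kPa) are only
    known when the state came from the swelling solver; states read from
    reference tables leave them ``None``.
    """

    model_config = ConfigDict(frozen=True)

    level: DiscLevel
    scenario: str
    h: float  # mm
    A: float  # mm^2
    V: float  # mm^3
    phi_NP: float
    phi_AF: float
    phi: float
    np_area_fraction: float = DEFAULT_NP_AREA_FRACTION
    r: Optional[float] = None
    Fs: Optional[float] = None  # kPa

    @model_validator(mode="after")
    def _consistency(self) -> "DiscState":
        if not (0 < self.phi_AF <= self.phi_NP < 1):
            raise ValueError(
                f"require 0 < phi_AF <= phi_NP < 1, got NP={self.phi_NP}, AF={self.phi_AF}"
            )
        v = self.h * self.A
        if abs(self.V - v) > 1e-9 * max(1.0, abs(v)):
            raise ValueError(f"V={self.V} inconsistent with h*A={v}")
        f = self.np_area_fraction
        mix = f * self.phi_NP + (1.0 - f) * self.phi_AF
        if abs(self.phi - mix) > 1e-12:
            raise ValueError(f"phi={self.phi} inconsistent with mixture {mix}")
        return self


def make_state(
    level: DiscLevel,
    scenario: str,
    h: float,
    A: float,
    phi_NP: float,
    phi_AF: float,
    np_area_fraction: float = DEFAULT_NP_AREA_FRACTION,
    r: Optional[float] = None,
    Fs: Optional[float] = None,
) -> DiscState:
    """Build a consistent :class:`DiscState`, deriving volume and combined phi."""
    f = np_area_fraction
    return DiscState(
        level=level,
        scenario=scenario,
        h=h,
        A=A,
        V=disc_volume(h, A),
        phi_NP=phi_NP,
        phi_AF=phi_AF,
        phi=f * phi_NP + (1.0 - f) * phi_AF,
        np_area_fraction=np_area_fraction,
        r=r,
        Fs=Fs,
    )


class DiscLoad(BaseModel):
    """Per-level disc load: axial compression (N, positive = compressive) and
    sagittal shear (N, positive = directed posterior to the coronal plane)."""

    model_config = ConfigDict(frozen=True)

    level: DiscLevel
    scenario: str
    compression: float
    shear: float


def disc_volume(h: float, A: float) -> float:
    """Volume (mm^3) of the lumped disc element: height times area.

    Raises :class:`DomainError` for negative inputs.
    """
    if h < 0 or A < 0:
        raise DomainError(f"height and area must be nonnegative, got h={h}, A={A}")
    return h * A


def percent_change(reference: float, new: float) -> float:
    """Relative change from ``reference`` to ``new``, in percent.

    Evaluated in decimal arithmetic on the shortest representation of the
    inputs, so table values with few printed digits yield exact ties
    (e.g. 0.80 -> 0.87 gives exactly 8.75) instead of binary-float noise.
    Raises :class:`DomainError` when ``reference`` is zero.
    """
    if reference == 0:
        raise DomainError("percent change is undefined for a zero reference")
    ref_d, new_d = Decimal(repr(float(reference))), Decimal(repr(float(new)))
    return float(100 * (new_d - ref_d) / ref_d)


def round_to_print(x: float, ndigits: int = 1, mode: str = "half_even") -> float:
    """Round to the precision used in printed report tables.

    Defaults to round-half-even, which reproduces the published contrast
    tables at exact .5 ties; ``mode='half_away'`` rounds ties away from zero.
    """
    rounding = {"half_even": ROUND_HALF_EVEN, "half_away": ROUND_HALF_UP}[mode]
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=rounding))


# --------------------------------------------------------------------------
# Packaged reference tables
# --------------------------------------------------------------------------

_DATA_PACKAGE = "cervdisc.data"

_REFERENCE_COLUMNS = ["level", "A0_mm2", "h0_mm", "phi0_np", "phi0_af"]


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files(_DATA_PACKAGE).joinpath(name)))


def load_reference_table(
    source: str | Path | None = None,
    np_area_fraction: float = DEFAULT_NP_AREA_FRACTION,
    fcd_ratio_AF_NP: float = DEFAULT_FCD_RATIO_AF_NP,
    c0F_NP: float = DEFAULT_C0F_NP,
) -> list[DiscReference]:
    """Load per-level disc reference parameters from CSV.

    With no ``source``, the packaged reference table is used. Records are
    returned in cranio-caudal order; the osmotic defaults (NP area fraction,
    AF/NP fixed-charge ratio, NP reference FCD) are injected into every record.
    """
    path = data_path("disc_reference.csv") if source is None else Path(source)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _REFERENCE_COLUMNS:
            raise ValueError(
                f"expected columns {_REFERENCE_COLUMNS}, got {reader.fieldnames}"
            )
        rows = {row["level"]: row for row in reader}
    missing = [lv.value for lv in LEVELS if lv.value not in rows]
    if missing:
        raise ValueError(f"reference table is missing levels: {missing}")
    refs = []
    for lv in LEVELS:
        row = rows[lv.value]
        refs.append(
            DiscReference(
                level=lv,
                A0=float(row["A0_mm2"]),
                h0=float(row["h0_mm"]),
                phi0_NP=float(row["phi0_np"]),
                phi0_AF=float(row["phi0_af"]),
                np_area_fraction=np_area_fraction,
                fcd_ratio_AF_NP=fcd_ratio_AF_NP,
                c0F_NP=c0F_NP,
            )
        )
    return refs


def write_reference_table(refs: Iterable[DiscReference], path: str | Path) -> None:
    """Write reference records in the packaged CSV dialect (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_REFERENCE_COLUMNS)
        for ref in refs:
            writer.writerow(
                [
                    ref.level.value,
                    format(ref.A0, "g"),
                    format(ref.h0, "g"),
                    format(ref.phi0_NP, "g"),
                    format(ref.phi0_AF, "g"),
                ]
            )


def reference_by_level(refs: Iterable[DiscReference]) -> dict[DiscLevel, DiscReference]:
    return {ref.level: ref for ref in refs}


def load_known_discrepancies() -> list[dict]:
    """Internal inconsistencies of the packaged reference report, as shipped.

    Each entry names the table cell, the value printed in the source report,
    and the value this pipeline recomputes; flagged cells are reported with
    both numbers and are never silently corrected.
    """
    with open(data_path("known_discrepancies.json"), encoding="utf-8") as fh:
        return json.load(fh)
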
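"""Simplified quasi-static cervical load model.

A transparent stand-in for a full inverse-dynamics engine: each disc level
carries the weight of the head plus the cervical segments above it, resolved
into the disc's local frame by the level's sagittal tilt, plus an equivalent
single-extensor compression that balances the gravitational flexion moment,
plus a constant co-contraction offset representing baseline muscle tone
(which is what keeps disc compression nonzero in weightlessness).

Sign convention for shear: positive points posterior to the coronal plane,
so gravity acting on an anteriorly tilted level produces negative (anterior)
shear. The model is linear in the gravity factor when the co-contraction
offset is zero, and reduces to pure axial load for an upright, untilted
spine. It makes no claim to reproduce the absolute joint loads of a
muscle-recruitment optimizer; those are shipped separately as reference
load tables for the reporting stage.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .disc import LEVELS, DiscLevel, DiscLoad, data_path

G0 = 9.81  # m/s^2

#: Joint angle names accepted in posture definitions (degrees).
JOINT_ANGLE_NAMES = (
    "neck_flexion",
    "sternoclavicular_protraction",
    "sternoclavicular_elevation",
    "shoulder_flexion",
    "shoulder_abduction",
    "elbow_flexion",
    "elbow_pronation",
    "hip_flexion",
    "hip_abduction",
    "hip_external_rotation",
    "knee_flexion",
    "ankle_plantarflexion",
)

#: Baseline anterior tilt (deg) of each disc level in a neutral lordotic
#: stance, decreasing cranio-caudally (upper levels are more inclined).
DEFAULT_LORDOSIS_TILT = {
    DiscLevel.C2C3: 10.0,
    DiscLevel.C3C4: 9.0,
    DiscLevel.C4C5: 8.0,
    DiscLevel.C5C6: 7.0,
    DiscLevel.C6C7: 6.0,
    DiscLevel.C7T1: 5.0,
}


class PostureScenario(BaseModel):
    """A named whole-body posture: joint angles (deg) plus a gravity factor."""

    model_config = ConfigDict(frozen=True)

    name: str
    gravity_factor: float
    joint_angles: dict[str, float] = {}
    cervical_tilt_per_level: Optional[dict[DiscLevel, float]] = None

    @field_validator("gravity_factor")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"gravity_factor must be >= 0, got {v}")
        return v

    @field_validator("joint_angles")
    @classmethod
    def _known_finite(cls, v: dict[str, float]) -> dict[str, float]:
        for name, angle in v.items():
            if name not in JOINT_ANGLE_NAMES:
                raise ValueError(f"unknown joint angle {name!r}")
            if not math.isfinite(angle):
                raise ValueError(f"joint angle {name} must be finite, got {angle}")
        return v

    def angle(self, name: str) -> float:
        """Joint angle in degrees; unspecified angles default to 0."""
        return self.joint_angles.get(name, 0.0)

    def tilt(self, level: DiscLevel) -> float:
        """Sagittal tilt (deg, anterior positive) of a disc level.

        Baseline lordosis tilt, overridden by ``cervical_tilt_per_level``,
        plus the neck flexion angle applied uniformly to every level.
        """
        base = (self.cervical_tilt_per_level or DEFAULT_LORDOSIS_TILT)[level]
        return base + self.angle("neck_flexion")


def load_scenario(source: str | Path) -> PostureScenario:
    """Read a posture scenario from YAML."""
    with open(source, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw.get("cervical_tilt_per_level"):
        raw["cervical_tilt_per_level"] = {
            DiscLevel(k): float(v) for k, v in raw["cervical_tilt_per_level"].items()
        }
    return PostureScenario(**raw)


def packaged_scenario(name: str) -> PostureScenario:
    """One of the packaged study postures: nbp1g, sm0g or nbp0g."""
    return load_scenario(data_path(f"scenarios/{name}.yaml"))


class Anthropometry(BaseModel):
    """Segment masses and geometry of the modeled subject.

    Mass fractions follow standard adult segment-inertia tables (head+neck
    roughly 6.9% of body mass); cervical soft tissue is distributed in small
    per-level increments so supported weight grows cranio-caudally.
    """

    model_config = ConfigDict(frozen=True)

    total_mass: float = 72.0  # kg
    head_mass_fraction: float = 0.0694
    cervical_segment_mass_fractions: dict[DiscLevel, float] = {
        lv: 0.0015 for lv in LEVELS
    }
    segment_lengths: dict[DiscLevel, float] = {lv: 17.0 for lv in LEVELS}  # mm
    head_com_height: float = 120.0  # mm above the C2-C3 disc
    com_anterior_offset: float = 20.0  # mm, supported-mass CoM ahead of the axis
    extensor_moment_arm: float = 40.0  # mm

    @field_validator("total_mass", "extensor_moment_arm", "head_com_height")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @model_validator(mode="after")
    def _fractions(self) -> "Anthropometry":
        if not 0 < self.head_mass_fraction < 1:
            raise ValueError("head_mass_fraction must lie in (0, 1)")
        for lv, f in self.cervical_segment_mass_fractions.items():
            if not 0 < f < 1:
                raise ValueError(f"mass fraction for {lv} must lie in (0, 1)")
        return self

    def supported_mass(self, level: DiscLevel) -> float:
        """Mass (kg) above a disc level: head plus cervical segments above it."""
        mass = self.head_mass_fraction * self.total_mass
        for lv in LEVELS:
            if lv.index >= level.index:
                break
            mass += self.cervical_segment_mass_fractions[lv] * self.total_mass
        return mass

    def com_height(self, level: DiscLevel) -> float:
        """Height (mm) of the supported-mass CoM above a disc level."""
        height = self.head_com_height
        for lv in LEVELS:
            if lv.index >= level.index:
                break
            height += self.segment_lengths[lv]
        return height


def supported_weight(level: DiscLevel, anthro: Anthropometry, gravity_factor: float) -> float:
    """Weight (N) carried by a disc level under the given gravity factor."""
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    return gravity_factor * G0 * anthro.supported_mass(level)


def disc_loads(
    scenario: PostureScenario,
    anthro: Anthropometry | None = None,
    muscle_cocontraction: float = 30.0,
    include_extensor: bool = True,
) -> list[DiscLoad]:
    """Per-level compression and sagittal shear (N) for a posture.

    Compression = W cos(tilt) + extensor force + co-contraction offset,
    shear = -W sin(tilt) (anterior negative). The extensor force balances
    the gravitational flexion moment W * d about the level, where the CoM
    lever arm d combines a fixed anterior offset with the forward lean of
    the supported column, divided by the extensor moment arm.

    ``muscle_cocontraction`` (N) is an explicit tuning constant standing in
    for baseline muscle tone; set it and ``include_extensor=False`` to
    recover the pure gravity resolution (compression^2 + shear^2 = W^2).
    """
    anthro = anthro or Anthropometry()
    flexion = scenario.angle("neck_flexion")
    out = []
    for level in LEVELS:
        w = supported_weight(level, anthro, scenario.gravity_factor)
        theta = math.radians(scenario.tilt(level))
        compression = w * math.cos(theta)
        shear = -w * math.sin(theta)
        if include_extensor:
            lever = anthro.com_anterior_offset + anthro.com_height(level) * math.sin(
                math.radians(flexion)
            )
            compression += w * lever / anthro.extensor_moment_arm
        compression += muscle_cocontraction
        out.append(
            DiscLoad(level=level, scenario=scenario.name, compression=compression, shear=shear)
        )
    return out
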
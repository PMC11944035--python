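"""YAML-backed pipeline configuration.

Keys mirror the physical structure: ``osmotic`` (gas constant, temperature,
bath concentration), ``disc`` (NP reference FCD, NP area fraction, AF/NP
FCD ratio), ``solver`` (tolerance, iteration cap, which area enters the
load balance) and ``loading`` (body mass, co-contraction offset).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict

from .disc import (
    DEFAULT_C0F_NP,
    DEFAULT_FCD_RATIO_AF_NP,
    DEFAULT_NP_AREA_FRACTION,
    DiscReference,
    load_reference_table,
)
from .swelling import OsmoticConstants


class OsmoticConfig(BaseModel):
    model_config = ConfigDict(frozen=True)
    R: float = 8.3144
    T_kelvin: float = 310.15
    c_star_mM: float = 150.0


class DiscConfig(BaseModel):
    model_config = ConfigDict(frozen=True)
    c0F_NP_mM: float = DEFAULT_C0F_NP
    np_area_fraction: float = DEFAULT_NP_AREA_FRACTION
    fcd_ratio_af_np: float = DEFAULT_FCD_RATIO_AF_NP


class SolverConfig(BaseModel):
    model_config = ConfigDict(frozen=True)
    tol: float = 1e-10
    max_iter: int = 200
    #: which cross-sectional area enters the load balance; the deformed area
    #: is an independent observable in the reference tables, so 'reference'
    #: is the default and 'deformed' is reserved for sensitivity studies.
    area_mode: Literal["reference", "deformed"] = "reference"


class LoadingConfig(BaseModel):
    model_config = ConfigDict(frozen=True)
    total_mass_kg: float = 72.0
    muscle_cocontraction_N: float = 30.0


class AppConfig(BaseModel):
    model_config = ConfigDict(frozen=True)
    osmotic: OsmoticConfig = OsmoticConfig()
    disc: DiscConfig = DiscConfig()
    solver: SolverConfig = SolverConfig()
    loading: LoadingConfig = LoadingConfig()

    def constants(self) -> OsmoticConstants:
        return OsmoticConstants(R=self.osmotic.R, T=self.osmotic.T_kelvin, c_star=self.osmotic.c_star_mM)

    def references(self) -> list[DiscReference]:
        return load_reference_table(
            np_area_fraction=self.disc.np_area_fraction,
            fcd_ratio_AF_NP=self.disc.fcd_ratio_af_np,
            c0F_NP=self.disc.c0F_NP_mM,
        )

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run metadata."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> AppConfig:
    """Load configuration from YAML; defaults when no path is given."""
    if path is None:
        return AppConfig()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return AppConfig(**raw)
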
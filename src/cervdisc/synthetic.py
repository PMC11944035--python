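"""Synthetic study inputs and parameter recovery.

Generators for (i) perturbed per-level disc parameter populations, (ii)
random admissible postures, (iii) random axial load profiles and (iv) noisy
NP/AF water-content observations under the swelling model — everything the
pipeline consumes, reproducible from a single integer seed with no global
random state. Plus a calibration routine that recovers the unmeasured NP
reference fixed charge density from (load, water content) observations.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator
from scipy.optimize import minimize_scalar

from .disc import DiscLevel, DiscReference
from .loading import JOINT_ANGLE_NAMES, PostureScenario
from .swelling import OsmoticConstants, partition_water_content, solve_equilibrium_many


class GeneratorConfig(BaseModel):
    """Knobs of the synthetic-input generators.

    cv_geometry: coefficient of variation of the lognormal factors applied
    to reference area and height (5% is a plausible inter-subject spread).
    noise_sd_phi: SD of Gaussian observation noise on water fractions
    (0.005 ~ half a percentage point, the precision of the reference tables).
    load_range: admissible axial forces, N.
    """

    model_config = ConfigDict(frozen=True)

    seed: int
    n_subjects: int = 10
    cv_geometry: float = 0.05
    noise_sd_phi: float = 0.005
    load_range: tuple[float, float] = (20.0, 180.0)

    @field_validator("cv_geometry", "noise_sd_phi")
    @classmethod
    def _nonneg(cls, v: float, info) -> float:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-median-free, unit-*mean* multiplicative factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def make_disc_population(
    config: GeneratorConfig,
    base: Sequence[DiscReference] | None = None,
) -> list[list[DiscReference]]:
    """Perturbed per-subject copies of the reference disc parameter table.

    Area and height are multiplied by independent lognormal factors with the
    configured CV (lognormal keeps them positive, so the reference-table
    invariants survive any draw); water fractions are left at their
    reference values.
    """
    from .disc import load_reference_table

    base = list(base) if base is not None else load_reference_table()
    rng = np.random.default_rng(config.seed)
    subjects = []
    for _ in range(config.n_subjects):
        fa = _lognormal_factors(rng, config.cv_geometry, len(base))
        fh = _lognormal_factors(rng, config.cv_geometry, len(base))
        subjects.append(
            [
                ref.model_copy(update={"A0": ref.A0 * fa[i], "h0": ref.h0 * fh[i]})
                for i, ref in enumerate(base)
            ]
        )
    return subjects


def make_random_postures(
    config: GeneratorConfig, n: int | None = None
) -> list[PostureScenario]:
    """Random admissible postures: angles within +/-90 deg, gravity 0 or 1."""
    rng = np.random.default_rng(config.seed)
    n = n if n is not None else config.n_subjects
    postures = []
    for i in range(n):
        angles = {
            name: float(rng.uniform(-90.0, 90.0)) for name in JOINT_ANGLE_NAMES
        }
        angles["neck_flexion"] = float(rng.uniform(0.0, 45.0))
        postures.append(
            PostureScenario(
                name=f"random_{i}",
                gravity_factor=float(rng.integers(0, 2)),
                joint_angles=angles,
            )
        )
    return postures


def random_loads(config: GeneratorConfig, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform random axial loads (N) inside the configured range."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.load_range
    return rng.uniform(lo, hi, size=n)


def simulate_observed_phi(
    ref: DiscReference,
    r_true: float | np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy NP/AF water-fraction observations at true height ratio(s).

    Gaussian noise is added to the model water fractions; draws falling
    outside (0, 1) are resampled (not clipped) so no probability mass piles
    up at the boundaries.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi_np, phi_af, _ = partition_water_content(np.asarray(r_true, dtype=float), ref)
    obs = []
    for clean in (np.atleast_1d(phi_np), np.atleast_1d(phi_af)):
        draw = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean.copy()
        bad = (draw <= 0.0) | (draw >= 1.0)
        while np.any(bad):
            draw[bad] = clean[bad] + rng.normal(0.0, noise_sd, size=int(bad.sum()))
            bad = (draw <= 0.0) | (draw >= 1.0)
        obs.append(draw)
    return obs[0], obs[1]


def recover_c0F(
    loads: np.ndarray,
    phi_np_obs: np.ndarray,
    phi_af_obs: Optional[np.ndarray],
    ref: DiscReference,
    constants: OsmoticConstants | None = None,
    bounds: tuple[float, float] = (20.0, 1000.0),
) -> float:
    """Least-squares estimate of the NP reference fixed charge density.

    For a candidate c0F, each observed load is pushed through the
    equilibrium solver to a predicted height ratio and hence predicted
    NP/AF water fractions; the candidate minimizing the summed squared
    water-fraction error over a bracketed scalar search is returned.
    The map c0F -> phi at fixed load is strictly monotone, so the estimate
    is unique. Raises ``ValueError`` for non-identifiable input (no loads,
    or all loads zero).
    """
    constants = constants or OsmoticConstants()
    loads = np.asarray(loads, dtype=float)
    phi_np_obs = np.asarray(phi_np_obs, dtype=float)
    if loads.size == 0:
        raise ValueError("at least one (load, water content) pair is required")
    if np.all(loads == 0.0):
        raise ValueError(
            "all loads are zero: the free-swelling state carries no information "
            "about the fixed charge density"
        )

    def sse(c0F: float) -> float:
        cand = ref.model_copy(update={"c0F_NP": float(c0F)})
        r = solve_equilibrium_many(loads, cand, constants)
        phi_np, phi_af, _ = partition_water_content(r, cand)
        err = np.sum((phi_np - phi_np_obs) ** 2)
        if phi_af_obs is not None:
            err += np.sum((phi_af - np.asarray(phi_af_obs, dtype=float)) ** 2)
        return float(err)

    res = minimize_scalar(sse, bounds=bounds, method="bounded", options={"xatol": 1e-4})
    return float(res.x)
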
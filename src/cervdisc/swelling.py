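"""Donnan swelling model of the intervertebral disc and its load-height
equilibrium.

The disc matrix carries fixed negative charges (glycosaminoglycans). At a
reference height ``h0`` the nucleus pulposus holds a fixed charge density
``c0F`` at water fraction ``phi0``. Axial deformation to height ``h`` scales
the tissue volume by ``r^3`` with ``r = h/h0`` (isotropic volume bookkeeping
on the lumped element), so the water volume changes by ``r^3 - 1`` and the
fixed charges dilute:

    cF(r) = c0F * phi0 / (phi0 + r^3 - 1)

Against a bath of monovalent salt at concentration ``c*``, ideal Donnan
equilibrium gives the swelling pressure

    Fs(r) = R * T * (sqrt(cF^2 + 4 c*^2) - 2 c*)

which vanishes as cF -> 0 and grows linearly with cF in the high-FCD limit.
The deformed water fraction follows from the same volume bookkeeping:

    phi(r) = (phi0 + r^3 - 1) / r^3

NP and AF share one height ratio (single rigid endplate); the disc-level
pressure and water fraction are area-weighted mixtures of the two
compartments (NP fraction 0.4 by default, AF fixed charge 0.8x NP).

At equilibrium the swelling pressure over the reference area balances the
applied axial force; because ``Fs`` is strictly decreasing in ``r`` the
balance has a unique root, found by bracketed bisection.

Interface units: mm/mm^2 for geometry, kPa for pressure, mol m^-3 (= mM)
for concentrations, N for force. The gas-law product R*T*c is evaluated in
SI (Pa) and converted once at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .disc import DiscReference, DomainError

__all__ = [
    "OsmoticConstants",
    "EquilibriumSolution",
    "BracketingError",
    "fixed_charge_density",
    "donnan_pressure",
    "deformed_water_content",
    "height_ratio_from_water_content",
    "partition_water_content",
    "disc_swelling_stress",
    "attainable_force_range",
    "solve_equilibrium",
    "solve_equilibrium_many",
]

#: kPa * mm^2 -> N
_KPA_MM2_TO_N = 1e-3


class OsmoticConstants(BaseModel):
    """Physical constants of the Donnan model.

    R: universal gas constant, J K^-1 mol^-1.
    T: absolute temperature, K (body temperature by default).
    c_star: external Na+/Cl- bath concentration, mol/m^3.
    """

    model_config = ConfigDict(frozen=True)

    R: float = 8.3144
    T: float = 310.15
    c_star: float = 150.0

    @field_validator("R", "T", "c_star")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v


@dataclass(frozen=True)
class EquilibriumSolution:
    """Result of a load-height equilibrium solve."""

    r: float  #: equilibrium height ratio h/h0
    Fs: float  #: swelling pressure at r, kPa
    residual: float  #: |Fs * A0 - F_applied|, N
    iterations: int


class BracketingError(DomainError):
    """The applied force lies outside the pressures attainable in the bracket."""


def _r_min(phi0: float) -> float:
    """Lower height-ratio bound: deformed water volume must stay positive."""
    return (1.0 - phi0) ** (1.0 / 3.0)


def fixed_charge_density(c0F: float, phi0: float, r):
    """Fixed charge density (mol/m^3) after deformation to height ratio ``r``.

    Dilution law ``c0F * phi0 / (phi0 + r^3 - 1)``; strictly decreasing in r.
    Requires ``r^3 > 1 - phi0`` so the deformed water volume is positive.
    """
    r = np.asarray(r, dtype=float)
    water = phi0 + r**3 - 1.0
    if np.any(water <= 0):
        raise DomainError(
            f"height ratio must exceed (1 - phi0)^(1/3) = {_r_min(phi0):.6f}; "
            f"got r={r}"
        )
    out = c0F * phi0 / water
    return float(out) if out.ndim == 0 else out


def donnan_pressure(cF, constants: OsmoticConstants | None = None):
    """Ideal Donnan swelling pressure (kPa) at fixed charge density ``cF``.

    ``R*T*(sqrt(cF^2 + 4 c*^2) - 2 c*)``: zero at cF=0, strictly increasing,
    asymptotically ``R*T*cF`` for cF >> c*.
    """
    constants = constants or OsmoticConstants()
    cF = np.asarray(cF, dtype=float)
    if np.any(cF < 0):
        raise DomainError(f"fixed charge density must be nonnegative, got {cF}")
    pa = constants.R * constants.T * (np.sqrt(cF**2 + 4.0 * constants.c_star**2) - 2.0 * constants.c_star)
    out = pa / 1e3
    return float(out) if out.ndim == 0 else out


def deformed_water_content(phi0: float, r):
    """Water fraction after deformation to height ratio ``r`` (volume bookkeeping).

    ``(phi0 + r^3 - 1)/r^3``: equals phi0 at r=1, increases toward 1 as the
    disc swells. Requires ``r^3 > 1 - phi0``.
    """
    r = np.asarray(r, dtype=float)
    water = phi0 + r**3 - 1.0
    if np.any(water <= 0):
        raise DomainError(
            f"height ratio must exceed (1 - phi0)^(1/3) = {_r_min(phi0):.6f}; "
            f"got r={r}"
        )
    out = water / r**3
    return float(out) if out.ndim == 0 else out


def height_ratio_from_water_content(phi, phi0: float):
    """Invert the water-content update: r = ((1 - phi0)/(1 - phi))^(1/3)."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi >= 1.0) or np.any(phi <= 0.0):
        raise DomainError(f"water fraction must lie in (0, 1), got {phi}")
    out = ((1.0 - phi0) / (1.0 - phi)) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def partition_water_content(r, ref: DiscReference):
    """NP, AF and combined water fractions at height ratio ``r``.

    The combined fraction is the NP-area-weighted mixture, which (exactly,
    by linearity of the volume bookkeeping) equals applying the update to
    the mixed reference fraction.
    """
    phi_np = deformed_water_content(ref.phi0_NP, r)
    phi_af = deformed_water_content(ref.phi0_AF, r)
    f = ref.np_area_fraction
    return phi_np, phi_af, f * phi_np + (1.0 - f) * phi_af


def disc_swelling_stress(r, ref: DiscReference, constants: OsmoticConstants | None = None):
    """Area-weighted disc swelling pressure (kPa) at height ratio ``r``.

    NP and AF contribute through their own reference water fractions and
    fixed charge densities (AF FCD = fcd_ratio_AF_NP * NP FCD); strictly
    decreasing in r.
    """
    constants = constants or OsmoticConstants()
    cF_np = fixed_charge_density(ref.c0F_NP, ref.phi0_NP, r)
    cF_af = fixed_charge_density(ref.fcd_ratio_AF_NP * ref.c0F_NP, ref.phi0_AF, r)
    f = ref.np_area_fraction
    return f * donnan_pressure(cF_np, constants) + (1.0 - f) * donnan_pressure(cF_af, constants)


def _default_bracket(ref: DiscReference) -> tuple[float, float]:
    # AF has the smaller reference water fraction, hence the larger r_min.
    lo = _r_min(min(ref.phi0_NP, ref.phi0_AF)) * (1.0 + 1e-6)
    return lo, 3.0


def attainable_force_range(
    ref: DiscReference,
    constants: OsmoticConstants | None = None,
    bracket: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """(F_min, F_max) in N attainable over the solver bracket.

    F_min is the residual swelling force at the upper bracket edge (the
    free-swelling asymptote Fs -> 0 is approached but never reached at
    finite r), F_max the force at the compressed edge.
    """
    lo, hi = bracket or _default_bracket(ref)
    f_hi = disc_swelling_stress(hi, ref, constants) * ref.A0 * _KPA_MM2_TO_N
    f_lo = disc_swelling_stress(lo, ref, constants) * ref.A0 * _KPA_MM2_TO_N
    return f_hi, f_lo


def solve_equilibrium(
    F_applied: float,
    ref: DiscReference,
    constants: OsmoticConstants | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
    bracket: tuple[float, float] | None = None,
) -> EquilibriumSolution:
    """Height ratio at which swelling pressure balances the applied axial force.

    Solves ``Fs(r) * A0 = F_applied`` for ``r`` by bisection on the strictly
    monotone residual; the balance uses the reference area A0 (the deformed
    area is an independent observable and does not enter). ``tol`` is
    relative to ``max(F_applied, 1 N)``.

    Raises :class:`BracketingError` when ``F_applied`` lies outside the
    attainable range — in particular for F=0, where free swelling only
    reaches equilibrium in the r -> infinity asymptote.
    """
    constants = constants or OsmoticConstants()
    lo, hi = bracket or _default_bracket(ref)
    f_min, f_max = attainable_force_range(ref, constants, (lo, hi))
    if not (f_min < F_applied < f_max):
        raise BracketingError(
            f"applied force {F_applied} N is outside the attainable range "
            f"({f_min:.6g}, {f_max:.6g}) N for r in ({lo:.6g}, {hi:.6g}); "
            "zero load corresponds to the free-swelling asymptote r -> inf"
        )

    def residual(r: float) -> float:
        return disc_swelling_stress(r, ref, constants) * ref.A0 * _KPA_MM2_TO_N - F_applied

    scale = max(abs(F_applied), 1.0)
    a, b = lo, hi  # residual(a) > 0 > residual(b)
    mid = 0.5 * (a + b)
    res = residual(mid)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        mid = 0.5 * (a + b)
        res = residual(mid)
        if abs(res) <= tol * scale or (b - a) < 1e-15:
            break
        if res > 0:
            a = mid
        else:
            b = mid
    return EquilibriumSolution(
        r=mid,
        Fs=disc_swelling_stress(mid, ref, constants),
        residual=abs(res),
        iterations=iterations,
    )


def solve_equilibrium_many(
    F_applied: np.ndarray,
    ref: DiscReference,
    constants: OsmoticConstants | None = None,
    n_iter: int = 80,
    bracket: tuple[float, float] | None = None,
) -> np.ndarray:
    """Vectorized equilibrium solve for an array of axial forces (N).

    Fixed-count bisection (80 halvings shrink the bracket below 1e-23), used
    by calibration and Monte-Carlo code paths where many solves are needed.
    """
    constants = constants or OsmoticConstants()
    F = np.asarray(F_applied, dtype=float)
    lo_edge, hi_edge = bracket or _default_bracket(ref)
    f_min, f_max = attainable_force_range(ref, constants, (lo_edge, hi_edge))
    if np.any(F <= f_min) or np.any(F >= f_max):
        raise BracketingError(
            f"forces must lie strictly inside the attainable range "
            f"({f_min:.6g}, {f_max:.6g}) N"
        )
    lo = np.full(F.shape, lo_edge)
    hi = np.full(F.shape, hi_edge)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        res = disc_swelling_stress(mid, ref, constants) * ref.A0 * _KPA_MM2_TO_N - F
        too_stiff = res > 0  # pressure still exceeds load: move toward larger r
        lo = np.where(too_stiff, mid, lo)
        hi = np.where(too_stiff, hi, mid)
    return 0.5 * (lo + hi)
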
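"""Sedimentation trapping and critical-flow operating windows.

A non-adherent spherical tissue settles into a square-section trap under an
effective volume force (gravity by default).  Confinement by the trap walls
increases Stokes drag by a factor K(d/w) — the classical wall-corrected
solution for a sphere settling along the axis of a long cylinder — which
slows settling and shapes an optimum trap-to-tissue size ratio.

Once trapped, applying a channel flow rate Q exposes the tissue to two
competing thresholds:

* ``Q_shear``: the flow at which the maximum wall shear stress on the
  tissue reaches the damage threshold tau_max (~1 Pa physiologically);
  scales as w^3 for a cubic trap at d/w = 0.5.
* ``Q_lift``: the flow whose hydrodynamic lift balances net weight and
  ejects a non-adherent tissue; scales as sqrt(d) w^2.

Because Q_shear falls faster than Q_lift as a device is scaled down, there
is a minimum trap width w_min below which flow damages tissues before it
can eject them.  ``operating_window`` packages these thresholds and
classifies any applied flow rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .params import MediumProperties, TissueSample, TrapGeometry

__all__ = [
    "NonSettlingError",
    "ModelValidityWarning",
    "SettlingResult",
    "OperatingWindow",
    "LAMBDA_MAX",
    "stokes_settling_velocity",
    "wall_correction_factor",
    "settling_velocity",
    "settling_time",
    "settling_result",
    "optimal_trap_ratio",
    "critical_shear_flow",
    "critical_lift_flow",
    "minimum_trap_width",
    "operating_window",
    "TAU_MAX_DEFAULT",
]

#: physiological shear-damage threshold, Pa
TAU_MAX_DEFAULT = 1.0

#: validity limit of the wall-correction polynomial fit
LAMBDA_MAX = 0.9

#: empirical prefactor linking channel flow to peak shear on the trapped
#: tissue for a cubic trap at d/w = 0.5 (fit to 3D flow simulations)
SHEAR_PREFACTOR = 9.6

#: exact prefactor of the minimum-width formula, (2/3) * 9.6^2 = 61.44:
#: the width at which the shear and lift critical-flow curves cross with
#: d = w/2 (commonly quoted rounded to 61)
MIN_WIDTH_PREFACTOR = (2.0 / 3.0) * SHEAR_PREFACTOR**2


class NonSettlingError(ValueError):
    """Tissue is not denser than the medium: no finite settling time."""


class ModelValidityWarning(UserWarning):
    """A closed-form model is being used outside its fitted regime."""


@dataclass(frozen=True)
class SettlingResult:
    """Settling kinematics of one tissue/trap pairing."""

    v_stokes: float   # unconfined Stokes velocity, m/s
    K: float          # wall-correction drag factor, dimensionless
    v_set: float      # confined settling velocity, m/s
    t_settle: float   # time to settle over the trap depth, s


def stokes_settling_velocity(tissue: TissueSample, medium: MediumProperties) -> float:
    """Unconfined Stokes settling velocity (1/18)(drho/eta) g_eff d^2, m/s."""
    drho = tissue.rho_T - medium.rho_M
    if drho <= 0:
        raise NonSettlingError(
            f"tissue density {tissue.rho_T} kg/m^3 does not exceed medium "
            f"density {medium.rho_M} kg/m^3: sample does not settle"
        )
    return drho * medium.g_eff * tissue.d**2 / (18.0 * medium.eta)


def wall_correction_factor(lam: float) -> float:
    """Drag-enhancement factor K(lambda) for a sphere settling in a
    square-section well, lambda = d/w.

    K(0) = 1 (unconfined) and K grows monotonically with confinement; the
    rational polynomial fit is valid for lambda < 0.9.
    """
    if lam < 0:
        raise ValueError(f"confinement ratio must be non-negative, got {lam}")
    if lam >= LAMBDA_MAX:
        raise ValueError(
            f"confinement ratio {lam:.3g} >= {LAMBDA_MAX}: outside the "
            "validity of the wall-correction polynomial"
        )
    num = 1.0 - 0.76 * lam**5
    den = 1.0 - 2.1 * lam + 2.1 * lam**3 - 1.7 * lam**5 + 0.73 * lam**6
    return num / den


def settling_velocity(
    tissue: TissueSample, trap: TrapGeometry, medium: MediumProperties
) -> float:
    """Wall-corrected settling velocity v_stokes / K(d/w), m/s.

    Confinement increases drag, so the confined velocity is the Stokes
    velocity divided by the drag factor K.
    """
    lam = tissue.d / trap.w
    return stokes_settling_velocity(tissue, medium) / wall_correction_factor(lam)


def settling_time(
    tissue: TissueSample, trap: TrapGeometry, medium: MediumProperties
) -> float:
    """Upper bound on trapping time: trap depth / confined velocity, s.

    Bottom-wall retardation is neglected, which is why this bounds the
    experimental sedimentation time from above only loosely near contact.
    """
    return trap.h / settling_velocity(tissue, trap, medium)


def settling_result(
    tissue: TissueSample, trap: TrapGeometry, medium: MediumProperties
) -> SettlingResult:
    """Bundle Stokes velocity, drag factor, confined velocity and time."""
    v0 = stokes_settling_velocity(tissue, medium)
    K = wall_correction_factor(tissue.d / trap.w)
    v = v0 / K
    return SettlingResult(v_stokes=v0, K=K, v_set=v, t_settle=trap.h / v)


def optimal_trap_ratio(
    bracket: tuple[float, float] = (0.05, LAMBDA_MAX - 1e-6),
    grid_points: int = 2000,
) -> float:
    """Confinement ratio d/w minimizing settling time for a square trap
    with w = h fixed and tissue size varying.

    Settling time scales as K(lambda)/lambda^2 (small tissues settle slowly
    for lack of weight, large ones for excess drag), so the minimizer is a
    pure property of the drag polynomial — independent of trap size,
    density contrast and viscosity.  Found by coarse grid scan plus local
    bounded refinement.
    """
    lo, hi = bracket
    if not (0 < lo < hi < LAMBDA_MAX):
        raise ValueError(f"bracket {bracket} must lie inside (0, {LAMBDA_MAX})")

    def objective(lam: float) -> float:
        return wall_correction_factor(lam) / lam**2

    grid = np.linspace(lo, hi, grid_points)
    values = [objective(x) for x in grid]
    i = int(np.argmin(values))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_points - 1)]
    res = minimize_scalar(objective, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def _warn_if_outside_cubic_regime(
    trap: TrapGeometry, tissue: TissueSample | None = None
) -> None:
    if not math.isclose(trap.h, trap.w, rel_tol=0.25):
        warnings.warn(
            f"critical-flow formulas were fitted for a cubic trap (h = w); "
            f"got h/w = {trap.h / trap.w:.2f}",
            ModelValidityWarning,
            stacklevel=3,
        )
    if tissue is not None:
        lam = tissue.d / trap.w
        if not (0.4 <= lam <= 0.6):
            warnings.warn(
                f"critical-flow formulas were fitted at d/w = 0.5; got "
                f"d/w = {lam:.2f}",
                ModelValidityWarning,
                stacklevel=3,
            )


def critical_shear_flow(
    trap: TrapGeometry,
    medium: MediumProperties,
    tau_max: float = TAU_MAX_DEFAULT,
) -> float:
    """Channel flow rate at which peak shear on the tissue reaches tau_max.

    Q_shear = tau_max w^3 / (9.6 eta); valid for a cubic trap holding a
    tissue at d/w = 0.5 (warned otherwise).  Returns m^3/s.
    """
    if tau_max <= 0:
        raise ValueError(f"shear threshold must be positive, got {tau_max}")
    _warn_if_outside_cubic_regime(trap)
    return tau_max * trap.w**3 / (SHEAR_PREFACTOR * medium.eta)


def critical_lift_flow(
    tissue: TissueSample, trap: TrapGeometry, medium: MediumProperties
) -> float:
    """Minimum flow rate ejecting a non-adherent trapped tissue, m^3/s.

    Q_lift = sqrt(d) w^2 sqrt((4/3) g_eff (rho_T/rho_M - 1)).  Partially
    adherent tissues need more; this is the conservative lower threshold.
    """
    ratio = tissue.rho_T / medium.rho_M
    if ratio <= 1:
        raise NonSettlingError(
            "tissue is not denser than the medium: it is never held down, "
            "so no finite lift threshold exists"
        )
    _warn_if_outside_cubic_regime(trap, tissue)
    return (
        math.sqrt(tissue.d)
        * trap.w**2
        * math.sqrt((4.0 / 3.0) * medium.g_eff * (ratio - 1.0))
    )


def minimum_trap_width(
    medium: MediumProperties,
    density_ratio: float,
    tau_max: float = TAU_MAX_DEFAULT,
) -> float:
    """Trap width at which Q_shear = Q_lift (with d = w/2), m.

    w_min = 61.44 g_eff eta^2 (rho_T/rho_M - 1) / tau_max^2, the exact
    crossing of the two critical-flow curves (the prefactor is often
    quoted rounded to 61).  Below this width, shear reaches tau_max
    before the tissue can be lifted out, so flow cannot safely eject
    samples.
    """
    if tau_max <= 0:
        raise ValueError(f"shear threshold must be positive, got {tau_max}")
    if density_ratio <= 1:
        raise NonSettlingError(
            f"density ratio {density_ratio} must exceed 1 for a settling sample"
        )
    return (MIN_WIDTH_PREFACTOR * medium.g_eff * medium.eta**2
            * (density_ratio - 1.0) / tau_max**2)


@dataclass(frozen=True)
class OperatingWindow:
    """Critical flow rates for one tissue/trap pairing.

    ``has_safe_ejection`` is true when Q_lift < Q_shear, i.e. a flow range
    exists that ejects the tissue before shear becomes damaging.
    """

    Q_lift: float
    Q_shear: float

    @property
    def has_safe_ejection(self) -> bool:
        return self.Q_lift < self.Q_shear

    def regime(self, Q: float) -> str:
        """Classify an applied flow rate Q (m^3/s).

        Returns ``trapped_safe``, ``ejected_safe`` or ``damaging``.  The
        Q_shear boundary itself counts as damaging (conservative); when no
        safe-ejection window exists every flow at or above Q_shear is
        damaging before ejection.
        """
        if Q < 0:
            raise ValueError(f"flow rate must be non-negative, got {Q}")
        if Q >= self.Q_shear:
            return "damaging"
        if self.has_safe_ejection and Q >= self.Q_lift:
            return "ejected_safe"
        return "trapped_safe"


def operating_window(
    tissue: TissueSample,
    trap: TrapGeometry,
    medium: MediumProperties,
    tau_max: float = TAU_MAX_DEFAULT,
) -> OperatingWindow:
    """Compute both critical flows and package the regime classifier."""
    return OperatingWindow(
        Q_lift=critical_lift_flow(tissue, trap, medium),
        Q_shear=critical_shear_flow(trap, medium, tau_max),
    )
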
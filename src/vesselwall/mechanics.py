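"""Biaxial kinematics and wall stresses for a thin-walled, incompressible artery.

The artery is treated as an incompressible thin-walled cylinder inflated at a
fixed axial stretch λz.  Given the deformed outer diameter d_o, the deformed
inner diameter follows from conservation of wall volume,

    d_i = sqrt(d_o² − (D_o² − D_i²)/λz),

and the mean biaxial Cauchy stresses from equilibrium of the pressurised tube,

    σθ = P·r_i / h,
    σz = (f + P·π·r_i²) / (π·h·(2·r_i + h)),

with P the transmural pressure, r_i the deformed inner radius, h the deformed
wall thickness and f the measured axial force.  Stresses are reported in kPa,
tangent moduli in MPa.

The *in vivo* axial stretch is estimated as the stretch at which the axial
force is invariant under pressurisation: per-sweep slopes of f vs P are
interpolated across λz to find the zero crossing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import MMHG_TO_KPA, GeometryError, PressureSweep, RingGeometry, ValidationError

__all__ = [
    "AdmissibilityError",
    "DeformedState",
    "StressState",
    "InVivoStretchResult",
    "MechanicsResult",
    "deformed_inner_diameter",
    "cauchy_stresses",
    "circumferential_stretch",
    "estimate_in_vivo_stretch",
    "tangent_modulus_theta",
    "process_sweep",
]

# mN -> kPa·µm² (1 mN = 1e-3 N; 1 kPa·µm² = 1e3 N/m² · 1e-12 m² = 1e-9 N)
_MN_TO_KPA_UM2 = 1e6


class AdmissibilityError(ValueError):
    """A load point is incompatible with incompressible kinematics."""


@dataclass(frozen=True)
class DeformedState:
    """Kinematics of the wall at one load point.  Lengths µm, pressure kPa."""

    P: float  # transmural pressure, kPa
    d_o: float
    d_i: float
    lambda_z: float
    lambda_theta: float

    @property
    def r_i(self) -> float:
        return self.d_i / 2.0

    @property
    def r_o(self) -> float:
        return self.d_o / 2.0

    @property
    def h(self) -> float:
        return (self.d_o - self.d_i) / 2.0

    @property
    def lambda_r(self) -> float:
        """Radial stretch from incompressibility, λr = 1/(λθ·λz)."""
        return 1.0 / (self.lambda_theta * self.lambda_z)


@dataclass(frozen=True)
class StressState:
    """Mean biaxial Cauchy stresses (kPa) and the axial force (mN) at one load point."""

    sigma_theta: float
    sigma_z: float
    f: float


@dataclass
class InVivoStretchResult:
    """In vivo axial stretch estimate with per-sweep diagnostics."""

    lambda_iv: float
    slopes: np.ndarray  # mN/mmHg, one per sweep
    stretches: np.ndarray  # λz, one per sweep
    residual: float  # |interpolated slope| at lambda_iv, mN/mmHg
    no_sign_change: bool = False


@dataclass
class MechanicsResult:
    """Per-pressure kinematics/stresses for one sweep plus derived scalars."""

    sweep: PressureSweep
    states: list[DeformedState]
    stresses: list[StressState]
    reference_pressure: float  # mmHg (MAP)
    lambda_theta_at_reference: float
    tangent_modulus_theta: float  # MPa
    flags: list[str] = field(default_factory=list)

    @property
    def sigma_theta(self) -> np.ndarray:
        return np.array([s.sigma_theta for s in self.stresses])

    @property
    def sigma_z(self) -> np.ndarray:
        return np.array([s.sigma_z for s in self.stresses])

    @property
    def lambda_theta(self) -> np.ndarray:
        return np.array([s.lambda_theta for s in self.states])


def deformed_inner_diameter(
    d_o: float, D_o: float, D_i: float, lambda_z: float
) -> float:
    """Deformed inner diameter of an incompressible wall (all lengths µm).

    Solves volume conservation of the tube wall for d_i:
    ``d_i = sqrt(d_o² − (D_o² − D_i²)/λz)``.

    Raises
    ------
    AdmissibilityError
        If the radicand is negative, i.e. the observed d_o is smaller than an
        incompressible wall allows at this λz.
    """
    radicand = d_o**2 - (D_o**2 - D_i**2) / lambda_z
    if radicand < 0:
        raise AdmissibilityError(
            f"inadmissible load point: d_o={d_o:.6g} µm with D_o={D_o:.6g}, "
            f"D_i={D_i:.6g}, λz={lambda_z:.6g} gives negative d_i²={radicand:.6g}"
        )
    return math.sqrt(radicand)


def cauchy_stresses(P_kpa: float, f_mn: float, r_i: float, h: float) -> StressState:
    """Mean biaxial Cauchy stresses of a pressurised thin-walled tube.

    Parameters
    ----------
    P_kpa : float
        Transmural pressure in kPa.
    f_mn : float
        Axial force in mN.
    r_i, h : float
        Deformed inner radius and wall thickness in µm.

    Returns
    -------
    StressState
        σθ = P·r_i/h and σz = (f + P·π·r_i²)/(π·h·(2·r_i + h)), both in kPa.
    """
    if h <= 0 or r_i <= 0:
        raise GeometryError(f"need r_i > 0 and h > 0, got r_i={r_i}, h={h}")
    sigma_theta = P_kpa * r_i / h
    sigma_z = (f_mn * _MN_TO_KPA_UM2 + P_kpa * math.pi * r_i**2) / (
        math.pi * h * (2.0 * r_i + h)
    )
    return StressState(sigma_theta=sigma_theta, sigma_z=sigma_z, f=f_mn)


def circumferential_stretch(
    d_i: float,
    d_o: float,
    D_i: float,
    D_o: float,
    convention: str = "midwall",
) -> float:
    """Circumferential stretch ratio λθ.

    The default mid-wall convention uses the mean diameter,
    λθ = (d_i + d_o)/(D_i + D_o); ``convention="inner"`` uses d_i/D_i.
    """
    if convention == "midwall":
        return (d_i + d_o) / (D_i + D_o)
    if convention == "inner":
        return d_i / D_i
    raise ValueError(f"unknown λθ convention {convention!r}")


def estimate_in_vivo_stretch(sweeps: Sequence[PressureSweep]) -> InVivoStretchResult:
    """Estimate the axial stretch at which axial force is pressure-invariant.

    For each sweep the slope s(λz) of axial force versus pressure is obtained
    by least squares; the in vivo stretch λ_iv is the root of s(λz), found by
    linear interpolation between the bracketing sweeps (quadratic fit across
    all sweeps when ≥ 4 are available).  If no sign change exists, the λz with
    the smallest |s| is returned and ``no_sign_change`` is set.
    """
    if len(sweeps) < 3:
        raise ValidationError(f"need ≥ 3 sweeps at distinct λz, got {len(sweeps)}")
    for sw in sweeps:
        if len(sw) < 2:
            raise ValidationError(f"sweep {sw.label!r} has < 2 pressure points")
    order = np.argsort([sw.axial_stretch for sw in sweeps])
    sweeps = [sweeps[i] for i in order]
    stretches = np.array([sw.axial_stretch for sw in sweeps])
    if len(np.unique(stretches)) != len(stretches):
        raise ValidationError("sweeps must be at distinct axial stretches")
    slopes = np.array(
        [np.polyfit(sw.pressures, sw.axial_forces, 1)[0] for sw in sweeps]
    )

    sign_change = np.nonzero(np.diff(np.sign(slopes)) != 0)[0]
    if slopes.min() > 0 or slopes.max() < 0 or len(sign_change) == 0:
        k = int(np.argmin(np.abs(slopes)))
        return InVivoStretchResult(
            lambda_iv=float(stretches[k]),
            slopes=slopes,
            stretches=stretches,
            residual=float(abs(slopes[k])),
            no_sign_change=True,
        )

    exact = np.nonzero(slopes == 0)[0]
    if len(exact):
        lam = float(stretches[exact[0]])
        return InVivoStretchResult(lam, slopes, stretches, residual=0.0)

    if len(sweeps) >= 4:
        # quadratic fit of s(λz); pick the real root inside the tested range
        coeffs = np.polyfit(stretches, slopes, 2)
        roots = np.roots(coeffs)
        real = roots[np.isreal(roots)].real
        inside = real[(real >= stretches[0]) & (real <= stretches[-1])]
        if len(inside):
            lam = float(inside[np.argmin(np.abs(inside - stretches.mean()))])
            return InVivoStretchResult(
                lam, slopes, stretches, residual=float(abs(np.polyval(coeffs, lam)))
            )
    k = int(sign_change[0])
    lam = float(
        stretches[k]
        - slopes[k] * (stretches[k + 1] - stretches[k]) / (slopes[k + 1] - slopes[k])
    )
    interp_slope = np.interp(lam, stretches, slopes)
    return InVivoStretchResult(lam, slopes, stretches, residual=float(abs(interp_slope)))


def tangent_modulus_theta(
    lambda_theta: np.ndarray,
    sigma_theta_kpa: np.ndarray,
    pressures_mmhg: np.ndarray,
    reference_pressure: float,
    window: int = 5,
) -> float:
    """Circumferential tangent modulus dσθ/dλθ (MPa) at a reference pressure.

    The slope is taken from a local least-squares line over ``window`` points
    of the σθ(λθ) curve centred on the sample nearest ``reference_pressure``
    (the window is truncated at the curve ends).
    """
    lambda_theta = np.asarray(lambda_theta, dtype=float)
    sigma_theta_kpa = np.asarray(sigma_theta_kpa, dtype=float)
    pressures_mmhg = np.asarray(pressures_mmhg, dtype=float)
    n = len(lambda_theta)
    if n < 3:
        raise ValidationError(f"need ≥ 3 points for a tangent modulus, got {n}")
    if window < 2:
        raise ValueError("window must be ≥ 2")
    k = int(np.argmin(np.abs(pressures_mmhg - reference_pressure)))
    half = window // 2
    lo = max(0, k - half)
    hi = min(n, lo + window)
    lo = max(0, hi - window)
    x = lambda_theta[lo:hi]
    y = sigma_theta_kpa[lo:hi]
    if np.ptp(x) == 0:
        return 0.0
    slope_kpa = np.polyfit(x, y, 1)[0]
    return float(slope_kpa / 1000.0)  # kPa -> MPa


def process_sweep(
    sweep: PressureSweep,
    ring: RingGeometry,
    reference_pressure: float,
    lambda_theta_convention: str = "midwall",
    modulus_window: int = 5,
) -> MechanicsResult:
    """Full per-pressure kinematics and stress analysis of one inflation sweep.

    Computes the deformed state and Cauchy stresses at every pressure step,
    the circumferential stretch at the step nearest ``reference_pressure``
    (the group's mean arterial pressure, mmHg) and the circumferential tangent
    modulus there.  Inadmissible load points raise; degenerate (d_i = 0)
    points are flagged.
    """
    flags: list[str] = []
    states: list[DeformedState] = []
    stresses: list[StressState] = []
    for p_mmhg, d_o, f_mn in zip(sweep.pressures, sweep.outer_diameters, sweep.axial_forces):
        d_i = deformed_inner_diameter(d_o, ring.D_o, ring.D_i, sweep.axial_stretch)
        if d_i == 0.0:
            flags.append(f"degenerate state (d_i = 0) at P = {p_mmhg:g} mmHg")
        lam_theta = circumferential_stretch(
            d_i, d_o, ring.D_i, ring.D_o, convention=lambda_theta_convention
        )
        state = DeformedState(
            P=p_mmhg * MMHG_TO_KPA,
            d_o=d_o,
            d_i=d_i,
            lambda_z=sweep.axial_stretch,
            lambda_theta=lam_theta,
        )
        states.append(state)
        stresses.append(cauchy_stresses(state.P, f_mn, state.r_i, state.h))

    if not (sweep.pressures[0] <= reference_pressure <= sweep.pressures[-1]):
        flags.append(
            f"reference pressure {reference_pressure:g} mmHg outside sweep range "
            f"[{sweep.pressures[0]:g}, {sweep.pressures[-1]:g}]"
        )
        warnings.warn(flags[-1], stacklevel=2)
    k_ref = int(np.argmin(np.abs(sweep.pressures - reference_pressure)))
    modulus = tangent_modulus_theta(
        np.array([s.lambda_theta for s in states]),
        np.array([s.sigma_theta for s in stresses]),
        sweep.pressures,
        reference_pressure,
        window=modulus_window,
    )
    return MechanicsResult(
        sweep=sweep,
        states=states,
        stresses=stresses,
        reference_pressure=reference_pressure,
        lambda_theta_at_reference=states[k_ref].lambda_theta,
        tangent_modulus_theta=modulus,
        flags=flags,
    )
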
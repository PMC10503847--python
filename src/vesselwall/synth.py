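"""Synthetic data with known ground truth: vessel inflation sweeps and fiber images.

Vessel sweeps
-------------
The generator vessel is an incompressible thin-walled cylinder with a
neo-Hookean matrix reinforced by two symmetric fiber families at ±α from the
axial direction:

    W(λθ, λz) = c/2 (λθ² + λz² + λθ⁻²λz⁻² − 3)
              + c1/(2 c2) [exp(c2 (I4 − 1)²) − 1],
    I4 = λθ² sin²α + λz² cos²α,

which is the simplest standard form exhibiting nonlinear pressure stiffening
and a force-invariant axial stretch.  For a membrane under plane stress the
Cauchy stresses are σi = λi ∂W/∂λi, and at each pressure step the deformed
diameter is the root of the equilibrium condition σθ(λθ, λz) = P·r_i/h.  The
axial force follows by inverting the thin-wall σz relation.  Parameters are
fixture choices giving a rat-common-carotid-like response (unloaded outer
diameter ≈ 1 mm, in vivo stretch ≈ 1.7), not a fit to any animal.

Fiber images
------------
Fibers are rendered as sinusoidal polylines y = a·sin(2πt/w) in a frame
rotated to an orientation drawn from a von Mises mixture on (−90°, 90°]
(0° = axial = image x-axis).  The analytic straightness of such a fiber,
P_s* = chord/arc with the arc length evaluated by quadrature, is recorded as
ground truth alongside every image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

from .data_io import MMHG_TO_KPA, ImageStack, PressureSweep, RingGeometry
from .mechanics import cauchy_stresses, circumferential_stretch, deformed_inner_diameter

__all__ = [
    "VesselModel",
    "SweepGroundTruth",
    "FiberFieldSpec",
    "ModelStiffnessError",
    "simulate_sweep",
    "apply_observation_noise",
    "find_force_invariant_stretch",
    "sinusoid_straightness",
    "render_fiber_image",
    "render_fiber_stack",
]

_MN_PER_KPA_UM2 = 1e-6  # kPa·µm² -> mN


class ModelStiffnessError(RuntimeError):
    """Equilibrium root not bracketed: model too soft/stiff for the pressure grid."""


@dataclass(frozen=True)
class VesselModel:
    """Thin-walled vessel with neo-Hookean matrix + two symmetric fiber families.

    Parameters
    ----------
    D_i, D_o : float
        Unloaded inner/outer diameter, µm.
    c : float
        Matrix shear modulus, kPa.
    c1 : float
        Fiber-family stiffness, kPa.
    c2 : float
        Fiber exponential stiffening exponent, dimensionless.
    alpha_deg : float
        Fiber angle from the axial direction, degrees (0 = axial, 90 = circumferential).
    diameter_noise_sd, force_noise_sd : float
        Multiplicative Gaussian noise SDs for the observed d_o and f.
    """

    D_i: float = 800.0
    D_o: float = 1000.0
    c: float = 25.0
    c1: float = 15.0
    c2: float = 1.5
    alpha_deg: float = 60.0
    diameter_noise_sd: float = 0.0
    force_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.D_o > self.D_i > 0):
            raise ValueError("require D_o > D_i > 0")
        if self.c <= 0 or self.c1 < 0 or self.c2 < 0:
            raise ValueError("require c > 0, c1 ≥ 0, c2 ≥ 0")
        if not (0.0 <= self.alpha_deg <= 90.0):
            raise ValueError("fiber angle must lie in [0°, 90°]")

    @property
    def ring(self) -> RingGeometry:
        """Equivalent unloaded ring geometry."""
        return RingGeometry(math.pi * self.D_i, math.pi * self.D_o)

    # -- constitutive response (incompressible membrane, σr = 0) --

    def stresses(self, lam_theta: float, lam_z: float) -> tuple[float, float]:
        """Constitutive Cauchy stresses (σθ, σz) in kPa at the given stretches."""
        lt2, lz2 = lam_theta**2, lam_z**2
        sin2 = math.sin(math.radians(self.alpha_deg)) ** 2
        cos2 = 1.0 - sin2
        i4 = lt2 * sin2 + lz2 * cos2
        e4 = i4 - 1.0
        # fiber families only resist extension (I4 > 1)
        if e4 > 0 and self.c1 > 0:
            fib = self.c1 * e4 * math.exp(min(self.c2 * e4 * e4, 500.0))
        else:
            fib = 0.0
        inv = 1.0 / (lt2 * lz2)
        sigma_theta = self.c * (lt2 - inv) + 2.0 * fib * lt2 * sin2
        sigma_z = self.c * (lz2 - inv) + 2.0 * fib * lz2 * cos2
        return sigma_theta, sigma_z


@dataclass
class SweepGroundTruth:
    """Noise-free states/stresses underlying a simulated sweep."""

    pressures: np.ndarray  # mmHg
    outer_diameters: np.ndarray  # µm, noise-free
    inner_diameters: np.ndarray  # µm
    axial_forces: np.ndarray  # mN, noise-free
    lambda_theta: np.ndarray
    sigma_theta: np.ndarray  # kPa
    sigma_z: np.ndarray  # kPa
    axial_stretch: float


def _equilibrium_residual(d_o: float, model: VesselModel, lam_z: float, p_kpa: float) -> float:
    d_i = deformed_inner_diameter(d_o, model.D_o, model.D_i, lam_z)
    lam_theta = circumferential_stretch(d_i, d_o, model.D_i, model.D_o)
    sigma_theta, _ = model.stresses(lam_theta, lam_z)
    r_i, h = d_i / 2.0, (d_o - d_i) / 2.0
    return sigma_theta - p_kpa * r_i / h


def _solve_state(model: VesselModel, lam_z: float, p_mmhg: float) -> tuple[float, float, float]:
    """Solve thin-wall equilibrium for (d_o, d_i, λθ) at one pressure step."""
    p_kpa = p_mmhg * MMHG_TO_KPA
    # smallest admissible d_o (d_i -> 0) slightly inflated to avoid the pole
    d_o_min = math.sqrt((model.D_o**2 - model.D_i**2) / lam_z) * (1.0 + 1e-9)
    lo, hi = d_o_min * (1.0 + 1e-6), 6.0 * model.D_o
    f_lo = _equilibrium_residual(lo, model, lam_z, p_kpa)
    f_hi = _equilibrium_residual(hi, model, lam_z, p_kpa)
    if f_lo * f_hi > 0:
        raise ModelStiffnessError(
            f"equilibrium root not bracketed at P = {p_mmhg:g} mmHg, λz = {lam_z:g}"
        )
    d_o = optimize.brentq(
        _equilibrium_residual, lo, hi, args=(model, lam_z, p_kpa), xtol=1e-10, rtol=1e-14
    )
    d_i = deformed_inner_diameter(d_o, model.D_o, model.D_i, lam_z)
    lam_theta = circumferential_stretch(d_i, d_o, model.D_i, model.D_o)
    return d_o, d_i, lam_theta


def simulate_sweep(
    model: VesselModel,
    lam_z: float,
    pressure_grid: Sequence[float] | None = None,
    seed: int | None = None,
    label: str = "synthetic",
) -> tuple[PressureSweep, SweepGroundTruth]:
    """Simulate one stepwise inflation sweep at fixed axial stretch.

    ``pressure_grid`` defaults to the stepwise protocol 0–120 mmHg in 10-mmHg
    increments (P = 0 is replaced by 0.5 mmHg so the pressure series stays
    strictly increasing from a near-unloaded state while remaining solvable).
    Returns the (possibly noisy) observable sweep plus noise-free ground truth.
    """
    if pressure_grid is None:
        pressure_grid = [0.5] + list(range(10, 121, 10))
    pressures = np.asarray(pressure_grid, dtype=float)

    d_os, d_is, lams, s_th, s_z, forces = [], [], [], [], [], []
    for p in pressures:
        d_o, d_i, lam_theta = _solve_state(model, lam_z, p)
        sigma_theta, sigma_z = model.stresses(lam_theta, lam_z)
        r_i, h = d_i / 2.0, (d_o - d_i) / 2.0
        p_kpa = p * MMHG_TO_KPA
        f_mn = (sigma_z * math.pi * h * (2 * r_i + h) - p_kpa * math.pi * r_i**2) * _MN_PER_KPA_UM2
        d_os.append(d_o)
        d_is.append(d_i)
        lams.append(lam_theta)
        s_th.append(sigma_theta)
        s_z.append(sigma_z)
        forces.append(f_mn)

    truth = SweepGroundTruth(
        pressures=pressures,
        outer_diameters=np.array(d_os),
        inner_diameters=np.array(d_is),
        axial_forces=np.array(forces),
        lambda_theta=np.array(lams),
        sigma_theta=np.array(s_th),
        sigma_z=np.array(s_z),
        axial_stretch=lam_z,
    )
    sweep = apply_observation_noise(truth, model, seed=seed, label=label)
    return sweep, truth


def apply_observation_noise(
    truth: SweepGroundTruth,
    model: VesselModel,
    seed: int | None = None,
    label: str = "synthetic",
) -> PressureSweep:
    """Turn noise-free ground truth into an observed sweep with multiplicative noise.

    Separated from :func:`simulate_sweep` so that many noisy realisations can
    be drawn from one (expensive) equilibrium solve.
    """
    rng = np.random.default_rng(seed)
    d = truth.outer_diameters.copy()
    f = truth.axial_forces.copy()
    if model.diameter_noise_sd > 0:
        d = d * (1.0 + model.diameter_noise_sd * rng.standard_normal(len(d)))
    if model.force_noise_sd > 0:
        f = f * (1.0 + model.force_noise_sd * rng.standard_normal(len(f)))
    return PressureSweep(
        axial_stretch=truth.axial_stretch,
        pressures=truth.pressures.copy(),
        outer_diameters=d,
        axial_forces=f,
        label=label,
    )


def _force_pressure_slope(model: VesselModel, lam_z: float, pressure_grid: np.ndarray) -> float:
    _, truth = simulate_sweep(model, lam_z, pressure_grid, seed=None)
    return float(np.polyfit(truth.pressures, truth.axial_forces, 1)[0])


def find_force_invariant_stretch(
    model: VesselModel,
    lam_z_range: tuple[float, float] = (1.3, 2.2),
    pressure_grid: Sequence[float] | None = None,
    n_scan: int = 13,
) -> float:
    """Axial stretch λ* at which the simulated axial force is pressure-invariant.

    Scans the slope s(λz) of noise-free force vs pressure over ``lam_z_range``
    and refines the sign change by bisection to |s(λ*)| < 1e-6 mN/mmHg.

    Raises
    ------
    ModelStiffnessError
        If s(λz) has no sign change in the range (e.g. matrix-only models).
    """
    if pressure_grid is None:
        pressure_grid = [0.5] + list(range(10, 121, 10))
    grid = np.asarray(pressure_grid, dtype=float)
    lam_values = np.linspace(lam_z_range[0], lam_z_range[1], n_scan)
    slopes = np.array([_force_pressure_slope(model, lz, grid) for lz in lam_values])
    sign_change = np.nonzero(np.diff(np.sign(slopes)) < 0)[0]
    if len(sign_change) == 0:
        sign_change = np.nonzero(np.diff(np.sign(slopes)) != 0)[0]
    if len(sign_change) == 0:
        raise ModelStiffnessError(
            f"force–pressure slope has no sign change for λz in {lam_z_range}"
        )
    k = int(sign_change[0])
    lo, hi = lam_values[k], lam_values[k + 1]
    s_lo = slopes[k]
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        s_mid = _force_pressure_slope(model, mid, grid)
        if abs(s_mid) < 1e-6:
            return float(mid)
        if s_lo * s_mid < 0:
            hi = mid
        else:
            lo, s_lo = mid, s_mid
    return float(0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# Fiber image rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FiberFieldSpec:
    """Specification of a rendered sinusoidal fiber field.

    Orientations are drawn from a von Mises mixture on (−90°, 90°] by sampling
    the doubled angle (axial data have period 180°).  ``amplitude`` and
    ``wavelength`` are in µm; the analytic straightness P_s* follows by
    quadrature and is exposed as :attr:`straightness_truth`.
    """

    n_fibers: int = 12
    amplitude: float = 3.0  # µm
    wavelength: float = 60.0  # µm
    fiber_length: float = 180.0  # µm, straight span (chord direction extent)
    mixture_means: tuple[float, ...] = (0.0,)  # degrees
    mixture_kappas: tuple[float, ...] = (8.0,)
    mixture_weights: tuple[float, ...] = (1.0,)
    fiber_width: float = 2.0  # px, Gaussian ridge sigma
    image_size: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0  # µm / px
    background: float = 10.0
    foreground: float = 200.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.mixture_weights), 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if self.amplitude < 0 or self.wavelength <= 0:
            raise ValueError("need amplitude ≥ 0 and wavelength > 0")
        diag = math.hypot(*self.image_size) * self.pixel_size
        if self.fiber_length > diag:
            raise ValueError(
                f"fiber length {self.fiber_length} µm exceeds image diagonal {diag:.1f} µm"
            )

    @property
    def straightness_truth(self) -> float:
        """Analytic P_s* of the rendered sinusoid (chord / quadrature arc length)."""
        return sinusoid_straightness(self.amplitude, self.wavelength, self.fiber_length)


def sinusoid_straightness(amplitude: float, wavelength: float, length: float) -> float:
    """P_s of y = a·sin(2πx/w) over a span ``length``: chord / quadrature arc.

    Returns 1.0 exactly for a = 0.
    """
    if amplitude == 0:
        return 1.0
    k = 2.0 * math.pi / wavelength
    arc, _ = integrate.quad(
        lambda x: math.sqrt(1.0 + (amplitude * k * math.cos(k * x)) ** 2), 0.0, length,
        limit=200,
    )
    return length / arc


def _sample_axial_angles(spec: FiberFieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample fiber orientations (degrees in (−90, 90]) from the von Mises mixture."""
    comps = rng.choice(len(spec.mixture_weights), size=spec.n_fibers, p=spec.mixture_weights)
    angles = np.empty(spec.n_fibers)
    for i, c in enumerate(comps):
        # axial data: sample the doubled angle on the circle, halve back
        mu2 = math.radians(2.0 * spec.mixture_means[c])
        kappa = spec.mixture_kappas[c]
        if kappa <= 0:
            theta2 = rng.uniform(-math.pi, math.pi)
        else:
            theta2 = rng.vonmises(mu2, kappa)
        ang = math.degrees(theta2) / 2.0
        # wrap into (−90, 90]
        ang = ((ang + 90.0) % 180.0) - 90.0
        if ang == -90.0:
            ang = 90.0
        angles[i] = ang
    return angles


def _splat_polyline(image: np.ndarray, xs: np.ndarray, ys: np.ndarray, sigma: float, amp: float) -> None:
    """Accumulate a Gaussian-profile ridge along a finely sampled polyline."""
    ny, nx = image.shape
    r = max(1, int(math.ceil(3.0 * sigma)))
    # occupancy trick: keep per-pixel max of the splat rather than the sum, so
    # densely sampled points along the line do not inflate the ridge intensity
    for x, y in zip(xs, ys):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - r), min(nx, cx + r + 1)
        y0, y1 = max(0, cy - r), min(ny, cy + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.arange(x0, x1) - x
        gy = np.arange(y0, y1) - y
        g = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2.0 * sigma**2))
        patch = image[y0:y1, x0:x1]
        np.maximum(patch, amp * g, out=patch)


def render_fiber_image(spec: FiberFieldSpec) -> tuple[np.ndarray, "pd.DataFrame"]:
    """Render one fiber field image and its per-fiber ground-truth table.

    Returns
    -------
    image : ndarray, float
        Rendered intensity image of shape ``spec.image_size``.
    truth : pandas.DataFrame
        Per-fiber columns ``angle_deg`` and ``straightness`` (analytic P_s*).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.image_size
    image = np.zeros((ny, nx), dtype=float)
    angles = _sample_axial_angles(spec, rng)
    ps_truth = spec.straightness_truth

    length_px = spec.fiber_length / spec.pixel_size
    amp_px = spec.amplitude / spec.pixel_size
    wav_px = spec.wavelength / spec.pixel_size
    t = np.arange(0.0, length_px + 0.25, 0.25)
    records = []
    for i, ang in enumerate(angles):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        # keep the whole fiber inside the canvas so the analytic P_s* applies
        # exactly; the margin depends on the fiber's own orientation, so e.g.
        # near-axial fibers still spread over the full image height.  Fall
        # back to a loose placement when the fiber barely fits.
        th_i = math.radians(ang)
        pad = 3.0 * spec.fiber_width
        mx = abs(length_px / 2.0 * math.cos(th_i)) + abs(amp_px * math.sin(th_i)) + pad
        my = abs(length_px / 2.0 * math.sin(th_i)) + abs(amp_px * math.cos(th_i)) + pad
        x_lo, x_hi = (mx, nx - mx) if 2 * mx < nx else (0.15 * nx, 0.85 * nx)
        y_lo, y_hi = (my, ny - my) if 2 * my < ny else (0.1 * ny, 0.9 * ny)
        cx = rng.uniform(x_lo, x_hi)
        cy = rng.uniform(y_lo, y_hi)
        u = t - length_px / 2.0
        v = amp_px * np.sin(2.0 * math.pi * t / wav_px + phase)
        th = math.radians(ang)
        # image y axis points down; rotate so +angle is counter-clockwise on screen
        xs = cx + u * math.cos(th) - (-v) * math.sin(th)
        ys = cy - (u * math.sin(th) + (-v) * math.cos(th))
        _splat_polyline(image, xs, ys, spec.fiber_width, spec.foreground)
        records.append({"fiber": i, "angle_deg": ang, "straightness": ps_truth})

    image += spec.background
    if spec.noise_sd > 0:
        image += spec.noise_sd * rng.standard_normal(image.shape)
    np.clip(image, 0.0, None, out=image)
    return image, pd.DataFrame.from_records(records)


def render_fiber_stack(
    specs: Sequence[FiberFieldSpec],
    z_spacing: float = 1.0,
    interface_depth: float | None = None,
    channel: str = "elastin_2PEF",
    pressure: float | None = None,
    axial_stretch: float | None = None,
) -> tuple[ImageStack, dict]:
    """Render a depth-ordered stack from per-depth fiber specs.

    ``interface_depth`` is recorded in the truth dict (frames at depth ≥
    interface_depth are expected to be circumferential-dominant by
    construction of the specs — the caller chooses the specs).
    """
    frames = []
    per_frame = []
    for spec in specs:
        img, truth = render_fiber_image(spec)
        frames.append(img)
        per_frame.append(truth)
    stack = ImageStack(
        frames=np.stack(frames),
        pixel_size=specs[0].pixel_size,
        z_spacing=z_spacing,
        channel=channel,
        pressure=pressure,
        axial_stretch=axial_stretch,
    )
    truth = {
        "interface_depth": interface_depth,
        "per_frame": per_frame,
        "straightness": [s.straightness_truth for s in specs],
    }
    return stack, truth


def axial_to_circumferential_specs(
    n_frames: int,
    interface_frame: int,
    base: FiberFieldSpec | None = None,
    seed: int = 0,
) -> list[FiberFieldSpec]:
    """Per-depth specs that switch from axial- to circumferential-dominant fibers.

    Frames ``0 .. interface_frame-1`` use the axial mixture (mean 0°); frames
    from ``interface_frame`` on use the circumferential mixture (mean 90°),
    emulating the adventitia→media transition seen in elastin stacks.
    """
    base = base or FiberFieldSpec()
    rng = np.random.default_rng(seed)
    specs = []
    for k in range(n_frames):
        mean = 0.0 if k < interface_frame else 90.0
        specs.append(
            FiberFieldSpec(
                n_fibers=base.n_fibers,
                amplitude=base.amplitude,
                wavelength=base.wavelength,
                fiber_length=base.fiber_length,
                mixture_means=(mean,),
                mixture_kappas=base.mixture_kappas,
                mixture_weights=(1.0,),
                fiber_width=base.fiber_width,
                image_size=base.image_size,
                pixel_size=base.pixel_size,
                background=base.background,
                foreground=base.foreground,
                noise_sd=base.noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
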
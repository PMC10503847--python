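"""FFT-based fiber orientation analysis of multiphoton images.

Orientation convention: angles are measured in degrees on (−90°, 90°] with
0° the axial direction (image x-axis) and ±90° the circumferential
direction.  A structure oriented at angle θ concentrates spectral power
along θ ± 90° in the 2-D power spectrum; the orientation distribution is the
angular histogram of spectral power (DC and a small low-frequency disk
excluded, radially symmetric Hann window applied first), normalised to unit
mass.

Derived quantities follow the standard depth-resolved analysis of arterial
z-stacks: per-depth distributions stacked into a surface map, the
circumferential-to-axial mass ratio Q_C/Q_A (split at ±45° by default), and
the adventitia–media interface depth, detected as the first depth at which
the distribution turns circumferential-dominant (Q_C/Q_A > 1) persistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import ImageStack, ValidationError

__all__ = [
    "OrientationDistribution",
    "DepthOrientationMap",
    "QRatio",
    "orientation_distribution",
    "average_distribution",
    "depth_orientation_map",
    "qc_qa_ratio",
    "detect_interface",
]


@dataclass
class OrientationDistribution:
    """Angular density of structure orientation over (−90°, 90°]."""

    angle_bins: np.ndarray  # bin centers, degrees
    density: np.ndarray  # fraction per bin, sums to 1
    no_structure: bool = False  # constant image: uniform density, flag set

    def __post_init__(self) -> None:
        self.angle_bins = np.asarray(self.angle_bins, float)
        self.density = np.asarray(self.density, float)
        if len(self.angle_bins) != len(self.density):
            raise ValidationError("angle_bins and density length mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.angle_bins)

    @property
    def bin_width(self) -> float:
        return 180.0 / self.n_bins

    def mode_angle(self) -> float:
        """Bin-center angle of maximum density."""
        return float(self.angle_bins[int(np.argmax(self.density))])


@dataclass
class DepthOrientationMap:
    """Per-depth orientation distributions of a z-stack (depth 0 = outer adventitia)."""

    depths: np.ndarray  # µm, strictly increasing
    distributions: list[OrientationDistribution]
    interface_depth: float | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, float)
        if len(self.depths) != len(self.distributions):
            raise ValidationError("one distribution per depth required")
        if np.any(np.diff(self.depths) <= 0):
            raise ValidationError("depths must be strictly increasing")

    def surface(self) -> np.ndarray:
        """(n_depths, n_bins) density matrix for surface plotting."""
        return np.vstack([d.density for d in self.distributions])


@dataclass
class QRatio:
    """Circumferential vs axial orientation mass and their ratio."""

    Q_C: float
    Q_A: float
    ratio: float  # Q_C / Q_A; inf when Q_A == 0
    split_angle: float = 45.0
    infinite: bool = False


def _angle_bin_centers(n_bins: int) -> np.ndarray:
    width = 180.0 / n_bins
    return -90.0 + width * (np.arange(n_bins) + 0.5)


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap orientation angles into [−90, 90)."""
    return (theta + 90.0) % 180.0 - 90.0


def orientation_distribution(
    image: np.ndarray,
    n_bins: int = 90,
    low_freq_radius: float = 3.0,
    window: str = "hann",
) -> OrientationDistribution:
    """Orientation distribution of one image from its 2-D power spectrum.

    A radially symmetric Hann window suppresses edge leakage; the power of
    every spatial-frequency component outside the excluded low-frequency disk
    is binned by the orientation of the structure that produced it (the
    spectral angle rotated by 90°) and normalised to unit mass.

    A constant (structure-free) image yields the uniform density with
    ``no_structure`` set.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) <= 32:
        raise ValidationError(f"need a 2-D image larger than 32×32, got {img.shape}")
    ny, nx = img.shape
    centers = _angle_bin_centers(n_bins)

    yy = np.arange(ny) - (ny - 1) / 2.0
    xx = np.arange(nx) - (nx - 1) / 2.0
    rr = np.hypot(yy[:, None] / (ny / 2.0), xx[None, :] / (nx / 2.0))
    if window == "hann":
        win = np.where(rr <= 1.0, 0.5 * (1.0 + np.cos(math.pi * np.minimum(rr, 1.0))), 0.0)
    elif window == "none":
        win = np.ones_like(rr)
    else:
        raise ValueError(f"unknown window {window!r}")

    work = (img - img.mean()) * win
    spec = np.fft.fftshift(np.abs(np.fft.fft2(work)) ** 2)

    cy, cx = ny // 2, nx // 2
    fy = -(np.arange(ny) - cy)  # math y-axis points up; rows increase downwards
    fx = np.arange(nx) - cx
    fr = np.hypot(fy[:, None], fx[None, :])
    keep = fr > low_freq_radius

    phi = np.degrees(np.arctan2(fy[:, None] + np.zeros((1, nx)), fx[None, :] + np.zeros((ny, 1))))
    theta = _wrap_angle(phi - 90.0)  # spectral angle -> structure orientation

    width = 180.0 / n_bins
    idx = np.floor((theta + 90.0) / width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)

    power = np.where(keep, spec, 0.0)
    hist = np.bincount(idx.ravel(), weights=power.ravel(), minlength=n_bins)
    total = hist.sum()
    if total <= 0:
        return OrientationDistribution(centers, np.full(n_bins, 1.0 / n_bins), True)
    return OrientationDistribution(centers, hist / total)


def average_distribution(
    distributions: list[OrientationDistribution],
) -> OrientationDistribution:
    """Bin-wise mean of distributions on identical bins, renormalised."""
    if not distributions:
        raise ValidationError("need at least one distribution")
    ref = distributions[0].angle_bins
    for d in distributions[1:]:
        if len(d.angle_bins) != len(ref) or not np.allclose(d.angle_bins, ref):
            raise ValidationError("distributions have mismatched angle bins")
    mean = np.mean([d.density for d in distributions], axis=0)
    mean = mean / mean.sum()
    return OrientationDistribution(ref.copy(), mean)


def depth_orientation_map(
    stack: ImageStack,
    n_bins: int = 90,
    low_freq_radius: float = 3.0,
) -> DepthOrientationMap:
    """Per-frame orientation distributions of a z-stack, ordered by depth."""
    dists = [
        orientation_distribution(frame, n_bins=n_bins, low_freq_radius=low_freq_radius)
        for frame in stack.frames
    ]
    return DepthOrientationMap(depths=stack.depths, distributions=dists)


def qc_qa_ratio(
    distribution: OrientationDistribution, split_angle: float = 45.0
) -> QRatio:
    """Circumferential-to-axial orientation ratio Q_C/Q_A.

    Axial mass Q_A is the density with |angle| ≤ ``split_angle``;
    circumferential mass Q_C the remainder.  A bin straddling ±``split_angle``
    contributes proportionally to the overlap of its angular extent.
    """
    if not 0.0 < split_angle < 90.0:
        raise ValueError("split_angle must lie in (0°, 90°)")
    width = distribution.bin_width
    q_a = 0.0
    for center, dens in zip(distribution.angle_bins, distribution.density):
        lo, hi = center - width / 2.0, center + width / 2.0
        overlap = max(0.0, min(hi, split_angle) - max(lo, -split_angle))
        q_a += dens * overlap / width
    q_a = float(q_a)
    q_c = float(distribution.density.sum() - q_a)
    if q_a <= 0.0:
        return QRatio(Q_C=q_c, Q_A=q_a, ratio=math.inf, split_angle=split_angle, infinite=True)
    return QRatio(Q_C=q_c, Q_A=q_a, ratio=q_c / q_a, split_angle=split_angle)


def detect_interface(
    depth_map: DepthOrientationMap,
    persistence: int = 3,
    split_angle: float = 45.0,
) -> float | None:
    """Adventitia–media interface depth from the orientation flip.

    Returns the smallest depth at which Q_C/Q_A > 1 holds for ``persistence``
    consecutive frames (the orientation having turned circumferential-
    dominant), or ``None`` if the condition is never met — an absent
    interface is a valid outcome for shallow stacks.
    """
    if persistence < 1:
        raise ValueError("persistence must be ≥ 1")
    ratios = np.array(
        [qc_qa_ratio(d, split_angle).ratio for d in depth_map.distributions]
    )
    above = ratios > 1.0
    n = len(above)
    for k in range(n - persistence + 1):
        if above[k : k + persistence].all():
            return float(depth_map.depths[k])
    return None
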
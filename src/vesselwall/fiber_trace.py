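"""Fiber tracing and straightness quantification for collagen z-stacks.

The straightness parameter of a fiber is

    P_s = chord length / arc length,

so P_s = 1 for a straight fiber and P_s < 1 for an undulated one.  Fibers are
extracted per image by band-pass denoising, foreground segmentation, the
Euclidean distance transform whose ridge (medial axis) provides nucleation
points and centerlines, and decomposition of the centerline network into
simple paths.  Per-image histograms of P_s are stacked over depth into a
(depth × bin) table, and the per-stack scalar summary is the mean of the
per-slice median P_s values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import medial_axis

from .data_io import ImageStack

__all__ = [
    "FiberPath",
    "StraightnessHistogram",
    "StackStraightnessSummary",
    "denoise",
    "trace_fibers",
    "straightness",
    "stack_straightness",
]

DEFAULT_BIN_EDGES = np.linspace(0.5, 1.0, 21)


class DegeneratePathError(ValueError):
    pass


@dataclass
class FiberPath:
    """An ordered fiber centerline in physical coordinates (µm)."""

    points: np.ndarray  # (n, 2) array of (x, y) in µm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise DegeneratePathError("a fiber path needs ≥ 2 (x, y) points")

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    @property
    def chord_length(self) -> float:
        return float(np.hypot(*(self.points[-1] - self.points[0])))


@dataclass
class StraightnessHistogram:
    """Histogram of per-fiber P_s for one image at a given depth."""

    bin_edges: np.ndarray
    counts: np.ndarray
    depth: float  # µm
    n_fibers: int
    median: float | None  # None when the slice has no fibers
    empty: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class StackStraightnessSummary:
    """Per-stack straightness reduction: mean of the per-slice median P_s."""

    histograms: list[StraightnessHistogram]
    mean_of_medians: float
    n_slices_used: int
    empty_slices: list[int] = field(default_factory=list)

    def depth_table(self) -> pd.DataFrame:
        """Long-format (depth, bin_center, count) table for 3-D bar plots."""
        rows = []
        for h in self.histograms:
            for c, n in zip(h.bin_centers, h.counts):
                rows.append({"depth_um": h.depth, "ps_bin": c, "count": int(n)})
        return pd.DataFrame(rows)


def denoise(
    image: np.ndarray,
    low_sigma: float = 1.0,
    high_sigma: float = 8.0,
) -> np.ndarray:
    """Band-pass (difference-of-Gaussians) denoising tuned to fiber width.

    ``low_sigma`` suppresses shot noise below the fiber scale and
    ``high_sigma`` removes slowly varying background.  The response is
    normalised to unit gain at the filter's centre frequency, so structure at
    the fiber scale passes through essentially unchanged and repeated
    application is stable.
    """
    if low_sigma <= 0 or high_sigma <= 0:
        raise ValueError("filter scales must be positive")
    if high_sigma <= low_sigma:
        raise ValueError("high_sigma must exceed low_sigma")
    img = np.asarray(image, dtype=float)
    out = ndimage.gaussian_filter(img, low_sigma) - ndimage.gaussian_filter(img, high_sigma)
    # unit gain at the band-pass peak: H(u) = exp(-2π²σ₁²u) − exp(-2π²σ₂²u)
    # with u = f², maximised at u* = ln(σ₂²/σ₁²) / (2π²(σ₂² − σ₁²))
    s1, s2 = low_sigma**2, high_sigma**2
    u_star = math.log(s2 / s1) / (2.0 * math.pi**2 * (s2 - s1))
    peak_gain = math.exp(-2.0 * math.pi**2 * s1 * u_star) - math.exp(
        -2.0 * math.pi**2 * s2 * u_star
    )
    return out / peak_gain


def _skeleton_paths(skeleton: np.ndarray) -> list[np.ndarray]:
    """Decompose a skeleton into simple 8-connected pixel chains.

    Junction pixels (> 2 neighbours) are removed so each remaining connected
    component is a simple open chain (or a loop); chains are ordered by
    walking from an endpoint.
    """
    nbr_kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
    nnb = ndimage.convolve(skeleton.astype(int), nbr_kernel, mode="constant")
    chains_mask = skeleton & (nnb <= 2)
    labels, n = ndimage.label(chains_mask, structure=np.ones((3, 3), int))
    paths = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < 2:
            continue
        pix = set(zip(ys.tolist(), xs.tolist()))
        # find an endpoint: pixel with ≤ 1 neighbour inside the chain
        def n_inside(p):
            y, x = p
            return sum(
                (y + dy, x + dx) in pix
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)
            )

        endpoints = [p for p in pix if n_inside(p) <= 1]
        start = min(endpoints) if endpoints else min(pix)  # loops: arbitrary start
        order = [start]
        visited = {start}
        cur = start
        while True:
            y, x = cur
            nxt = None
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dy, dx) == (0, 0):
                        continue
                    q = (y + dy, x + dx)
                    if q in pix and q not in visited:
                        # prefer 4-connected continuation for smoother chains
                        if nxt is None or abs(dy) + abs(dx) < abs(nxt[0] - y) + abs(nxt[1] - x):
                            nxt = q
            if nxt is None:
                break
            order.append(nxt)
            visited.add(nxt)
            cur = nxt
        if len(order) >= 2:
            paths.append(np.array(order))
    return paths


def _endpoint_direction(rc: np.ndarray, end: int, k: int = 4) -> np.ndarray:
    """Outward unit tangent at a chain end (end=0: start, end=1: tail)."""
    if end == 0:
        a, b = rc[min(k, len(rc) - 1)], rc[0]
    else:
        a, b = rc[max(-k - 1, -len(rc))], rc[-1]
    d = (b - a).astype(float)
    n = np.hypot(*d)
    return d / n if n > 0 else d


def _link_through_junctions(
    chains: list[np.ndarray],
    junctions: np.ndarray,
    max_gap: float = 3.0,
    max_bend_deg: float = 50.0,
) -> list[np.ndarray]:
    """Merge chain fragments across skeleton junctions by tangent continuity.

    Crossing fibers share skeleton junction pixels; after the junctions are
    removed each fiber is split into fragments.  At every junction cluster the
    two fragment ends whose tangents best continue one another (bend below
    ``max_bend_deg``) are re-joined, so a fiber crossing another is traced as
    one path rather than four stubs.
    """
    if not junctions.any():
        return chains
    labels, n_clusters = ndimage.label(junctions, structure=np.ones((3, 3), int))
    cluster_pixels = [
        np.column_stack(np.nonzero(labels == lab)) for lab in range(1, n_clusters + 1)
    ]
    cos_max = math.cos(math.radians(max_bend_deg))

    chains = list(chains)
    for _ in range(16):  # fixpoint: each round may enable further merges
        merged_any = False
        for pixels in cluster_pixels:
            # candidate chain ends near any pixel of this junction cluster
            ends = []
            for ci, rc in enumerate(chains):
                for end, pt in ((0, rc[0]), (1, rc[-1])):
                    gap = np.min(np.hypot(*(pixels - pt).T))
                    if gap <= max_gap:
                        ends.append((ci, end, _endpoint_direction(rc, end)))
            best = None
            for i in range(len(ends)):
                for j in range(i + 1, len(ends)):
                    ci, ei, di = ends[i]
                    cj, ej, dj = ends[j]
                    if ci == cj:
                        continue
                    # continuation quality: outward tangents anti-parallel
                    score = -float(di @ dj)
                    if score >= cos_max and (best is None or score > best[0]):
                        best = (score, ci, ei, cj, ej)
            if best is None:
                continue
            _, ci, ei, cj, ej = best
            a = chains[ci] if ei == 1 else chains[ci][::-1]
            b = chains[cj] if ej == 0 else chains[cj][::-1]
            merged = np.concatenate([a, b])
            chains = [c for k, c in enumerate(chains) if k not in (ci, cj)]
            chains.append(merged)
            merged_any = True
        if not merged_any:
            break
    return chains


def _prune_spurs(
    chains: list[np.ndarray], junctions: np.ndarray, min_spur: int = 12, max_gap: float = 3.0
) -> list[np.ndarray]:
    """Drop short dangling branches (one end at a junction, one end free).

    The medial axis grows small side spurs where crossing fibers thicken the
    mask; they are not fibers and their endpoints confuse junction linking.
    """
    if not junctions.any():
        return chains
    jpix = np.column_stack(np.nonzero(junctions))
    kept = []
    for rc in chains:
        if len(rc) >= min_spur:
            kept.append(rc)
            continue
        near = [bool(np.min(np.hypot(*(jpix - pt).T)) <= max_gap) for pt in (rc[0], rc[-1])]
        if near[0] != near[1]:  # exactly one junction end: a spur
            continue
        kept.append(rc)
    return kept


def _merge_close_endpoints(
    chains: list[np.ndarray], max_gap: float = 3.5, max_bend_deg: float = 50.0
) -> list[np.ndarray]:
    """Greedily merge chain ends that nearly touch and continue collinearly."""
    cos_max = math.cos(math.radians(max_bend_deg))
    chains = list(chains)
    for _ in range(16):
        best = None
        for i in range(len(chains)):
            for j in range(i + 1, len(chains)):
                for ei, pi in ((0, chains[i][0]), (1, chains[i][-1])):
                    for ej, pj in ((0, chains[j][0]), (1, chains[j][-1])):
                        if np.hypot(*(pi - pj)) > max_gap:
                            continue
                        di = _endpoint_direction(chains[i], ei)
                        dj = _endpoint_direction(chains[j], ej)
                        score = -float(di @ dj)
                        if score >= cos_max and (best is None or score > best[0]):
                            best = (score, i, ei, j, ej)
        if best is None:
            break
        _, i, ei, j, ej = best
        a = chains[i] if ei == 1 else chains[i][::-1]
        b = chains[j] if ej == 0 else chains[j][::-1]
        merged = np.concatenate([a, b])
        chains = [c for k, c in enumerate(chains) if k not in (i, j)]
        chains.append(merged)
    return chains


def _smooth_path(rc: np.ndarray, window: int = 7) -> np.ndarray:
    """Moving-average smoothing of a pixel chain (reduces digitisation bias).

    Endpoints are preserved by reflecting the path at its ends before
    averaging, so chord length is essentially unchanged.
    """
    if len(rc) <= window:
        return rc.astype(float)
    w = window if window % 2 == 1 else window + 1
    pad = w // 2
    ext = np.concatenate(
        [2 * rc[:1] - rc[pad:0:-1], rc, 2 * rc[-1:] - rc[-2 : -pad - 2 : -1]], axis=0
    ).astype(float)
    kernel = np.ones(w) / w
    sm = np.column_stack(
        [np.convolve(ext[:, j], kernel, mode="valid") for j in range(rc.shape[1])]
    )
    return sm


def trace_fibers(
    image: np.ndarray,
    pixel_size: float = 1.0,
    min_length: int = 30,
    intensity_threshold: float | None = None,
    smoothing_window: int = 7,
) -> list[FiberPath]:
    """Trace fiber centerlines in a (denoised) image.

    The foreground is segmented by Otsu's threshold (or a fixed
    ``intensity_threshold``), the medial axis of the mask — the ridge of the
    Euclidean distance transform — provides the fiber centerlines, and the
    centerline network is split at junctions into simple paths.  Paths
    shorter than ``min_length`` pixels are discarded; each ridge pixel
    belongs to at most one fiber.  Returns fibers sorted longest-first.
    """
    img = np.asarray(image, dtype=float)
    if intensity_threshold is None:
        if np.ptp(img) == 0:
            return []
        intensity_threshold = threshold_otsu(img)
    mask = img > intensity_threshold
    if not mask.any():
        return []
    skeleton = medial_axis(mask, rng=0)  # seeded tie-break: tracing is deterministic
    nbr_kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
    nnb = ndimage.convolve(skeleton.astype(int), nbr_kernel, mode="constant")
    junctions = skeleton & (nnb > 2)
    chains = _prune_spurs(_skeleton_paths(skeleton), junctions)
    chains = _link_through_junctions(chains, junctions)
    chains = _merge_close_endpoints(chains)
    fibers = []
    for rc in chains:
        if len(rc) < min_length:
            continue
        sm = _smooth_path(rc, smoothing_window)
        pts = np.column_stack([sm[:, 1], sm[:, 0]]) * pixel_size  # (x, y) µm
        fibers.append(FiberPath(pts))
    fibers.sort(key=lambda f: -f.arc_length)
    return fibers


def straightness(path: FiberPath) -> float:
    """Straightness parameter P_s = chord / arc, clamped to (0, 1]."""
    arc = path.arc_length
    if arc <= 0:
        raise DegeneratePathError("zero arc length")
    return float(min(path.chord_length / arc, 1.0))


def stack_straightness(
    stack: ImageStack,
    bin_edges: np.ndarray | None = None,
    min_length: int = 30,
    intensity_threshold: float | None = None,
    denoise_params: dict | None = None,
) -> StackStraightnessSummary:
    """Per-slice P_s histograms and the mean-of-medians summary for a z-stack.

    Every frame is denoised, traced and reduced to a histogram of per-fiber
    P_s over ``bin_edges`` (default: 20 uniform bins on (0.5, 1.0]; values
    below the range are counted in the lowest bin so counts always sum to the
    number of fibers).  Slices with zero fibers are flagged empty and
    excluded from the mean of per-slice medians.
    """
    edges = DEFAULT_BIN_EDGES if bin_edges is None else np.asarray(bin_edges, float)
    dn = denoise_params or {}
    hists: list[StraightnessHistogram] = []
    empty = []
    for k, frame in enumerate(stack.frames):
        depth = k * stack.z_spacing
        fibers = trace_fibers(
            denoise(frame, **dn),
            pixel_size=stack.pixel_size,
            min_length=min_length,
            intensity_threshold=intensity_threshold,
        )
        ps = np.array([straightness(f) for f in fibers])
        if len(ps) == 0:
            hists.append(
                StraightnessHistogram(edges, np.zeros(len(edges) - 1, int), depth, 0, None, True)
            )
            empty.append(k)
            continue
        clipped = np.clip(ps, edges[0] + 1e-12, edges[-1])
        counts, _ = np.histogram(clipped, bins=edges)
        hists.append(
            StraightnessHistogram(edges, counts, depth, len(ps), float(np.median(ps)))
        )
    medians = [h.median for h in hists if not h.empty]
    mean_of_medians = float(np.mean(medians)) if medians else math.nan
    return StackStraightnessSummary(
        histograms=hists,
        mean_of_medians=mean_of_medians,
        n_slices_used=len(medians),
        empty_slices=empty,
    )
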
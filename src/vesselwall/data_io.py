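"""Input/output and unit conventions for myograph sweeps, ring geometry and image stacks.

Conventions used throughout the package
---------------------------------------
* Pressures are stored in mmHg and converted to kPa only inside stress
  computations (1 mmHg = 0.133322 kPa).
* Lengths are in micrometres (µm), forces in millinewtons (mN).
* Image stacks are depth-ordered with frame index 0 at the *outer adventitial
  surface*; depth of frame ``k`` is ``k * z_spacing`` µm.  Stacks acquired
  inside-out can be reversed on read with ``reverse=True``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MMHG_TO_KPA",
    "PressureSweep",
    "RingGeometry",
    "ImageStack",
    "FormatError",
    "ValidationError",
    "GeometryError",
    "read_myograph_table",
    "write_myograph_table",
    "ring_geometry",
    "read_ring_table",
    "read_image_stack",
    "write_image_stack",
]

#: Conversion factor from mmHg to kPa.
MMHG_TO_KPA = 0.133322


class FormatError(ValueError):
    """A file does not conform to the expected layout (missing columns, bad TIFF...)."""


class ValidationError(ValueError):
    """Parsed data violate a physical or protocol invariant."""


class GeometryError(ValueError):
    """Impossible ring or wall geometry."""


@dataclass
class PressureSweep:
    """One stepwise inflation record acquired at a fixed axial stretch.

    Parameters
    ----------
    axial_stretch : float
        Axial stretch ratio λz (deformed / unloaded length), dimensionless.
    pressures : ndarray
        Transmural pressures in mmHg, strictly increasing.
    outer_diameters : ndarray
        Deformed outer diameters d_o in µm, one per pressure step.
    axial_forces : ndarray
        Measured axial forces f in mN, one per pressure step.
    label : str
        Free-text sample / group identifier.
    """

    axial_stretch: float
    pressures: np.ndarray
    outer_diameters: np.ndarray
    axial_forces: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.outer_diameters = np.asarray(self.outer_diameters, dtype=float)
        self.axial_forces = np.asarray(self.axial_forces, dtype=float)
        n = len(self.pressures)
        if n < 2:
            raise ValidationError(
                f"sweep {self.label!r}: need at least 2 pressure points, got {n}"
            )
        if not (len(self.outer_diameters) == n == len(self.axial_forces)):
            raise ValidationError(
                f"sweep {self.label!r}: series lengths differ "
                f"(P={n}, d_o={len(self.outer_diameters)}, f={len(self.axial_forces)})"
            )
        dp = np.diff(self.pressures)
        if np.any(dp <= 0):
            bad = np.nonzero(dp <= 0)[0] + 1
            raise ValidationError(
                f"sweep {self.label!r}: pressures not strictly increasing at rows "
                f"{bad.tolist()} (values {self.pressures[bad].tolist()})"
            )
        if np.any(self.outer_diameters <= 0):
            raise ValidationError(f"sweep {self.label!r}: non-positive outer diameter")
        if not self.axial_stretch > 0:
            raise ValidationError(f"sweep {self.label!r}: axial stretch must be > 0")

    def __len__(self) -> int:
        return len(self.pressures)


@dataclass(frozen=True)
class RingGeometry:
    """Unloaded reference dimensions from a traced arterial ring.

    Diameters follow from the traced circumferences as D = C/π and the
    unloaded wall thickness as H = (D_o − D_i)/2.  All lengths in µm.
    """

    inner_circumference: float
    outer_circumference: float
    D_i: float = field(init=False)
    D_o: float = field(init=False)
    H: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.outer_circumference > self.inner_circumference > 0):
            raise GeometryError(
                "require outer_circumference > inner_circumference > 0, got "
                f"C_i={self.inner_circumference}, C_o={self.outer_circumference}"
            )
        object.__setattr__(self, "D_i", self.inner_circumference / math.pi)
        object.__setattr__(self, "D_o", self.outer_circumference / math.pi)
        object.__setattr__(self, "H", (self.D_o - self.D_i) / 2.0)


def ring_geometry(inner_circumference: float, outer_circumference: float) -> RingGeometry:
    """Build a :class:`RingGeometry` from traced inner/outer circumferences (µm)."""
    return RingGeometry(float(inner_circumference), float(outer_circumference))


@dataclass
class ImageStack:
    """A single-channel multiphoton z-stack with acquisition metadata.

    ``frames[k]`` is the 2-D intensity image at depth ``k * z_spacing`` µm,
    with depth 0 at the outer adventitial surface.
    """

    frames: np.ndarray  # (n_frames, ny, nx)
    pixel_size: float  # µm / pixel
    z_spacing: float = 1.0  # µm
    channel: str = "collagen_SHG"  # or "elastin_2PEF"
    pressure: float | None = None  # mmHg
    axial_stretch: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be a (n, ny, nx) array, got ndim={self.frames.ndim}"
            )
        if self.pixel_size <= 0 or self.z_spacing <= 0:
            raise ValidationError("pixel_size and z_spacing must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def depths(self) -> np.ndarray:
        """Depth of each frame below the outer adventitial surface, µm."""
        return np.arange(len(self.frames), dtype=float) * self.z_spacing


# ---------------------------------------------------------------------------
# Myograph tables
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "pressure": "pressure_mmHg",
    "diameter": "outer_diameter_um",
    "force": "force_mN",
    "stretch": "axial_stretch",
}

#: Multiplicative factors bringing a value in the named unit to the canonical one.
_UNIT_FACTORS = {
    "pressure": {"mmHg": 1.0, "kPa": 1.0 / MMHG_TO_KPA},
    "diameter": {"um": 1.0, "µm": 1.0, "mm": 1000.0},
    "force": {"mN": 1.0, "uN": 1e-3, "µN": 1e-3, "N": 1e3},
}


def read_myograph_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    units: dict[str, str] | None = None,
    sep: str | None = None,
    label: str = "",
    drop_preconditioning: bool = True,
) -> list[PressureSweep]:
    """Read a delimited myograph export into one :class:`PressureSweep` per axial-stretch block.

    The file must contain pressure, outer-diameter, force and axial-stretch
    columns; ``column_map`` maps the logical names ``pressure``, ``diameter``,
    ``force``, ``stretch`` to the file's column headers.  Lines starting with
    ``#`` are ignored.  ``units`` may override the canonical units per logical
    column (e.g. ``{"force": "uN"}``).  Rows are grouped into contiguous
    blocks of constant axial stretch; each block becomes one sweep.

    An optional boolean/integer ``preconditioning`` column flags acquisition
    blocks recorded during preconditioning cycles; these are dropped by
    default (``drop_preconditioning=True``).
    """
    path = Path(path)
    cmap = dict(_DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty or unreadable table") from exc

    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; present: {list(df.columns)}"
        )

    units = units or {}
    for logical in ("pressure", "diameter", "force"):
        unit = units.get(logical)
        if unit is None:
            continue
        try:
            factor = _UNIT_FACTORS[logical][unit]
        except KeyError:
            raise FormatError(f"unknown unit {unit!r} for {logical}") from None
        df[cmap[logical]] = df[cmap[logical]] * factor

    if drop_preconditioning and "preconditioning" in df.columns:
        df = df[~df["preconditioning"].astype(bool)]

    sweeps: list[PressureSweep] = []
    # contiguous blocks of constant axial stretch -> one sweep each
    stretch = df[cmap["stretch"]].to_numpy(dtype=float)
    block_id = np.concatenate([[0], np.cumsum(np.diff(stretch) != 0)])
    for bid in np.unique(block_id):
        block = df[block_id == bid].sort_values(cmap["pressure"])
        sweeps.append(
            PressureSweep(
                axial_stretch=float(block[cmap["stretch"]].iloc[0]),
                pressures=block[cmap["pressure"]].to_numpy(dtype=float),
                outer_diameters=block[cmap["diameter"]].to_numpy(dtype=float),
                axial_forces=block[cmap["force"]].to_numpy(dtype=float),
                label=label or path.stem,
            )
        )
    return sweeps


def write_myograph_table(sweeps: Sequence[PressureSweep], path: str | Path) -> None:
    """Write sweeps to CSV in the canonical column layout (mmHg / µm / mN)."""
    rows = []
    for sw in sweeps:
        for p, d, f in zip(sw.pressures, sw.outer_diameters, sw.axial_forces):
            rows.append(
                {
                    "axial_stretch": sw.axial_stretch,
                    "pressure_mmHg": p,
                    "outer_diameter_um": d,
                    "force_mN": f,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_ring_table(path: str | Path) -> RingGeometry:
    """Read a two-column CSV with ``inner_circumference_um, outer_circumference_um``."""
    df = pd.read_csv(path, comment="#")
    for col in ("inner_circumference_um", "outer_circumference_um"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return ring_geometry(
        float(df["inner_circumference_um"].iloc[0]),
        float(df["outer_circumference_um"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------


def read_image_stack(
    path: str | Path,
    pixel_size: float | None = None,
    z_spacing: float | None = None,
    channel: str | None = None,
    pressure: float | None = None,
    axial_stretch: float | None = None,
    reverse: bool = False,
) -> ImageStack:
    """Read a single-channel multi-page TIFF as an :class:`ImageStack`.

    Metadata may be passed explicitly or read from a JSON sidecar named
    ``<stem>.json`` next to the TIFF (explicit arguments win).  Set
    ``reverse=True`` for stacks acquired inside-out so that frame 0 ends up
    at the outer adventitial surface.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    try:
        frames = tifffile.imread(path)
    except (ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(
            f"{path}: expected a single-channel z-stack, got shape {frames.shape}"
        )
    if reverse:
        frames = frames[::-1]
    return ImageStack(
        frames=frames,
        pixel_size=float(pixel_size if pixel_size is not None else meta.get("pixel_size", 1.0)),
        z_spacing=float(z_spacing if z_spacing is not None else meta.get("z_spacing", 1.0)),
        channel=channel if channel is not None else meta.get("channel", "collagen_SHG"),
        pressure=pressure if pressure is not None else meta.get("pressure"),
        axial_stretch=axial_stretch
        if axial_stretch is not None
        else meta.get("axial_stretch"),
    )


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size": stack.pixel_size,
                "z_spacing": stack.z_spacing,
                "channel": stack.channel,
                "pressure": stack.pressure,
                "axial_stretch": stack.axial_stretch,
            },
            indent=2,
        )
    )
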
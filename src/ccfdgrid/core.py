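"""Domain types and file I/O for en face OCTA slabs, masks and box tables.

Coordinate convention: row-major, 0-based, (row, col) = (y, x).  Grid boxes
are half-open pixel ranges [r0, r0 + box) x [c0, c0 + box).  Physical scale
is carried as a uniform pixel spacing in µm (default 12, i.e. 500 A-scans
across a 6-mm scan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

# Default physical pixel pitch: 6 mm scan / 500 A-scans.
DEFAULT_SPACING_UM = 12.0

SLAB_NAMES = ("cc_flow", "cc_structure", "subrpe_structure", "vasculature")
MASK_KINDS = ("exclusion", "hypertd", "vessel", "low_signal", "integrated")

# Tri-state codes for binary CCFD maps.
FLOW = 0
DEFICIT = 1
INVALID = 2

# 8-bit PNG palette used when exporting binary CCFD maps.
_PNG_CODE = {FLOW: 0, DEFICIT: 255, INVALID: 128}


class ShapeMismatchError(ValueError):
    """Rasters belonging to one visit do not share a common shape."""


@dataclass(frozen=True)
class EnFaceImage:
    """A 2-D en face intensity raster with physical pixel spacing.

    ``ceiling`` records the dynamic-range ceiling of the source data
    (e.g. 65535 for 16-bit exports); compensation clips to it.
    """

    pixels: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM
    slab_name: str = "cc_flow"
    ceiling: float = 65535.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2-D raster")
        if not np.all(np.isfinite(px)):
            raise ValueError("intensities must be finite")
        if px.min() < 0:
            raise ValueError("intensities must be >= 0")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if self.slab_name not in SLAB_NAMES:
            raise ValueError(f"unknown slab_name {self.slab_name!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class MaskImage:
    """A boolean raster flagging pixels (exclusion, hyperTD, vessel, ...)."""

    pixels: np.ndarray
    kind: str = "exclusion"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            px = px.astype(bool)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a nonempty 2-D raster")
        if self.kind not in MASK_KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def __or__(self, other: "MaskImage") -> "MaskImage":
        if self.shape != other.shape:
            raise ShapeMismatchError("mask shapes differ")
        return MaskImage(self.pixels | other.pixels, kind=self.kind)


@dataclass(frozen=True)
class Transform:
    """Integer pixel translation mapping a moving visit onto the reference.

    Applying ``(dy, dx)`` moves content at (r, c) to (r + dy, c + dx).
    """

    dy: int
    dx: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "dy", int(self.dy))
        object.__setattr__(self, "dx", int(self.dx))


@dataclass(frozen=True)
class BinaryCCFDMap:
    """Tri-state raster: each pixel is deficit, flow, or invalid."""

    state: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        st = np.asarray(self.state, dtype=np.uint8)
        if st.ndim != 2 or st.size == 0:
            raise ValueError("state must be a nonempty 2-D raster")
        if not np.isin(st, (FLOW, DEFICIT, INVALID)).all():
            raise ValueError("state values must be one of {flow, deficit, invalid}")
        object.__setattr__(self, "state", st)

    @property
    def shape(self) -> tuple[int, int]:
        return self.state.shape

    @property
    def deficit(self) -> np.ndarray:
        return self.state == DEFICIT

    @property
    def flow(self) -> np.ndarray:
        return self.state == FLOW

    @property
    def invalid(self) -> np.ndarray:
        return self.state == INVALID


@dataclass(frozen=True)
class VisitRecord:
    """All rasters and metadata for one visit of one eye.

    visit_index runs 0..3: 0 = one year pre-onset, 1 = hyperTD onset
    (T = 0), 2 and 3 = one and two years post-onset.  Visit 1 is the first
    visit whose hyperTD mask contains the target lesion.
    """

    visit_index: int
    cc_flow: EnFaceImage
    cc_structure: EnFaceImage
    subrpe_structure: EnFaceImage
    vasculature: EnFaceImage
    exclusion_mask: MaskImage
    hypertd_mask: MaskImage
    vessel_mask: Optional[MaskImage] = None
    eye_id: str = "eye0"
    patient_id: str = "pt0"

    def __post_init__(self) -> None:
        if not (0 <= int(self.visit_index) <= 3):
            raise ValueError("visit_index must be in 0..3")
        shapes = {
            "cc_flow": self.cc_flow.shape,
            "cc_structure": self.cc_structure.shape,
            "subrpe_structure": self.subrpe_structure.shape,
            "vasculature": self.vasculature.shape,
            "exclusion_mask": self.exclusion_mask.shape,
            "hypertd_mask": self.hypertd_mask.shape,
        }
        if self.vessel_mask is not None:
            shapes["vessel_mask"] = self.vessel_mask.shape
        ref = shapes["cc_flow"]
        bad = {k: s for k, s in shapes.items() if s != ref}
        if bad:
            raise ShapeMismatchError(
                f"rasters disagree with cc_flow shape {ref}: {bad}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.cc_flow.shape


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def _read_gray(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):  # tolerate RGB(A) exports
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise IOError(f"{path} is not a 2-D grayscale raster (shape {arr.shape})")
    return arr


def read_slab(path: str | Path, slab_name: str,
              spacing_um: float = DEFAULT_SPACING_UM) -> EnFaceImage:
    arr = _read_gray(path)
    ceiling = float(np.iinfo(arr.dtype).max) if arr.dtype.kind in "ui" else 65535.0
    return EnFaceImage(arr.astype(float), spacing_um=spacing_um,
                       slab_name=slab_name, ceiling=ceiling)


def read_mask(path: str | Path, kind: str) -> MaskImage:
    # Mask files binarize at > 0: any nonzero pixel is True.
    return MaskImage(_read_gray(path) > 0, kind=kind)


def write_slab(path: str | Path, image: EnFaceImage) -> None:
    px = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px)
    else:
        iio.imwrite(path, px)


def write_mask(path: str | Path, mask: MaskImage) -> None:
    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def write_ccfd_map(path: str | Path, ccfd: BinaryCCFDMap) -> None:
    out = np.zeros(ccfd.shape, dtype=np.uint8)
    for code, value in _PNG_CODE.items():
        out[ccfd.state == code] = value
    iio.imwrite(Path(path), out)


def read_ccfd_map(path: str | Path,
                  spacing_um: float = DEFAULT_SPACING_UM) -> BinaryCCFDMap:
    arr = _read_gray(path)
    state = np.full(arr.shape, INVALID, dtype=np.uint8)
    state[arr == _PNG_CODE[FLOW]] = FLOW
    state[arr == _PNG_CODE[DEFICIT]] = DEFICIT
    return BinaryCCFDMap(state, spacing_um=spacing_um)


def load_visit(paths: Mapping[str, str | Path], meta: Mapping[str, object],
               config=None, spacing_um: float = DEFAULT_SPACING_UM) -> VisitRecord:
    """Load one visit's slabs and masks from disk into a VisitRecord.

    ``paths`` maps raster roles (cc_flow, cc_structure, subrpe_structure,
    vasculature, exclusion_mask, hypertd_mask, optionally vessel_mask) to
    files; ``meta`` provides patient_id, eye_id and visit_index.  Shape
    consistency is enforced here, naming the offending file.
    """
    required = ("cc_flow", "cc_structure", "subrpe_structure", "vasculature",
                "exclusion_mask", "hypertd_mask")
    missing = [k for k in required if k not in paths]
    if missing:
        raise ValueError(f"missing raster paths: {missing}")

    slabs = {name: read_slab(paths[name], name, spacing_um)
             for name in SLAB_NAMES}
    excl = read_mask(paths["exclusion_mask"], "exclusion")
    hyper = read_mask(paths["hypertd_mask"], "hypertd")
    vessel = (read_mask(paths["vessel_mask"], "vessel")
              if paths.get("vessel_mask") else None)

    ref_shape = slabs["cc_flow"].shape
    for role in required[1:] + (("vessel_mask",) if vessel is not None else ()):
        shape = {"cc_structure": slabs["cc_structure"].shape,
                 "subrpe_structure": slabs["subrpe_structure"].shape,
                 "vasculature": slabs["vasculature"].shape,
                 "exclusion_mask": excl.shape,
                 "hypertd_mask": hyper.shape,
                 "vessel_mask": vessel.shape if vessel is not None else None}[role]
        if shape != ref_shape:
            raise ShapeMismatchError(
                f"{paths[role]}: shape {shape} does not match cc_flow {ref_shape}")

    return VisitRecord(
        visit_index=int(meta["visit_index"]),
        cc_flow=slabs["cc_flow"], cc_structure=slabs["cc_structure"],
        subrpe_structure=slabs["subrpe_structure"],
        vasculature=slabs["vasculature"],
        exclusion_mask=excl, hypertd_mask=hyper, vessel_mask=vessel,
        eye_id=str(meta.get("eye_id", "eye0")),
        patient_id=str(meta.get("patient_id", "pt0")),
    )


# ---------------------------------------------------------------------------
# Box table I/O
# ---------------------------------------------------------------------------

BOX_TABLE_COLUMNS = ("patient_id", "eye_id", "box_id", "visit_index",
                     "category", "ccfd_pct", "valid_frac", "included")


@dataclass(frozen=True)
class BoxObservation:
    """One (eye, box, visit) CCFD measurement."""

    patient_id: str
    eye_id: str
    box_id: int
    visit_index: int
    category: str
    ccfd_pct: Optional[float]  # None when excluded or empty denominator
    valid_frac: float
    included: bool


def box_table(observations: Sequence[BoxObservation]) -> pd.DataFrame:
    if len(observations) == 0:
        raise ValueError("no box observations to tabulate")
    rows = [{c: getattr(o, c) for c in BOX_TABLE_COLUMNS} for o in observations]
    df = pd.DataFrame(rows, columns=list(BOX_TABLE_COLUMNS))
    df["ccfd_pct"] = df["ccfd_pct"].astype(float)  # None -> NaN
    return df


def write_box_table(observations: Sequence[BoxObservation] | pd.DataFrame,
                    path: str | Path) -> None:
    """Write the long-format box table (one row per eye x box x visit)."""
    df = (observations if isinstance(observations, pd.DataFrame)
          else box_table(observations))
    if len(df) == 0:
        raise ValueError("no box observations to write")
    df = df[list(BOX_TABLE_COLUMNS)]
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise IOError(f"cannot write box table to {path}: {exc}") from exc


def read_box_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BOX_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"box table {path} lacks columns {sorted(missing)}")
    return df[list(BOX_TABLE_COLUMNS)]
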
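"""Grid-box placement, categorization, per-box CCFD% and MDC flags.

A 74 x 74-px target box is centered on the annotated target hyperTD on the
registration-reference frame, and a lattice of equal boxes (pitch = box
side, anchored at the target box) tiles the raster as far as complete
boxes fit.  Box categories — target, non-target hyperTD, adjacent
background, non-adjacent background — are decided once from the union of
hyperTD masks over all visits and frozen for the whole series.

Per box and visit, CCFD% = 100 * deficit / (deficit + flow) over available
pixels; a box in which more than 25% of the area is unavailable (masked,
low-signal or registration-cropped) at *any* visit is excluded at all
visits, mirroring the integrated-mask philosophy.  A change from the
pre-onset baseline larger than the 5% minimal detectable change (MDC) is
flagged as real.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig
from .core import (DEFICIT, FLOW, INVALID, BinaryCCFDMap, EnFaceImage,
                   MaskImage, ShapeMismatchError)

CATEGORIES = ("target", "nontarget_hypertd", "adjacent_background",
              "nonadjacent_background")


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned lattice of non-overlapping boxes on the reference frame."""

    anchor: Tuple[int, int]  # top-left of the target box
    box_px: int
    boxes: Tuple[Tuple[int, int, int], ...]  # (box_id, row0, col0), row-major
    target_box_id: int
    shape: Tuple[int, int]

    def box_slices(self, box_id: int) -> Tuple[slice, slice]:
        _, r0, c0 = self.boxes[box_id]
        return slice(r0, r0 + self.box_px), slice(c0, c0 + self.box_px)


def make_target_box(target_annotation: MaskImage,
                    config: AnalysisConfig = AnalysisConfig()) -> Tuple[int, int]:
    """Top-left corner of the box centered on the annotation centroid.

    The centroid is rounded to the nearest pixel; the box is clamped to lie
    fully inside the raster.
    """
    rows, cols = np.nonzero(target_annotation.pixels)
    if rows.size == 0:
        raise ValueError("target annotation is empty")
    b = config.box_px
    h, w = target_annotation.shape
    if h < b or w < b:
        raise ValueError("raster smaller than one box")
    cy = int(np.rint(rows.mean()))
    cx = int(np.rint(cols.mean()))
    r0 = min(max(cy - b // 2, 0), h - b)
    c0 = min(max(cx - b // 2, 0), w - b)
    return r0, c0


def tile_grid(shape: Tuple[int, int], target_box: Tuple[int, int],
              config: AnalysisConfig = AnalysisConfig()) -> GridSpec:
    """Tile the raster with complete boxes on the target-anchored lattice."""
    b = config.box_px
    h, w = shape
    r0, c0 = target_box
    if not (0 <= r0 <= h - b and 0 <= c0 <= w - b):
        raise ValueError("target box not inside raster")
    row_start = r0 % b
    col_start = c0 % b
    row0s = range(row_start, h - b + 1, b)
    col0s = range(col_start, w - b + 1, b)
    boxes = []
    target_id = None
    for i, rr in enumerate(row0s):
        for j, cc in enumerate(col0s):
            box_id = len(boxes)
            boxes.append((box_id, rr, cc))
            if (rr, cc) == (r0, c0):
                target_id = box_id
    if target_id is None:
        raise ValueError("target box does not lie on its own lattice")
    return GridSpec(anchor=(r0, c0), box_px=b, boxes=tuple(boxes),
                    target_box_id=target_id, shape=(h, w))


def classify_boxes(grid: GridSpec,
                   hypertd_masks_by_visit: Sequence[MaskImage],
                   target_annotation: MaskImage) -> Dict[int, str]:
    """Freeze each box's category from hyperTD overlap across all visits.

    The target box (the one centered on the annotation) is ``target``; any
    other box overlapping any hyperTD pixel at any visit — including
    spillover of the target lesion beyond its own box — is
    ``nontarget_hypertd``.  Remaining boxes are ``adjacent_background``
    when 8-neighbouring a hyperTD-overlapping box on the lattice, else
    ``nonadjacent_background``.
    """
    union = np.zeros(grid.shape, dtype=bool)
    for m in hypertd_masks_by_visit:
        if m.shape != grid.shape:
            raise ShapeMismatchError("hyperTD mask shape mismatch")
        union |= m.pixels
    union |= target_annotation.pixels

    b = grid.box_px
    # Lattice coordinates (cell indices) for adjacency checks.
    coords = {box_id: ((r0 - grid.anchor[0] % b) // b,
                       (c0 - grid.anchor[1] % b) // b)
              for box_id, r0, c0 in grid.boxes}

    hyper_boxes = set()
    for box_id, r0, c0 in grid.boxes:
        if union[r0:r0 + b, c0:c0 + b].any():
            hyper_boxes.add(box_id)

    hyper_cells = {coords[i] for i in hyper_boxes}
    categories: Dict[int, str] = {}
    for box_id, r0, c0 in grid.boxes:
        if box_id == grid.target_box_id:
            categories[box_id] = "target"
        elif box_id in hyper_boxes:
            categories[box_id] = "nontarget_hypertd"
        else:
            ci, cj = coords[box_id]
            near = any((ci + di, cj + dj) in hyper_cells
                       for di in (-1, 0, 1) for dj in (-1, 0, 1)
                       if (di, dj) != (0, 0))
            categories[box_id] = ("adjacent_background" if near
                                  else "nonadjacent_background")
    return categories


def low_signal_mask(compensated_structure: EnFaceImage,
                    config: AnalysisConfig = AnalysisConfig()) -> MaskImage:
    """Pixels too dark to quantify: below background + 5 dB.

    The background level is the median of the darkest 5% of pixels of the
    compensated structure slab (a robust noise-floor proxy); the cutoff is
    ``background * 10^(low_signal_db / 10)`` on linear intensity.
    """
    px = compensated_structure.pixels
    k = max(1, int(np.ceil(0.05 * px.size)))
    darkest = np.partition(px.ravel(), k - 1)[:k]
    background = float(np.median(darkest))
    cutoff = background * 10.0 ** (config.low_signal_db / 10.0)
    return MaskImage(px < cutoff, kind="low_signal")


def box_ccfd(ccfd: BinaryCCFDMap, box: Tuple[slice, slice],
             low_sig: Optional[MaskImage] = None,
             config: AnalysisConfig = AnalysisConfig()
             ) -> Tuple[Optional[float], float, bool]:
    """CCFD%, valid fraction, and the per-visit 25% availability verdict.

    ``unavailable`` is the union of invalid-state and low-signal pixels in
    the box.  Returns ``(ccfd_pct, valid_frac, included)`` where included
    means the unavailable fraction does not exceed ``max_invalid_frac``
    (strictly more than 25% unavailable excludes).  ``ccfd_pct`` is None
    when no pixel is available.
    """
    sl = ccfd.state[box]
    unavailable = sl == INVALID
    if low_sig is not None:
        unavailable = unavailable | low_sig.pixels[box]
    area = sl.size
    n_unavail = int(unavailable.sum())
    valid_frac = 1.0 - n_unavail / area
    included = (n_unavail / area) <= config.max_invalid_frac
    avail = ~unavailable
    n_def = int((sl[avail] == DEFICIT).sum())
    n_flow = int((sl[avail] == FLOW).sum())
    denom = n_def + n_flow
    ccfd_pct = 100.0 * n_def / denom if denom > 0 else None
    return ccfd_pct, valid_frac, included


def mdc_change(series: Sequence[Optional[float]],
               config: AnalysisConfig = AnalysisConfig()) -> List[Optional[bool]]:
    """Flag visits whose CCFD% moved beyond the MDC from the baseline visit.

    ``series`` holds per-visit CCFD% with index 0 the pre-onset baseline.
    The baseline gets None (no self-comparison); visit v gets True when
    |ccfd(v) - ccfd(0)| is strictly greater than ``config.mdc_pct``
    (decreases count), False otherwise, None when the value is missing.
    """
    if len(series) == 0 or series[0] is None or (isinstance(series[0], float)
                                                 and np.isnan(series[0])):
        raise ValueError("baseline (visit 0) CCFD% is required")
    base = float(series[0])
    flags: List[Optional[bool]] = [None]
    for v in series[1:]:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            flags.append(None)
        else:
            flags.append(abs(float(v) - base) > config.mdc_pct)
    return flags
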
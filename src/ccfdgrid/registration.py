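"""Inter-visit registration via retinal vasculature, and mask integration.

Follow-up scans are fovea-centered, so a rigid integer translation is
estimated per visit by maximizing zero-normalized cross-correlation (ZNCC)
of the en face retinal-vasculature images against the reference visit (the
final visit of the series).  The recorded transform is then applied to the
binary CCFD map and exclusion mask of that visit; pixels shifted in from
outside the field become invalid (maps) or excluded (masks).  Per-visit
registered exclusion masks are merged into one "integrated" mask so that
the same regions are excluded at every visit.
"""

from __future__ import annotations

from typing import Sequence, Union, overload

import numpy as np
from skimage.feature import match_template

from .config import AnalysisConfig
from .core import (INVALID, BinaryCCFDMap, EnFaceImage, MaskImage,
                   ShapeMismatchError, Transform)


class RegistrationError(RuntimeError):
    """Vessel correlation peak too weak to trust the alignment."""


def estimate_shift(moving: EnFaceImage, reference: EnFaceImage,
                   config: AnalysisConfig = AnalysisConfig(),
                   return_score: bool = False):
    """Estimate the integer translation aligning ``moving`` to ``reference``.

    A central window of the moving vasculature (up to 256 px across, which
    carries ample vessel texture) is slid over the correspondingly cropped
    reference; the ZNCC peak within |dy|, |dx| <= radius wins.  Exact ties
    break toward the smaller |dy| + |dx|, then lexicographically on
    (dy, dx).  A peak below ``config.zncc_min_peak`` raises
    :class:`RegistrationError` (the case cannot be tracked).
    """
    if moving.shape != reference.shape:
        raise ShapeMismatchError("vasculature shapes differ")
    r = config.search_radius_px
    h, w = moving.shape
    if h <= 2 * r or w <= 2 * r:
        raise ValueError("raster too small for the registration search radius")
    ty = min(256, h - 2 * r)
    tx = min(256, w - 2 * r)
    y0 = (h - ty) // 2
    x0 = (w - tx) // 2
    template = moving.pixels[y0:y0 + ty, x0:x0 + tx]
    search = reference.pixels[y0 - r:y0 + ty + r, x0 - r:x0 + tx + r]
    if template.std() == 0 or search.std() == 0:
        raise RegistrationError("featureless vasculature image")

    zncc = match_template(search, template, pad_input=False)
    peak = float(np.nanmax(zncc))
    if not np.isfinite(peak) or peak < config.zncc_min_peak:
        raise RegistrationError(
            f"vessel correlation peak {peak:.3f} below {config.zncc_min_peak}")

    ties = np.argwhere(zncc == np.nanmax(zncc))
    shifts = ties - r  # result index (r + dy, r + dx) -> (dy, dx)
    order = np.lexsort((shifts[:, 1], shifts[:, 0],
                        np.abs(shifts).sum(axis=1)))
    dy, dx = shifts[order[0]]
    t = Transform(dy=int(dy), dx=int(dx))
    return (t, peak) if return_score else t


def _shift_array(arr: np.ndarray, t: Transform, fill) -> np.ndarray:
    out = np.full_like(arr, fill)
    dy, dx = t.dy, t.dx
    h, w = arr.shape
    src = (slice(max(0, -dy), h - max(0, dy)), slice(max(0, -dx), w - max(0, dx)))
    dst = (slice(max(0, dy), h - max(0, -dy)), slice(max(0, dx), w - max(0, -dx)))
    out[dst] = arr[src]
    return out


def apply_transform(raster: Union[BinaryCCFDMap, MaskImage],
                    t: Transform) -> Union[BinaryCCFDMap, MaskImage]:
    """Translate a CCFD map or mask by ``t``.

    Border pixels with no source content become invalid (CCFD maps) or, for
    exclusion-type masks (exclusion / integrated / low_signal), True: an
    unobserved border pixel cannot be quantified.  Annotation-type masks
    (hypertd / vessel) fill with False — unobserved content is not a
    lesion.  Translated content is preserved exactly.
    """
    if isinstance(raster, BinaryCCFDMap):
        return BinaryCCFDMap(_shift_array(raster.state, t, INVALID),
                             spacing_um=raster.spacing_um)
    if isinstance(raster, MaskImage):
        fill = raster.kind in ("exclusion", "integrated", "low_signal")
        return MaskImage(_shift_array(raster.pixels, t, fill), kind=raster.kind)
    raise TypeError(f"cannot transform {type(raster).__name__}")


def translate_image(image: EnFaceImage, t: Transform, fill: float = 0.0) -> EnFaceImage:
    """Translate an intensity raster, filling vacated borders with ``fill``."""
    return EnFaceImage(_shift_array(image.pixels, t, fill),
                       spacing_um=image.spacing_um, slab_name=image.slab_name,
                       ceiling=image.ceiling)


def integrate_masks(registered_exclusions: Sequence[MaskImage]) -> MaskImage:
    """Pixelwise union of the registered per-visit exclusion masks."""
    if len(registered_exclusions) == 0:
        raise ValueError("no exclusion masks to integrate")
    shape = registered_exclusions[0].shape
    out = np.zeros(shape, dtype=bool)
    for m in registered_exclusions:
        if m.shape != shape:
            raise ShapeMismatchError("exclusion mask shapes differ")
        out |= m.pixels
    return MaskImage(out, kind="integrated")
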
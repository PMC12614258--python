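"""Fuzzy C-means global thresholding of the compensated CC flow slab.

Flow-deficit pixels are separated from perfused pixels by a single global
threshold derived from a two-cluster fuzzy C-means (FCM, fuzzifier m = 2)
partition of the intensity histogram.  With m = 2 the equal-membership
point of two clusters is the midpoint of the centers, which is the
threshold.  Deficits smaller than the physiological intercapillary
distance (24 µm equivalent diameter) are removed as noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import measure

from .config import AnalysisConfig
from .core import (DEFICIT, FLOW, INVALID, BinaryCCFDMap, EnFaceImage,
                   MaskImage, ShapeMismatchError)

N_BINS = 256
MAX_ITER = 500
TOL = 1e-6


class DegenerateHistogramError(ValueError):
    """All valid pixels share one intensity; no threshold exists."""


@dataclass(frozen=True)
class FCMResult:
    centers: tuple[float, float]  # (c_low, c_high)
    threshold: float
    n_iter: int
    objective: float


def _fcm_objective(x: np.ndarray, w: np.ndarray, c1: float, c2: float) -> float:
    """FCM objective J(c1, c2) with memberships optimal for m = 2.

    For m = 2 the inner minimum over memberships gives
    J = sum_k w_k * (d1k^2 * d2k^2) / (d1k^2 + d2k^2)  (harmonic form).
    """
    d1 = (x - c1) ** 2
    d2 = (x - c2) ** 2
    denom = d1 + d2
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(denom > 0, d1 * d2 / denom, 0.0)
    return float(np.sum(w * j))


def fcm_threshold(image: EnFaceImage, valid_mask: Optional[MaskImage] = None,
                  config: AnalysisConfig = AnalysisConfig()) -> FCMResult:
    """Two-cluster FCM on the 256-bin intensity histogram of valid pixels.

    Deterministic: centers initialize at the 25th/75th percentiles of the
    valid pixels and iterate until the largest center movement falls below
    1e-6 (or 500 iterations).  The threshold is the midpoint of the two
    converged centers.
    """
    if valid_mask is not None:
        if valid_mask.shape != image.shape:
            raise ShapeMismatchError("valid_mask shape mismatch")
        vals = image.pixels[valid_mask.pixels]
    else:
        vals = image.pixels.ravel()
    if vals.size == 0 or np.unique(vals).size < 2:
        raise DegenerateHistogramError("need >= 2 distinct valid intensities")

    lo, hi = float(vals.min()), float(vals.max())
    counts, edges = np.histogram(vals, bins=N_BINS, range=(lo, hi))
    x = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(float)
    keep = w > 0
    x, w = x[keep], w[keep]

    c = np.array([np.percentile(vals, 25.0), np.percentile(vals, 75.0)], dtype=float)
    if c[0] == c[1]:  # heavily skewed histogram; still two distinct values exist
        c = np.array([lo, hi], dtype=float)

    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        d = (x[None, :] - c[:, None]) ** 2
        # membership u_ik = d_ik^-1 / sum_j d_jk^-1 (m = 2); exact hits get u = 1
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        hit = d == 0
        any_hit = hit.any(axis=0)
        u = np.empty_like(d)
        u[:, ~any_hit] = inv[:, ~any_hit] / inv[:, ~any_hit].sum(axis=0)
        u[:, any_hit] = hit[:, any_hit].astype(float)
        wu2 = w * u ** 2
        c_new = (wu2 * x).sum(axis=1) / wu2.sum(axis=1)
        shift = float(np.max(np.abs(c_new - c)))
        c = c_new
        if shift < TOL:
            break

    c_low, c_high = float(min(c)), float(max(c))
    return FCMResult(centers=(c_low, c_high),
                     threshold=0.5 * (c_low + c_high),
                     n_iter=n_iter,
                     objective=_fcm_objective(x, w, c_low, c_high))


def binarize(flow_comp: EnFaceImage, fcm: FCMResult,
             integrated_mask: MaskImage,
             vessel_mask: Optional[MaskImage] = None) -> BinaryCCFDMap:
    """Classify each pixel as deficit (< threshold), flow, or invalid.

    Mask precedence: pixels under the integrated exclusion mask or the
    retinal-vessel mask are invalid regardless of intensity.  Intensity
    exactly at the threshold counts as flow (strict <).
    """
    if integrated_mask.shape != flow_comp.shape:
        raise ShapeMismatchError("integrated_mask shape mismatch")
    if vessel_mask is not None and vessel_mask.shape != flow_comp.shape:
        raise ShapeMismatchError("vessel_mask shape mismatch")

    state = np.where(flow_comp.pixels < fcm.threshold, DEFICIT, FLOW).astype(np.uint8)
    state[integrated_mask.pixels] = INVALID
    if vessel_mask is not None:
        state[vessel_mask.pixels] = INVALID
    return BinaryCCFDMap(state, spacing_um=flow_comp.spacing_um)


def remove_small_deficits(ccfd: BinaryCCFDMap,
                          config: AnalysisConfig = AnalysisConfig()) -> BinaryCCFDMap:
    """Drop deficit components below the intercapillary-distance scale.

    8-connected deficit components whose equivalent circular diameter
    ``2 * spacing * sqrt(area_px / pi)`` is strictly below
    ``config.min_deficit_diam_um`` are reassigned to flow.  Invalid pixels
    are untouched and no deficit is ever created.
    """
    labels, n = measure.label(ccfd.deficit, connectivity=2, return_num=True)
    if n == 0:
        return ccfd
    areas = np.bincount(labels.ravel())[1:]  # component areas, label 1..n
    diam_um = 2.0 * ccfd.spacing_um * np.sqrt(areas / np.pi)
    small = np.flatnonzero(diam_um < config.min_deficit_diam_um) + 1
    if small.size == 0:
        return ccfd
    state = ccfd.state.copy()
    state[np.isin(labels, small)] = FLOW
    return BinaryCCFDMap(state, spacing_um=ccfd.spacing_um)
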
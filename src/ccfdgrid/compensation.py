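"""Gamma-optimized attenuation compensation of choriocapillaris slabs.

Drusen and other RPE/BM abnormalities attenuate the OCT signal reaching the
choriocapillaris, darkening the en face CC slabs and inflating apparent
flow deficits.  Compensation multiplies the CC flow and structure slabs by
``N(x)^(-gamma)``, where ``N`` is the smoothed sub-RPE structure slab
normalized by its 99th percentile: dark (shadowed) reference pixels yield
factors > 1, brightening the shadowed CC signal; gamma = 0 is a no-op.

The exponent gamma is chosen per scan by exhaustive search over a grid,
minimizing the standard deviation ("illumination inhomogeneity") of the
compensated CC *structure* slab over eligible pixels.  HyperTD regions are
protected: compensating areas of RPE loss would invert their brightness and
create artifactual deficits, so the compensation mask pins their factor at 1
and removes them from the objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import AnalysisConfig
from .core import EnFaceImage, MaskImage, ShapeMismatchError

# Floor for the normalized reference, as a fraction of its ceiling (p99).
# Prevents unbounded amplification in near-zero shadow pixels.
NORM_FLOOR = 1e-3


class UnquantifiableScanError(RuntimeError):
    """Too few eligible pixels to optimize compensation for this scan."""


@dataclass(frozen=True)
class CompensationResult:
    gamma_star: float
    compensated_flow: EnFaceImage
    compensated_structure: EnFaceImage
    objective_curve: dict  # gamma -> std of compensated structure


def smooth_reference(subrpe_structure: EnFaceImage,
                     config: AnalysisConfig = AnalysisConfig()) -> EnFaceImage:
    """Gaussian-filter the sub-RPE reference slab before optimization.

    Kernel is truncated to ``smooth_kernel_px`` x ``smooth_kernel_px``
    (13 x 13 by default) with sigma 15 px — with sigma this large relative
    to the kernel the filter is nearly a box average, which is the point:
    it suppresses the high-frequency noise that destabilizes the gamma
    objective.  Borders are handled by reflection; the output is floored
    at a small epsilon so it is strictly positive.
    """
    radius = (config.smooth_kernel_px - 1) // 2
    out = ndimage.gaussian_filter(subrpe_structure.pixels, sigma=config.smooth_sigma,
                                  truncate=radius / config.smooth_sigma,
                                  mode="reflect")
    eps = 1e-6 * max(1.0, float(out.max()))
    out = np.maximum(out, eps)
    return EnFaceImage(out, spacing_um=subrpe_structure.spacing_um,
                       slab_name=subrpe_structure.slab_name,
                       ceiling=subrpe_structure.ceiling)


def _normalized_reference(reference: EnFaceImage,
                          comp_mask: MaskImage | None = None) -> np.ndarray:
    """Reference scaled into (0, 1] by its 99th percentile.

    The percentile is taken over pixels outside the compensation mask:
    hyperTDs are never compensated, so their brightness must not set the
    normalization ceiling for the rest of the scan.
    """
    px = reference.pixels
    pool = px[~comp_mask.pixels] if comp_mask is not None else px
    if pool.size == 0:
        pool = px
    p99 = float(np.percentile(pool, 99))
    if p99 <= 0:
        p99 = max(float(pool.max()), 1e-12)
    return np.clip(px / p99, NORM_FLOOR, 1.0)


def compensate(flow: EnFaceImage, cc_structure: EnFaceImage,
               reference: EnFaceImage, comp_mask: MaskImage,
               gamma: float) -> tuple[EnFaceImage, EnFaceImage]:
    """Apply gamma compensation to CC flow and structure slabs.

    Pixels under ``comp_mask`` (hyperTDs) keep factor 1 and are bit-level
    unchanged.  Outputs are clipped at the input dynamic-range ceiling.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    for name, img in (("cc_structure", cc_structure), ("reference", reference)):
        if img.shape != flow.shape:
            raise ShapeMismatchError(f"{name} shape {img.shape} != flow {flow.shape}")
    if comp_mask.shape != flow.shape:
        raise ShapeMismatchError("comp_mask shape mismatch")

    n = _normalized_reference(reference, comp_mask)
    factor = n ** (-float(gamma))
    factor[comp_mask.pixels] = 1.0

    def _apply(img: EnFaceImage) -> EnFaceImage:
        out = img.pixels * factor
        # Exact identity where the factor is 1 (gamma 0 or masked pixels).
        out[factor == 1.0] = img.pixels[factor == 1.0]
        out = np.minimum(out, img.ceiling)
        return EnFaceImage(out, spacing_um=img.spacing_um,
                           slab_name=img.slab_name, ceiling=img.ceiling)

    return _apply(flow), _apply(cc_structure)


def optimize_gamma(cc_structure: EnFaceImage, reference: EnFaceImage,
                   comp_mask: MaskImage, exclusion_mask: MaskImage,
                   config: AnalysisConfig = AnalysisConfig(),
                   flow: EnFaceImage | None = None) -> CompensationResult:
    """Select the gamma minimizing compensated-structure inhomogeneity.

    Every gamma in ``config.gamma_grid`` is evaluated; the objective is the
    standard deviation of the compensated CC structure slab over eligible
    pixels (outside both the compensation and exclusion masks).  Ties break
    toward the smaller gamma.  Raises :class:`UnquantifiableScanError` when
    fewer than ``config.min_eligible_px`` pixels are eligible.
    """
    if comp_mask.shape != cc_structure.shape or exclusion_mask.shape != cc_structure.shape:
        raise ShapeMismatchError("mask shape mismatch")
    eligible = ~comp_mask.pixels & ~exclusion_mask.pixels
    n_eligible = int(eligible.sum())
    if n_eligible < config.min_eligible_px:
        raise UnquantifiableScanError(
            f"only {n_eligible} eligible pixels (< {config.min_eligible_px})")

    n = _normalized_reference(reference, comp_mask)[eligible]
    s = cc_structure.pixels[eligible]
    log_n = np.log(n)
    curve: dict[float, float] = {}
    for gamma in config.gamma_grid:
        comp = np.minimum(s * np.exp(-gamma * log_n), cc_structure.ceiling)
        curve[float(gamma)] = float(comp.std())

    gammas = np.array(list(curve))
    objs = np.array(list(curve.values()))
    gamma_star = float(gammas[int(np.argmin(objs))])  # first minimum = smallest gamma

    flow_in = flow if flow is not None else cc_structure
    comp_flow, comp_struct = compensate(flow_in, cc_structure, reference,
                                        comp_mask, gamma_star)
    return CompensationResult(gamma_star=gamma_star,
                              compensated_flow=comp_flow,
                              compensated_structure=comp_struct,
                              objective_curve=curve)
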
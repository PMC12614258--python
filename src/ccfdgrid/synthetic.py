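"""Synthetic longitudinal SS-OCTA cases with known ground truth.

Each case emulates the four-visit timeline of an eye that develops a large
choroidal hyperTD: visit 0 one year before onset, visit 1 at onset (T = 0,
first visit whose sub-RPE slab shows the bright target lesion with GLD
>= 250 µm), visits 2 and 3 one and two years after.  All content is
rendered once on an oversized canvas; each visit's rasters are a window
into that canvas offset by a known integer shift, so the true inter-visit
translation is exact and every visit has full field content (the moving
scan window over a fixed fundus).

Rendered physics, deliberately minimal but covering every downstream stage:

* Flow deficits are a hard-core disc process (jittered lattice of
  non-overlapping discs, default 48 µm across, safely above the 24-µm size
  filter).  Inside a configurable neighborhood of the lesion the deficit
  fraction rises from ``deficit_fraction_pre`` to ``deficit_fraction_post``
  at the post-onset visits; the null scenario keeps both equal.
* Drusen attenuation is a product of Gaussian bumps scaling all slabs
  multiplicatively; the hyperTD interior is never attenuated (RPE loss
  increases light penetration) and appears as elevated sub-RPE brightness.
* HypoTDs (calcified drusen / hyperreflective-foci shadows) are near-zero
  discs in every slab, copied into the per-visit exclusion mask.
* The retinal vasculature is a branching random-walk tree with baked-in
  speckle, identical across visits up to the known shift.  The large
  retinal vessels cast shadows onto everything beneath them, so the same
  tree multiplies all slabs by ``vessel_shadow_factor``; the tree is also
  exposed as the per-visit vessel mask (projection/shadow artifacts are
  excluded from quantification, and the shadow pixels give the slabs the
  dark background population the 5-dB low-signal rule estimates from).
* Noise is additive Gaussian on linear intensity, truncated at zero, drawn
  fresh per visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import AnalysisConfig
from .core import DEFAULT_SPACING_UM, EnFaceImage, MaskImage, Transform, VisitRecord
from .grid import GridSpec

HYPOTD_SIGNAL_FACTOR = 0.02  # residual signal under a shadowing lesion


@dataclass(frozen=True)
class ScenarioParams:
    """Generator settings; defaults define the study conditions."""

    shape_px: Tuple[int, int] = (500, 500)
    spacing_um: float = DEFAULT_SPACING_UM
    baseline_flow_mean: float = 120.0
    deficit_signal_frac: float = 0.30     # residual decorrelation signal in deficits
    flow_noise_sd: float = 8.0
    visit_noise_jitter: float = 0.1       # lognormal sd of per-visit noise level
    deficit_persistence: float = 0.55     # per-visit probability a deficit site is active
    visit_activity_jitter: float = 0.005  # sd of the per-visit shift in that probability
    cc_structure_mean: float = 160.0
    subrpe_mean: float = 200.0
    structure_noise_sd: float = 6.0
    deficit_fraction_pre: float = 0.10
    deficit_fraction_post: float = 0.10   # == pre: null scenario
    effect_radius_um: float = 1250.0      # lesion neighborhood for the post rise
    deficit_disc_diam_um: float = 48.0
    n_speckle: int = 0                    # sub-24-µm false deficits (filter tests)
    n_drusen: int = 15
    drusen_depth: float = 0.55            # multiplicative attenuation at bump center
    drusen_sigma_um: float = 150.0
    attenuation_floor: float = 0.5        # overlapping shadows never null the signal
    hypertd_onset_visit: int = 1          # fixed by the visit-selection design
    hypertd_radius_by_visit_um: Tuple[float, float, float, float] = (0.0, 150.0, 200.0, 300.0)
    hypertd_brightness: float = 2.0
    n_hypotd: int = 3
    hypotd_radius_um: float = 100.0
    hypotd_margin_um: float = 100.0       # outlining margin of the exclusion mask
    hypotd_clear_um: float = 1500.0       # keep shadows clear of the target
    vessel_shadow_factor: float = 0.15    # CC-slab signal multiplier under vessels
    vessel_shadow_subrpe: float = 0.85    # much milder on the deep sub-RPE average
    visit_shifts: Tuple[Tuple[int, int], ...] = ((6, -9), (-5, 7), (4, 3), (0, 0))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.deficit_fraction_pre <= 1.0
                and 0.0 <= self.deficit_fraction_post <= 1.0):
            raise ValueError("deficit fractions must lie in [0, 1]")
        if self.deficit_fraction_post < self.deficit_fraction_pre:
            raise ValueError("deficit_fraction_post must be >= deficit_fraction_pre")
        if self.hypertd_onset_visit != 1:
            raise ValueError("hyperTD onset is visit 1 by design")
        if len(self.hypertd_radius_by_visit_um) != 4 or len(self.visit_shifts) != 4:
            raise ValueError("four visits are required")
        if self.hypertd_radius_by_visit_um[0] != 0.0:
            raise ValueError("visit 0 precedes onset: hyperTD radius must be 0")
        onset_gld = 2.0 * self.hypertd_radius_by_visit_um[1]
        if onset_gld < 250.0:
            raise ValueError(
                f"onset hyperTD GLD {onset_gld:.0f} µm is below the 250-µm definition")
        radii = np.asarray(self.hypertd_radius_by_visit_um[1:])
        if np.any(np.diff(radii) < 0):
            raise ValueError("hyperTD radius must be non-decreasing after onset")
        half_um = 0.5 * min(self.shape_px) * self.spacing_um
        if max(self.hypertd_radius_by_visit_um) >= half_um or self.hypotd_radius_um >= half_um:
            raise ValueError("lesion radius exceeds image bounds")


@dataclass(frozen=True)
class SyntheticTruth:
    """Noise-free ground truth on the reference (final-visit) frame."""

    deficit_mask: Tuple[np.ndarray, ...]      # per visit, bool
    attenuation_field: Tuple[np.ndarray, ...]  # per visit, float in (0, 1]
    hypertd_mask: Tuple[np.ndarray, ...]
    hypotd_mask: np.ndarray                    # static shadows
    vessel_mask: np.ndarray                    # retinal-vessel shadow footprint
    true_shift: Tuple[Transform, ...]          # maps each visit onto reference
    target_center: Tuple[int, int]
    effect_region: np.ndarray
    params: ScenarioParams


def _disc_offsets(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dy ** 2 + dx ** 2 <= radius_px ** 2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _stamp_discs(mask: np.ndarray, centers: np.ndarray, offsets: np.ndarray) -> None:
    h, w = mask.shape
    for cy, cx in centers:
        ys = offsets[:, 0] + cy
        xs = offsets[:, 1] + cx
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        mask[ys[ok], xs[ok]] = True


def _jittered_lattice(shape: Tuple[int, int], fraction: float, disc_area: int,
                      min_dist: float, rng: np.random.Generator) -> np.ndarray:
    """Disc centers on a jittered square lattice hitting ``fraction``.

    The lattice pitch is sqrt(disc_area / fraction); jitter is bounded so
    neighboring discs keep at least ``min_dist`` between centers, giving a
    hard-core process with essentially deterministic local density.
    """
    if fraction <= 0:
        return np.empty((0, 2), dtype=int)
    pitch = float(np.sqrt(disc_area / fraction))
    if pitch < min_dist:
        raise ValueError(f"deficit fraction {fraction} too dense for hard-core discs")
    jit = (pitch - min_dist) / 2.0
    h, w = shape
    iy = np.arange(pitch / 2, h, pitch)
    ix = np.arange(pitch / 2, w, pitch)
    gy, gx = np.meshgrid(iy, ix, indexing="ij")
    pts = np.stack([gy.ravel(), gx.ravel()], axis=1)
    pts = pts + rng.uniform(-jit, jit, size=pts.shape)
    pts = np.rint(pts).astype(int)
    ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    return pts[ok]


def _vessel_tree(shape: Tuple[int, int], rng: np.random.Generator,
                 min_coverage: float = 0.08) -> Tuple[np.ndarray, np.ndarray]:
    """Branching random-walk vessel raster with baked speckle texture.

    Returns ``(intensity_image, vessel_footprint)``; the footprint is the
    boolean set of vessel pixels, reused as the shadow/projection mask.
    Trunks are added until the footprint covers at least ``min_coverage``
    of the raster, so every synthetic eye has the substantial vascular
    texture (and dark-shadow population) a real macular scan shows.
    """
    h, w = shape
    canvas = np.zeros(shape, dtype=bool)

    def walk(pos, ang, steps, width):
        for _ in range(steps):
            ang += rng.normal(0.0, 0.12)
            pos = pos + np.array([np.sin(ang), np.cos(ang)])
            y, x = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= y < h and 0 <= x < w):
                return
            canvas[max(0, y - width // 2):y + width // 2 + 1,
                   max(0, x - width // 2):x + width // 2 + 1] = True
            if width > 1 and rng.random() < 0.015:
                walk(pos.copy(), ang + rng.choice([-1, 1]) * rng.uniform(0.4, 0.9),
                     int(rng.integers(150, 400)), width - 1)

    def trunk():
        side = rng.integers(4)
        if side == 0:
            pos, ang = np.array([0.0, rng.uniform(0, w)]), rng.uniform(0.25, 0.75) * np.pi
        elif side == 1:
            pos, ang = np.array([h - 1.0, rng.uniform(0, w)]), rng.uniform(1.25, 1.75) * np.pi
        elif side == 2:
            pos, ang = np.array([rng.uniform(0, h), 0.0]), rng.uniform(-0.25, 0.25) * np.pi
        else:
            pos, ang = np.array([rng.uniform(0, h), w - 1.0]), rng.uniform(0.75, 1.25) * np.pi
        walk(pos, ang, int(rng.integers(400, 800)), 2)

    for _ in range(8):
        trunk()
    attempts = 0
    while canvas.mean() < min_coverage and attempts < 60:
        trunk()
        attempts += 1
    img = np.where(canvas, 180.0, 25.0)
    img += rng.normal(0.0, 8.0, size=shape)  # baked texture, identical every visit
    return np.clip(img, 0.0, None), canvas


def generate_case(params: ScenarioParams = ScenarioParams(),
                  config: AnalysisConfig = AnalysisConfig(),
                  eye_id: str = "eye0", patient_id: str = "pt0",
                  ) -> Tuple[list, SyntheticTruth]:
    """Render one four-visit case; deterministic given ``params.rng_seed``."""
    for dy, dx in params.visit_shifts:
        if abs(dy) > config.search_radius_px or abs(dx) > config.search_radius_px:
            raise ValueError("visit shift exceeds the registration search radius")

    rng = np.random.default_rng(params.rng_seed)
    h, w = params.shape_px
    pad = config.search_radius_px + 8
    ch, cw = h + 2 * pad, w + 2 * pad
    sp = params.spacing_um

    # --- static canvas content -------------------------------------------
    target_ref = (h // 2, w // 2)
    target_canvas = (target_ref[0] + pad, target_ref[1] + pad)

    disc_r = 0.5 * params.deficit_disc_diam_um / sp
    offsets = _disc_offsets(disc_r)
    disc_area = len(offsets)
    min_dist = 2 * int(np.ceil(disc_r)) + 1

    yy, xx = np.mgrid[0:ch, 0:cw]
    d2_target = (yy - target_canvas[0]) ** 2 + (xx - target_canvas[1]) ** 2
    effect_canvas = d2_target <= (params.effect_radius_um / sp) ** 2

    # Candidate deficit sites on a hard-core lattice; each site is active at
    # a given visit with probability ``deficit_persistence`` (flow deficits
    # are partly transient, which is what gives CCFD% its test-retest
    # variability), so the lattice density is the target fraction divided
    # by the persistence.  Inside the lesion neighborhood the site density
    # corresponds to the post-onset fraction; a random subset of those
    # sites also exists pre-onset, so onset adds sites without moving any.
    pers = params.deficit_persistence
    if not (0.0 < pers <= 1.0):
        raise ValueError("deficit_persistence must lie in (0, 1]")
    centers_out = _jittered_lattice((ch, cw), params.deficit_fraction_pre / pers,
                                    disc_area, min_dist, rng)
    centers_out = centers_out[~effect_canvas[centers_out[:, 0], centers_out[:, 1]]]
    centers_in = _jittered_lattice((ch, cw), params.deficit_fraction_post / pers,
                                   disc_area, min_dist, rng)
    centers_in = centers_in[effect_canvas[centers_in[:, 0], centers_in[:, 1]]]
    if params.deficit_fraction_post > 0:
        keep_pre = rng.random(len(centers_in)) < (params.deficit_fraction_pre
                                                  / params.deficit_fraction_post)
    else:
        keep_pre = np.zeros(len(centers_in), dtype=bool)
    # The whole eye's perfusion state drifts a little between visit days,
    # shifting every site's activity probability together.
    pers_v = np.clip(pers + rng.normal(0.0, params.visit_activity_jitter, 4),
                     0.05, 1.0)
    active_out = rng.random((4, len(centers_out))) < pers_v[:, None]
    active_in = rng.random((4, len(centers_in))) < pers_v[:, None]

    def deficit_mask_for_visit(v: int) -> np.ndarray:
        mask = np.zeros((ch, cw), dtype=bool)
        _stamp_discs(mask, centers_out[active_out[v]], offsets)
        sel = active_in[v] & (keep_pre if v < 2 else np.ones(len(centers_in), bool))
        _stamp_discs(mask, centers_in[sel], offsets)
        return mask

    deficit_by_visit = [deficit_mask_for_visit(v) for v in range(4)]

    # Drusen attenuation: product of Gaussian bumps.
    atten = np.ones((ch, cw))
    sigma_px = params.drusen_sigma_um / sp
    for _ in range(params.n_drusen):
        cy = rng.uniform(0, ch)
        cx = rng.uniform(0, cw)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        atten *= 1.0 - (1.0 - params.drusen_depth) * np.exp(-d2 / (2 * sigma_px ** 2))
    atten = np.maximum(atten, params.attenuation_floor)

    # HypoTD shadows, kept clear of the target neighborhood.  The exclusion
    # outline carries a grading margin beyond the rendered shadow so that
    # partial-shadow edge pixels (and the smoothing halo they cause in the
    # compensation reference) are excluded too, as a human grader would.
    hypo = np.zeros((ch, cw), dtype=bool)
    hypo_excl = np.zeros((ch, cw), dtype=bool)
    hypo_r = params.hypotd_radius_um / sp
    hypo_off = _disc_offsets(hypo_r)
    excl_off = _disc_offsets((params.hypotd_radius_um + params.hypotd_margin_um) / sp)
    clear2 = (params.hypotd_clear_um / sp) ** 2
    placed = 0
    attempts = 0
    while placed < params.n_hypotd and attempts < 1000:
        attempts += 1
        cy = int(rng.uniform(hypo_r, ch - hypo_r))
        cx = int(rng.uniform(hypo_r, cw - hypo_r))
        if (cy - target_canvas[0]) ** 2 + (cx - target_canvas[1]) ** 2 < clear2:
            continue
        _stamp_discs(hypo, np.array([[cy, cx]]), hypo_off)
        _stamp_discs(hypo_excl, np.array([[cy, cx]]), excl_off)
        placed += 1

    vasc, vessel_fp = _vessel_tree((ch, cw), rng)
    vessel_shadow = np.where(vessel_fp, params.vessel_shadow_factor, 1.0)
    vessel_shadow_deep = np.where(vessel_fp, params.vessel_shadow_subrpe, 1.0)

    speckle_px = None
    if params.n_speckle > 0:
        speckle_px = (rng.integers(0, ch, params.n_speckle),
                      rng.integers(0, cw, params.n_speckle))

    # --- per-visit rendering ---------------------------------------------
    ref_win = (slice(pad, pad + h), slice(pad, pad + w))
    visits = []
    truth_deficit, truth_atten, truth_hyper = [], [], []
    shifts = [Transform(dy, dx) for dy, dx in params.visit_shifts]

    for v in range(4):
        r_um = params.hypertd_radius_by_visit_um[v]
        hyper = np.zeros((ch, cw), dtype=bool)
        if r_um > 0:
            _stamp_discs(hyper, np.array([list(target_canvas)]),
                         _disc_offsets(r_um / sp))
        atten_v = np.where(hyper, 1.0, atten)  # no attenuation over the lesion
        deficit_v = deficit_by_visit[v]

        hypo_factor = np.where(hypo, HYPOTD_SIGNAL_FACTOR, 1.0) * vessel_shadow
        # Deficits keep a residual decorrelation signal; scans differ in
        # noise level visit to visit (signal-quality jitter), which is what
        # gives the measurement its finite test-retest repeatability.
        deficit_level = params.baseline_flow_mean * params.deficit_signal_frac
        flow_clean = np.where(deficit_v, deficit_level, params.baseline_flow_mean)
        if speckle_px is not None:
            flow_clean = flow_clean.copy()
            flow_clean[speckle_px] = deficit_level
        flow = flow_clean * atten_v * hypo_factor
        if params.flow_noise_sd > 0:
            sd_v = params.flow_noise_sd * float(
                np.exp(rng.normal(0.0, params.visit_noise_jitter)))
            flow = flow + rng.normal(0.0, sd_v, (ch, cw))
        structure = params.cc_structure_mean * atten_v * hypo_factor
        subrpe = (params.subrpe_mean * atten_v
                  * np.where(hypo, HYPOTD_SIGNAL_FACTOR, 1.0) * vessel_shadow_deep)
        subrpe = np.where(hyper, params.subrpe_mean * params.hypertd_brightness, subrpe)
        if params.structure_noise_sd > 0:
            structure = structure + rng.normal(0.0, params.structure_noise_sd, (ch, cw))
            subrpe = subrpe + rng.normal(0.0, params.structure_noise_sd, (ch, cw))

        dy, dx = shifts[v].dy, shifts[v].dx
        win = (slice(pad + dy, pad + dy + h), slice(pad + dx, pad + dx + w))

        def crop(arr, window=win):
            return np.ascontiguousarray(arr[window])

        mk = lambda arr, name: EnFaceImage(np.clip(crop(arr), 0.0, None),
                                           spacing_um=sp, slab_name=name)
        visits.append(VisitRecord(
            visit_index=v,
            cc_flow=mk(flow, "cc_flow"),
            cc_structure=mk(structure, "cc_structure"),
            subrpe_structure=mk(subrpe, "subrpe_structure"),
            vasculature=mk(vasc, "vasculature"),
            exclusion_mask=MaskImage(crop(hypo_excl), kind="exclusion"),
            hypertd_mask=MaskImage(crop(hyper), kind="hypertd"),
            vessel_mask=MaskImage(crop(vessel_fp), kind="vessel"),
            eye_id=eye_id, patient_id=patient_id,
        ))
        truth_deficit.append(np.ascontiguousarray(deficit_v[ref_win]))
        truth_atten.append(np.ascontiguousarray(atten_v[ref_win]))
        truth_hyper.append(np.ascontiguousarray(hyper[ref_win]))

    truth = SyntheticTruth(
        deficit_mask=tuple(truth_deficit),
        attenuation_field=tuple(truth_atten),
        hypertd_mask=tuple(truth_hyper),
        hypotd_mask=np.ascontiguousarray(hypo_excl[ref_win]),
        vessel_mask=np.ascontiguousarray(vessel_fp[ref_win]),
        true_shift=tuple(shifts),
        target_center=target_ref,
        effect_region=np.ascontiguousarray(effect_canvas[ref_win]),
        params=params,
    )
    return visits, truth


def truth_box_ccfd(truth: SyntheticTruth, grid: GridSpec,
                   visit_index: int = 0) -> Dict[int, Optional[float]]:
    """Ground-truth per-box CCFD%, from the noise-free masks.

    percent = 100 * deficit / non-excluded pixels within the box, on the
    reference frame; a fully excluded box reports None (missing).  Excluded
    pixels are the hypoTD shadows and the retinal-vessel footprint, the
    regions the quantification itself never measures.
    """
    deficit = truth.deficit_mask[visit_index]
    excluded = truth.hypotd_mask | truth.vessel_mask
    out: Dict[int, Optional[float]] = {}
    for box_id, r0, c0 in grid.boxes:
        if r0 + grid.box_px > deficit.shape[0] or c0 + grid.box_px > deficit.shape[1]:
            raise ValueError(f"box {box_id} outside the truth raster")
        sl = (slice(r0, r0 + grid.box_px), slice(c0, c0 + grid.box_px))
        ok = ~excluded[sl]
        denom = int(ok.sum())
        if denom == 0:
            out[box_id] = None
        else:
            out[box_id] = 100.0 * float((deficit[sl] & ok).sum()) / denom
    return out
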
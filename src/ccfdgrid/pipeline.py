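"""Case- and study-level orchestration of the CCFD grid workflow.

``run_case`` takes the four visits of one eye through the full
quantification chain — reference smoothing, gamma-optimized compensation
with the hyperTD mask protected, fuzzy C-means binarization, small-deficit
removal, vessel-based registration to the final visit, integrated-mask
construction, grid tiling, box categorization and per-box CCFD% with the
25% availability rule and MDC change flags.  ``run_study`` pools several
cases and fits the category-level mixed models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats as ccfd_stats
from .binarization import binarize, fcm_threshold, remove_small_deficits
from .compensation import optimize_gamma, smooth_reference
from .config import AnalysisConfig
from .core import (INVALID, BinaryCCFDMap, BoxObservation, MaskImage,
                   VisitRecord, box_table)
from .grid import (GridSpec, box_ccfd, classify_boxes, low_signal_mask,
                   make_target_box, mdc_change, tile_grid)
from .registration import (apply_transform, estimate_shift, integrate_masks,
                           translate_image)

REFERENCE_VISIT = 3  # final visit of the series is the registration reference


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and visit."""

    def __init__(self, stage: str, visit_index: Optional[int], cause: Exception):
        self.stage = stage
        self.visit_index = visit_index
        self.cause = cause
        where = f" (visit {visit_index})" if visit_index is not None else ""
        super().__init__(f"stage {stage!r}{where}: {cause}")


@dataclass
class CaseResult:
    patient_id: str
    eye_id: str
    grid: GridSpec
    categories: Dict[int, str]
    observations: List[BoxObservation]
    table: pd.DataFrame
    target_series: List[Optional[float]]
    mdc_flags: List[Optional[bool]]
    final_maps: List[BinaryCCFDMap]
    integrated_mask: MaskImage
    manifest: dict


def _stage(stage: str, visit: Optional[int], fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with context
        raise StageError(stage, visit, exc) from exc


def run_case(visits: Sequence[VisitRecord],
             config: AnalysisConfig = AnalysisConfig(),
             target_annotation: Optional[MaskImage] = None) -> CaseResult:
    """Quantify one four-visit case; deterministic given inputs and config.

    ``target_annotation`` is the target-hyperTD outline on the reference
    (final-visit) frame; by default the final visit's hyperTD mask is used.
    """
    if len(visits) != 4:
        raise ValueError("a case comprises exactly 4 visits")
    visits = sorted(visits, key=lambda v: v.visit_index)
    if [v.visit_index for v in visits] != [0, 1, 2, 3]:
        raise ValueError("visit indices must be exactly 0..3")
    reference = visits[REFERENCE_VISIT]

    manifest: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in vars(config).items()},
                      "patient_id": reference.patient_id,
                      "eye_id": reference.eye_id, "visits": []}

    # --- per-visit compensation + binarization (visit frame) -------------
    maps: List[BinaryCCFDMap] = []
    low_masks: List[MaskImage] = []
    for v in visits:
        ref_sm = _stage("smooth_reference", v.visit_index,
                        smooth_reference, v.subrpe_structure, config)
        excl = v.exclusion_mask
        if v.vessel_mask is not None:
            excl = excl | v.vessel_mask
        comp = _stage("optimize_gamma", v.visit_index, optimize_gamma,
                      v.cc_structure, ref_sm, v.hypertd_mask, excl, config,
                      flow=v.cc_flow)
        valid = MaskImage(~excl.pixels, kind="exclusion")
        fcm = _stage("fcm_threshold", v.visit_index, fcm_threshold,
                     comp.compensated_flow, valid, config)
        bmap = _stage("binarize", v.visit_index, binarize,
                      comp.compensated_flow, fcm, v.exclusion_mask, v.vessel_mask)
        bmap = _stage("size_filter", v.visit_index,
                      remove_small_deficits, bmap, config)
        maps.append(bmap)
        low_masks.append(low_signal_mask(comp.compensated_structure, config))
        manifest["visits"].append({
            "visit_index": int(v.visit_index),
            "gamma_star": float(comp.gamma_star),
            "fcm_threshold": float(fcm.threshold),
            "fcm_centers": [float(c) for c in fcm.centers],
        })

    # --- registration to the final visit ---------------------------------
    registered_maps, registered_excl, registered_hyper, registered_low = [], [], [], []
    for v, bmap, low in zip(visits, maps, low_masks):
        t, peak = _stage("estimate_shift", v.visit_index, estimate_shift,
                         v.vasculature, reference.vasculature, config,
                         return_score=True)
        registered_maps.append(apply_transform(bmap, t))
        registered_excl.append(apply_transform(v.exclusion_mask, t))
        registered_hyper.append(apply_transform(v.hypertd_mask, t))
        registered_low.append(apply_transform(low, t))
        manifest["visits"][v.visit_index].update(
            {"dy": t.dy, "dx": t.dx, "zncc_peak": float(peak)})

    integrated = _stage("integrate_masks", None, integrate_masks, registered_excl)
    final_maps = []
    for bmap in registered_maps:
        state = bmap.state.copy()
        state[integrated.pixels] = INVALID
        final_maps.append(BinaryCCFDMap(state, spacing_um=bmap.spacing_um))

    # --- grid, categories, per-box CCFD% ---------------------------------
    annotation = target_annotation if target_annotation is not None \
        else registered_hyper[REFERENCE_VISIT]
    target_box = _stage("make_target_box", None, make_target_box, annotation, config)
    grid = _stage("tile_grid", None, tile_grid, reference.shape, target_box, config)
    categories = _stage("classify_boxes", None, classify_boxes,
                        grid, registered_hyper, annotation)

    observations: List[BoxObservation] = []
    per_box: Dict[int, List[Tuple[Optional[float], float, bool]]] = {}
    for box_id, _, _ in grid.boxes:
        sl = grid.box_slices(box_id)
        per_box[box_id] = [box_ccfd(final_maps[i], sl, registered_low[i], config)
                           for i in range(4)]
    for box_id, rows in per_box.items():
        include_all = all(r[2] for r in rows) and all(r[0] is not None for r in rows)
        for i, (pct, vfrac, _inc) in enumerate(rows):
            observations.append(BoxObservation(
                patient_id=reference.patient_id, eye_id=reference.eye_id,
                box_id=box_id, visit_index=i, category=categories[box_id],
                ccfd_pct=pct, valid_frac=vfrac, included=include_all))

    table = box_table(observations)
    tgt_rows = per_box[grid.target_box_id]
    target_series = [r[0] for r in tgt_rows]
    target_included = all(r[2] for r in tgt_rows) and all(r[0] is not None
                                                          for r in tgt_rows)
    if not target_included:
        raise StageError("target_box_inclusion", None,
                         RuntimeError("target box fails the 25% availability rule"))
    flags = mdc_change(target_series, config)
    manifest["target_box_id"] = grid.target_box_id
    manifest["target_series"] = [float(x) for x in target_series]
    manifest["mdc_flags"] = [None if f is None else bool(f) for f in flags]

    return CaseResult(patient_id=reference.patient_id, eye_id=reference.eye_id,
                      grid=grid, categories=categories, observations=observations,
                      table=table, target_series=target_series, mdc_flags=flags,
                      final_maps=final_maps, integrated_mask=integrated,
                      manifest=manifest)


@dataclass
class StudyResult:
    table: pd.DataFrame
    fits: Dict[str, ccfd_stats.LMMResult]
    tables: Dict[str, pd.DataFrame]
    report: str
    target_changes: pd.DataFrame
    cases: List[CaseResult]
    failures: List[Tuple[str, str]]  # (eye label, reason)


def run_study(case_visits: Sequence[Sequence[VisitRecord]],
              config: AnalysisConfig = AnalysisConfig()) -> StudyResult:
    """Run every case, pool box tables, and fit category-level mixed models.

    Cases whose quantification fails (unregisterable, unquantifiable, or a
    target box failing the availability rule) are excluded and reported in
    ``failures``, mirroring the study-level exclusions of the workflow.
    """
    if len(case_visits) < 2:
        raise ValueError("a study needs at least 2 cases")
    cases: List[CaseResult] = []
    failures: List[Tuple[str, str]] = []
    for visits in case_visits:
        label = f"{visits[0].patient_id}/{visits[0].eye_id}"
        try:
            cases.append(run_case(visits, config))
        except (StageError, ValueError) as exc:
            failures.append((label, str(exc)))
    if not cases:
        raise RuntimeError(f"all {len(case_visits)} cases failed: {failures}")

    table = pd.concat([c.table for c in cases], ignore_index=True)

    fits: Dict[str, ccfd_stats.LMMResult] = {}
    for cat in ("target", "background", "adjacent", "nonadjacent"):
        try:
            fits[cat] = ccfd_stats.fit_lmm(table, group=cat)
        except ccfd_stats.LMMError:
            pass
    tables = ccfd_stats.summarize_tables(fits)
    report = ccfd_stats.format_report(tables)

    rows = []
    for c in cases:
        base = c.target_series[0]
        for i, val in enumerate(c.target_series):
            rows.append({"patient_id": c.patient_id, "eye_id": c.eye_id,
                         "visit_index": i, "ccfd_pct": val,
                         "change_from_baseline": (None if val is None or base is None
                                                  else val - base),
                         "mdc_flag": c.mdc_flags[i]})
    target_changes = pd.DataFrame(rows)

    return StudyResult(table=table, fits=fits, tables=tables, report=report,
                       target_changes=target_changes, cases=cases,
                       failures=failures)
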
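"""Group-level inference on CCFD% box trajectories.

The per-box CCFD% measurements are analysed with linear mixed models:
``ccfd_pct ~ visit`` (categorical, four levels) with nested random
intercepts for patients, eyes within patients, and grid boxes within eyes
(REML).  A random intercept whose variance is estimated at zero (singular
fit) is removed and the model refit.  Estimated mean differences (EMDs)
between visits are reported against the hyperTD-onset visit with
Tukey-adjusted p-values over the family of all six pairwise visit
comparisons; confidence intervals are unadjusted 95% intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

ALPHA = 0.05
N_VISITS = 4

VISIT_LABELS = {
    0: "1 y prior to hyperTD onset",
    2: "1 y after hyperTD onset",
    3: "2 y after hyperTD onset",
}

GROUP_FILTERS = {
    "target": ("target",),
    "background": ("adjacent_background", "nonadjacent_background"),
    "adjacent": ("adjacent_background",),
    "nonadjacent": ("nonadjacent_background",),
}

_VAR_TOL = 1e-6  # relative to residual variance: below this a component is singular


class LMMError(RuntimeError):
    """Mixed-model fit failed; message carries diagnostics."""


@dataclass(frozen=True)
class Contrast:
    label: str
    visit_a: int
    visit_b: int
    emd: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    p_adj: float


@dataclass(frozen=True)
class LMMResult:
    variance_components: Dict[str, float]  # patient, eye, box, residual
    fixed_effects: Dict[int, float]        # visit -> estimated mean
    mean_cov: np.ndarray                   # covariance of the visit means
    df: float                              # denominator df for contrast tests
    dropped_intercepts: List[str]
    n_boxes: int
    n_obs: int
    converged: bool
    contrasts: List[Contrast] = field(default_factory=list)


def _prepare(table: pd.DataFrame, group: Optional[str]) -> pd.DataFrame:
    df = table.copy()
    if group is not None:
        cats = GROUP_FILTERS.get(group, (group,))
        df = df[df["category"].isin(cats)]
    df = df[df["included"].astype(bool)]
    df = df.dropna(subset=["ccfd_pct"])
    if df.empty:
        raise LMMError(f"no included observations for group {group!r}")
    df = df.reset_index(drop=True)
    df["eye_uid"] = df["patient_id"].astype(str) + ":" + df["eye_id"].astype(str)
    df["box_uid"] = df["eye_uid"] + ":" + df["box_id"].astype(str)
    if df["visit_index"].nunique() < 2:
        raise LMMError("need observations from at least two visits")
    return df


def _fit_once(df: pd.DataFrame, levels: Sequence[str]):
    """One REML fit with the given random-intercept levels (outer to inner)."""
    uid = {"patient": "patient_id", "eye": "eye_uid", "box": "box_uid"}
    formula = "ccfd_pct ~ C(visit_index)"
    if not levels:
        return sm.OLS.from_formula(formula, data=df).fit(), {}
    groups = df[uid[levels[0]]]
    vc = {lev: f"0 + C({uid[lev]})" for lev in levels[1:]}
    model = smf.mixedlm(formula, df, groups=groups, re_formula="1",
                        vc_formula=vc or None)
    last_exc = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, method=method, maxiter=200)
            if res.converged and np.all(np.isfinite(res.fe_params)):
                comps = {levels[0]: float(res.cov_re.iloc[0, 0])}
                for name, v in zip(model.exog_vc.names, np.atleast_1d(res.vcomp)):
                    comps[name] = float(v)
                return res, comps
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    raise LMMError(f"mixed model did not converge for levels {list(levels)}: "
                   f"{last_exc}")


def fit_lmm(table: pd.DataFrame, group: Optional[str] = None) -> LMMResult:
    """REML fit of CCFD% on visit with nested random intercepts.

    ``group`` filters on box category: "target", "background" (both
    background classes), "adjacent", "nonadjacent", or None for all rows.
    Random intercepts with zero estimated variance (singular) are removed
    and the model refit; levels with fewer than two units are
    unidentifiable and dropped up front.
    """
    df = _prepare(table, group)
    uid = {"patient": "patient_id", "eye": "eye_uid", "box": "box_uid"}
    # A nested level is identifiable only if it refines the coarser kept
    # level (e.g. with one eye per patient the eye intercept IS the patient
    # intercept) and has at least two units.
    levels: List[str] = []
    n_prev = 1
    for lev in ("patient", "eye", "box"):
        n = df[uid[lev]].nunique()
        if n >= 2 and n > n_prev:
            levels.append(lev)
            n_prev = n
    dropped = [lev for lev in ("patient", "eye", "box") if lev not in levels]

    while True:
        res, comps = _fit_once(df, levels)
        scale = float(res.scale) if hasattr(res, "scale") else float(res.mse_resid)
        if scale <= 1e-12:
            raise LMMError("residual variance is zero (all observations equal?)")
        singular = [lev for lev in levels if comps.get(lev, np.inf) < _VAR_TOL * scale]
        if not singular:
            break
        levels = [lev for lev in levels if lev not in singular]
        dropped.extend(singular)

    # Per-visit means and their covariance from the fixed effects.
    fe = res.params if not hasattr(res, "fe_params") else res.fe_params
    fe_names = list(fe.index)
    cov_fe = np.asarray(res.cov_params().loc[fe_names, fe_names])
    visits = sorted(df["visit_index"].unique())
    A = np.zeros((len(visits), len(fe_names)))
    for i, v in enumerate(visits):
        A[i, fe_names.index("Intercept")] = 1.0
        name = f"C(visit_index)[T.{v}]"
        if name in fe_names:
            A[i, fe_names.index(name)] = 1.0
    means = A @ np.asarray(fe)
    mean_cov = A @ cov_fe @ A.T

    n_units = sum(df[uid[lev]].nunique() for lev in levels)
    dof = max(float(len(df) - len(fe_names) - n_units), 1.0)

    var_comps = {lev: comps.get(lev, 0.0) for lev in ("patient", "eye", "box")}
    var_comps["residual"] = scale
    result = LMMResult(
        variance_components=var_comps,
        fixed_effects={int(v): float(m) for v, m in zip(visits, means)},
        mean_cov=mean_cov,
        df=dof,
        dropped_intercepts=dropped,
        n_boxes=int(df["box_uid"].nunique()),
        n_obs=int(len(df)),
        converged=True,
    )
    return result


def emd_contrasts(fit: LMMResult, reference_visit: int = 1) -> List[Contrast]:
    """All pairwise visit contrasts with Tukey-adjusted p-values.

    EMD(a vs b) = mean(a) - mean(b).  The Tukey family is every pairwise
    comparison of the visit means (six for four visits), adjusted via the
    studentized-range distribution with the model's denominator df; the
    95% CIs are unadjusted.  Contrasts against ``reference_visit`` carry
    the reporting labels used in the summary tables.
    """
    visits = sorted(fit.fixed_effects)
    k = len(visits)
    tcrit = sps.t.ppf(1 - ALPHA / 2, fit.df)
    out: List[Contrast] = []
    for i, a in enumerate(visits):
        for b in visits[:i]:
            ia, ib = visits.index(a), visits.index(b)
            emd = fit.fixed_effects[a] - fit.fixed_effects[b]
            se = float(np.sqrt(fit.mean_cov[ia, ia] + fit.mean_cov[ib, ib]
                               - 2 * fit.mean_cov[ia, ib]))
            if se > 0:
                q = abs(emd) / se * np.sqrt(2.0)
                p = float(np.clip(sps.studentized_range.sf(q, k, fit.df), 0.0, 1.0))
            else:
                p = 1.0 if emd == 0 else 0.0
            label = ""
            if b == reference_visit and a in VISIT_LABELS:
                label = VISIT_LABELS[a]
            elif a == reference_visit and b in VISIT_LABELS:
                label = VISIT_LABELS[b]
            out.append(Contrast(label=label, visit_a=a, visit_b=b,
                                emd=float(emd), se=se, df=fit.df,
                                ci_low=float(emd - tcrit * se),
                                ci_high=float(emd + tcrit * se), p_adj=p))
    return out


def onset_contrasts(fit: LMMResult, reference_visit: int = 1) -> List[Contrast]:
    """The three reported contrasts: each other visit minus the onset visit."""
    rows = []
    for c in emd_contrasts(fit, reference_visit):
        if c.visit_b == reference_visit and c.visit_a != reference_visit:
            rows.append(c)
        elif c.visit_a == reference_visit and c.visit_b != reference_visit:
            # flip so the EMD is (visit - onset)
            rows.append(Contrast(label=VISIT_LABELS.get(c.visit_b, ""),
                                 visit_a=c.visit_b, visit_b=c.visit_a,
                                 emd=-c.emd, se=c.se, df=c.df,
                                 ci_low=-c.ci_high, ci_high=-c.ci_low,
                                 p_adj=c.p_adj))
    rows.sort(key=lambda c: c.visit_a)
    return rows


def summarize_tables(results: Dict[str, LMMResult],
                     reference_visit: int = 1) -> Dict[str, pd.DataFrame]:
    """Per-category EMD tables (target, background, adjacent, non-adjacent).

    Each table has one row per non-onset visit: comparison label, number of
    boxes, EMD with unadjusted 95% CI, Tukey-adjusted p.  Missing
    categories are omitted with a warning.
    """
    tables: Dict[str, pd.DataFrame] = {}
    for cat in ("target", "background", "adjacent", "nonadjacent"):
        fit = results.get(cat)
        if fit is None:
            warnings.warn(f"no mixed-model fit for category {cat!r}; table omitted")
            continue
        rows = [{"comparison": c.label or f"visit {c.visit_a} vs {c.visit_b}",
                 "n_boxes": fit.n_boxes, "emd": c.emd,
                 "ci_low": c.ci_low, "ci_high": c.ci_high, "p_adj": c.p_adj}
                for c in onset_contrasts(fit, reference_visit)]
        tables[cat] = pd.DataFrame(rows)
    return tables


def format_report(tables: Dict[str, pd.DataFrame]) -> str:
    lines = ["Mean differences in CCFD% versus the hyperTD-onset visit", ""]
    for cat, df in tables.items():
        lines.append(f"== {cat} boxes ==")
        for _, r in df.iterrows():
            lines.append(
                f"  {r['comparison']:<28s} n={int(r['n_boxes']):>4d}  "
                f"EMD = {r['emd']:+.2f}% (95% CI {r['ci_low']:+.2f} to "
                f"{r['ci_high']:+.2f}), adj. p = {r['p_adj']:.3g}")
        lines.append("")
    return "\n".join(lines)
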
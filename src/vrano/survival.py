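"""Lesion-level time-to-event endpoints and FSRT-vs-SRS comparison.

Analyses are conducted at the level of individual metastases, ignoring
within-patient correlation (a robust/cluster variance option exists but
is off by default, matching the primary analysis design).  Time runs in
days from the start of stereotactic radiotherapy; events are dated at
the first MRI demonstrating progression (or at the intervention for
resection without prior imaging progression); all other lesions are
censored at the last imaging assessment.  Radionecrosis is analysed as
a censoring-based Kaplan–Meier endpoint, not as a competing risk.

Cox models use the Efron tie approximation — relevant here because the
~3-monthly MRI schedule makes event-time ties common.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .errors import InconsistentRecordError, InvalidInputError
from .radbio import (
    NORMAL_BRAIN_ALPHA_BETA,
    FractionationScheme,
    bed_lq,
    bed_lqc,
)
from .records import ClassificationResult, LesionRecord, Status

DAYS_PER_MONTH = 30.44

ENDPOINTS = ("local_progression", "radionecrosis_any", "radionecrosis_grade4")

_EVENT_STATUSES = {
    "local_progression": {Status.PROGRESSION, Status.PROGRESSION_AND_RADIONECROSIS},
    "radionecrosis_any": {Status.RADIONECROSIS, Status.PROGRESSION_AND_RADIONECROSIS},
}

#: Covariate sets mirroring the published univariate/multivariate model
#: structure.  BED covariates are offered univariate-only by default:
#: they are nearly collinear with the treatment arm.
LOCAL_CONTROL_COVARIATES = [
    "arm_fsrt", "former_wbrt", "histology", "pretreatment_volume",
]
RADIONECROSIS_COVARIATES = [
    "arm_fsrt", "pretreatment_volume", "former_wbrt", "checkpoint_inhibitor",
]
BED_COVARIATES = ["bed12_lqc", "bed2_lq"]

HISTOLOGY_LEVELS = ("melanoma", "lung", "breast", "renal", "other")


def build_endpoint_rows(
    classifications: Iterable[ClassificationResult],
    records: Iterable[LesionRecord],
    endpoint: str,
) -> pd.DataFrame:
    """One time-to-event row per lesion for the given endpoint.

    Event rows carry the classification's event time (intervention time
    for the grade-IV endpoint); censored rows carry the last-imaging (or
    intervention) date.  Covariates are taken from the lesion metadata,
    with both BED measures recomputed from the fractionation scheme.
    """
    if endpoint not in ENDPOINTS:
        raise InvalidInputError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    by_id = {r.lesion_id: r for r in records}
    rows = []
    for c in classifications:
        rec = by_id.get(c.lesion_id)
        if rec is None:
            raise InconsistentRecordError(f"no record for classified lesion {c.lesion_id}")
        rows.append(_endpoint_row(c, rec, endpoint))
    return pd.DataFrame(
        rows,
        columns=[
            "lesion_id", "patient_id", "arm", "time", "event",
            "former_wbrt", "histology", "pretreatment_volume",
            "checkpoint_inhibitor", "bed12_lqc", "bed2_lq",
        ],
    )


def _endpoint_row(c: ClassificationResult, rec: LesionRecord, endpoint: str) -> dict:
    last_imaging = rec.last_imaging_t()
    resection = rec.resection()
    censor_t = max(
        [t for t in (last_imaging, resection.t if resection else None) if t is not None],
        default=None,
    )
    if censor_t is None:
        raise InconsistentRecordError(f"lesion {rec.lesion_id}: no imaging or intervention date")

    if endpoint == "radionecrosis_grade4":
        is_event = c.grade4
        time = resection.t if (is_event and resection is not None) else censor_t
    else:
        is_event = c.status in _EVENT_STATUSES[endpoint]
        time = c.event_t if is_event else censor_t
        if is_event and c.event_t is not None and last_imaging is not None:
            if c.event_t > last_imaging and (resection is None or c.event_t > resection.t):
                raise InconsistentRecordError(
                    f"lesion {rec.lesion_id}: event at t={c.event_t} after last "
                    f"imaging at t={last_imaging}"
                )
    if time is None or time <= 0:
        raise InconsistentRecordError(
            f"lesion {rec.lesion_id}: non-positive endpoint time {time!r}"
        )

    baseline = rec.baseline()
    scheme: Optional[FractionationScheme] = rec.scheme
    return {
        "lesion_id": rec.lesion_id,
        "patient_id": rec.patient_id,
        "arm": rec.arm,
        "time": float(time),
        "event": bool(is_event),
        "former_wbrt": bool(rec.former_wbrt),
        "histology": rec.histology,
        "pretreatment_volume": baseline.volume if baseline is not None else np.nan,
        "checkpoint_inhibitor": bool(rec.checkpoint_inhibitor),
        "bed12_lqc": bed_lqc(scheme).bed if scheme is not None else np.nan,
        "bed2_lq": (
            bed_lq(
                FractionationScheme(
                    scheme.n_fractions,
                    scheme.dose_per_fraction,
                    alpha_beta=NORMAL_BRAIN_ALPHA_BETA,
                )
            ).bed
            if scheme is not None
            else np.nan
        ),
    }


@dataclass
class SurvivalComparison:
    """Per-arm Kaplan–Meier curves plus the two-sample log-rank test."""

    curves: pd.DataFrame  # arm, time, at_risk, survival
    medians: Mapping[str, Optional[float]]  # days; None if never reached
    n: Mapping[str, int]
    n_events: Mapping[str, int]
    logrank_statistic: Optional[float]
    logrank_p: Optional[float]
    _fitters: Mapping[str, KaplanMeierFitter] = field(default_factory=dict, repr=False)

    def survival_at(self, t_days: float) -> dict[str, float]:
        """KM survival estimate per arm at ``t_days``."""
        return {
            arm: float(kmf.survival_function_at_times(t_days).iloc[0])
            for arm, kmf in self._fitters.items()
        }


def km_logrank(rows: pd.DataFrame, arm_col: str = "arm") -> SurvivalComparison:
    """Kaplan–Meier estimates per arm and the log-rank test between arms.

    With zero events overall the log-rank statistic is undefined and
    reported as None (estimates only).
    """
    if rows.empty:
        raise InvalidInputError("no rows to analyse")
    curves = []
    medians: dict[str, Optional[float]] = {}
    n: dict[str, int] = {}
    n_events: dict[str, int] = {}
    fitters: dict[str, KaplanMeierFitter] = {}
    for arm, grp in rows.groupby(arm_col, sort=True):
        kmf = KaplanMeierFitter(label=str(arm))
        kmf.fit(grp["time"], event_observed=grp["event"])
        tbl = kmf.event_table
        sf = kmf.survival_function_.iloc[:, 0]
        curves.append(
            pd.DataFrame(
                {
                    "arm": str(arm),
                    "time": sf.index.to_numpy(dtype=float),
                    "at_risk": tbl["at_risk"].reindex(sf.index).to_numpy(),
                    "survival": sf.to_numpy(),
                }
            )
        )
        med = kmf.median_survival_time_
        medians[str(arm)] = None if np.isinf(med) else float(med)
        n[str(arm)] = int(len(grp))
        n_events[str(arm)] = int(grp["event"].sum())
        fitters[str(arm)] = kmf

    total_events = int(rows["event"].sum())
    if total_events == 0 or rows[arm_col].nunique() < 2:
        stat = p = None
    else:
        res = multivariate_logrank_test(rows["time"], rows[arm_col], rows["event"])
        stat, p = float(res.test_statistic), float(res.p_value)
    return SurvivalComparison(
        curves=pd.concat(curves, ignore_index=True),
        medians=medians,
        n=n,
        n_events=n_events,
        logrank_statistic=stat,
        logrank_p=p,
        _fitters=fitters,
    )


def cox_fit(
    rows: pd.DataFrame,
    covariates: Sequence[str],
    mode: str = "multivariate",
    robust: bool = False,
    cluster_col: Optional[str] = None,
) -> pd.DataFrame:
    """Cox proportional-hazards hazard-ratio table.

    ``mode='univariate'`` fits each covariate alone; ``'multivariate'``
    fits them jointly.  Categorical histology is dummy-coded with
    melanoma as the reference level.  Constant covariates are excluded
    with a note rather than breaking the fit; non-convergence is
    reported in the ``note`` column, never silently.
    """
    if mode not in ("univariate", "multivariate"):
        raise InvalidInputError(f"mode must be univariate|multivariate, got {mode!r}")
    design = _design_matrix(rows, covariates)
    groups = [[c] for c in design.columns] if mode == "univariate" else [list(design.columns)]

    out = []
    for cols in groups:
        block = pd.concat(
            [rows[["time", "event"]].reset_index(drop=True),
             design[cols].reset_index(drop=True)],
            axis=1,
        )
        if cluster_col is not None:
            block[cluster_col] = rows[cluster_col].to_numpy()
        const = [c for c in cols if block[c].nunique(dropna=True) <= 1]
        fit_cols = [c for c in cols if c not in const]
        for c in const:
            out.append(_hr_row(c, mode, note="constant covariate; excluded"))
        if not fit_cols:
            continue
        n_events = int(block["event"].sum())
        if n_events < len(fit_cols):
            for c in fit_cols:
                out.append(_hr_row(c, mode, note=f"too few events ({n_events}) to fit"))
            continue
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(
                    block[["time", "event"] + fit_cols + ([cluster_col] if cluster_col else [])],
                    duration_col="time",
                    event_col="event",
                    robust=robust or cluster_col is not None,
                    cluster_col=cluster_col,
                )
        except (ConvergenceError, ValueError) as exc:
            for c in fit_cols:
                out.append(_hr_row(c, mode, note=f"did not converge: {exc}"))
            continue
        summ = cph.summary
        for c in fit_cols:
            out.append(
                _hr_row(
                    c,
                    mode,
                    hr=float(summ.loc[c, "exp(coef)"]),
                    ci_lower=float(summ.loc[c, "exp(coef) lower 95%"]),
                    ci_upper=float(summ.loc[c, "exp(coef) upper 95%"]),
                    p=float(summ.loc[c, "p"]),
                    n=int(len(block)),
                    n_events=n_events,
                )
            )
    return pd.DataFrame(
        out,
        columns=["parameter", "mode", "hr", "ci_lower", "ci_upper", "p", "n", "n_events", "note"],
    )


def _design_matrix(rows: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "histology":
            hist = rows["histology"].astype(str).str.lower()
            for level in HISTOLOGY_LEVELS[1:]:  # melanoma is the reference
                cols[f"histology_{level}"] = (hist == level).astype(float)
        elif cov == "arm_fsrt":
            cols["arm_fsrt"] = (rows["arm"].astype(str).str.upper() == "FSRT").astype(float)
        else:
            if cov not in rows.columns:
                raise InvalidInputError(f"unknown covariate {cov!r}")
            cols[cov] = rows[cov].astype(float)
    return pd.DataFrame(cols)


def _hr_row(parameter, mode, hr=np.nan, ci_lower=np.nan, ci_upper=np.nan,
            p=np.nan, n=0, n_events=0, note=""):
    return {
        "parameter": parameter, "mode": mode, "hr": hr, "ci_lower": ci_lower,
        "ci_upper": ci_upper, "p": p, "n": n, "n_events": n_events, "note": note,
    }


def days_to_months(days: float) -> float:
    """Report-layer conversion (days / 30.44)."""
    return days / DAYS_PER_MONTH
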
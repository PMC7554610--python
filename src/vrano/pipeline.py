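"""End-to-end orchestration: filter → classify → endpoints → compare.

Inclusion rules mirror the emulated study design: lesions enter the
analysis only with a baseline volume strictly above the measurability
cutoff (>0.065 cm³, a >5 mm sphere), without concurrent whole-brain
radiotherapy, and — if WBRT was given before — with a gap of at least
56 days; prior WBRT then becomes a model covariate.  Every exclusion is
logged with its reason at lesion granularity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as vio
from .errors import InvalidInputError
from .records import LesionRecord
from .response_unidimensional import DEFAULT_1D_CONFIG, DiameterCriteriaConfig, classify_lesion_1d
from .response_volumetric import DEFAULT_CONFIG, CriteriaConfig, classify_lesion
from .survival import (
    BED_COVARIATES,
    ENDPOINTS,
    LOCAL_CONTROL_COVARIATES,
    RADIONECROSIS_COVARIATES,
    SurvivalComparison,
    build_endpoint_rows,
    cox_fit,
    km_logrank,
)

logger = logging.getLogger("vrano.pipeline")

MODES = ("volumetric", "unidimensional")


@dataclass(frozen=True)
class CohortFilterConfig:
    """Inclusion thresholds; both exactly as published and configurable."""

    min_baseline_volume: float = 0.065  # cm³, strict inequality
    min_wbrt_gap_days: float = 56.0
    exclude_concurrent_wbrt: bool = True

    def __post_init__(self) -> None:
        if not (self.min_baseline_volume > 0) or not (self.min_wbrt_gap_days > 0):
            raise InvalidInputError("filter thresholds must be positive")


def apply_inclusion_filters(
    records: Sequence[LesionRecord],
    config: CohortFilterConfig = CohortFilterConfig(),
) -> tuple[list[LesionRecord], pd.DataFrame]:
    """Split records into (included, exclusion log).

    Retains lesions with baseline volume strictly above the cutoff, no
    concurrent WBRT, any prior WBRT at least the configured gap before
    radiotherapy, and analysable follow-up (≥1 post-treatment
    measurement or a resection event).
    """
    included: list[LesionRecord] = []
    log_rows = []

    def exclude(rec: LesionRecord, reason: str) -> None:
        logger.info("excluding lesion %s: %s", rec.lesion_id, reason)
        log_rows.append({"lesion_id": rec.lesion_id, "reason": reason})

    for rec in records:
        baseline = rec.baseline()
        if baseline is None:
            exclude(rec, "no baseline measurement")
            continue
        if not (baseline.volume > config.min_baseline_volume):
            exclude(
                rec,
                f"baseline volume {baseline.volume:.4g} cm³ not > "
                f"{config.min_baseline_volume} cm³",
            )
            continue
        if config.exclude_concurrent_wbrt and rec.concurrent_wbrt:
            exclude(rec, "concurrent WBRT")
            continue
        if rec.former_wbrt and (
            rec.wbrt_gap_days is None or rec.wbrt_gap_days < config.min_wbrt_gap_days
        ):
            exclude(
                rec,
                f"prior WBRT gap {rec.wbrt_gap_days} d < {config.min_wbrt_gap_days} d",
            )
            continue
        if not rec.post_measurements() and rec.resection() is None:
            exclude(rec, "no post-treatment imaging and no resection")
            continue
        included.append(rec)
    return included, pd.DataFrame(log_rows, columns=["lesion_id", "reason"])


@dataclass
class ReportBundle:
    """Everything one pipeline run produces."""

    classifications: dict[str, pd.DataFrame]
    endpoint_rows: dict[tuple[str, str], pd.DataFrame]  # (endpoint, mode)
    survival: dict[tuple[str, str], Optional[SurvivalComparison]]
    cox: dict[str, dict[str, pd.DataFrame]]  # endpoint -> {univariate, multivariate}
    exclusions: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_analysis(
    measurements: pd.DataFrame,
    events: Optional[pd.DataFrame] = None,
    lesions: Optional[pd.DataFrame] = None,
    *,
    criteria: CriteriaConfig = DEFAULT_CONFIG,
    criteria_1d: DiameterCriteriaConfig = DEFAULT_1D_CONFIG,
    filter_config: CohortFilterConfig = CohortFilterConfig(),
    seed: Optional[int] = None,
    out_dir: Optional[str] = None,
) -> ReportBundle:
    """Full analysis: inclusion filters, both classification modes,
    the three endpoints, Kaplan–Meier/log-rank per endpoint and mode,
    and Cox hazard-ratio tables (volumetric mode) with the published
    covariate structure.  Writes CSVs plus a run manifest when
    ``out_dir`` is given."""
    records = vio.records_from_tables(measurements, lesions=lesions, events=events)
    included, exclusions = apply_inclusion_filters(records, filter_config)

    classifications: dict[str, pd.DataFrame] = {}
    results_by_mode: dict[str, list] = {}
    for mode, classify in (
        ("volumetric", lambda r: classify_lesion(r, criteria)),
        ("unidimensional", lambda r: classify_lesion_1d(r, criteria_1d)),
    ):
        results = [classify(rec) for rec in included]
        for res in results:
            if res.status.value != "controlled":
                logger.info(
                    "lesion %s (%s): %s at t=%s (basis=%s)",
                    res.lesion_id, mode, res.status.value, res.event_t,
                    res.basis.value if res.basis else "",
                )
        results_by_mode[mode] = results
        classifications[mode] = vio.classifications_to_frame(results)

    endpoint_rows: dict[tuple[str, str], pd.DataFrame] = {}
    survival: dict[tuple[str, str], Optional[SurvivalComparison]] = {}
    for mode in MODES:
        for endpoint in ENDPOINTS:
            rows = (
                build_endpoint_rows(results_by_mode[mode], included, endpoint)
                if included
                else pd.DataFrame()
            )
            endpoint_rows[(endpoint, mode)] = rows
            survival[(endpoint, mode)] = km_logrank(rows) if len(rows) else None

    cox: dict[str, dict[str, pd.DataFrame]] = {}
    cox_covariates = {
        "local_progression": LOCAL_CONTROL_COVARIATES,
        "radionecrosis_any": RADIONECROSIS_COVARIATES,
        "radionecrosis_grade4": RADIONECROSIS_COVARIATES,
    }
    for endpoint, covs in cox_covariates.items():
        rows = endpoint_rows[(endpoint, "volumetric")]
        if len(rows) == 0 or rows["event"].sum() == 0:
            cox[endpoint] = {"univariate": pd.DataFrame(), "multivariate": pd.DataFrame()}
            continue
        cox[endpoint] = {
            "univariate": cox_fit(rows, list(covs) + BED_COVARIATES, mode="univariate"),
            "multivariate": cox_fit(rows, covs, mode="multivariate"),
        }

    manifest = {
        "seed": seed,
        "config_hash": _config_hash(criteria, criteria_1d, filter_config),
        "n_input_lesions": len(records),
        "n_included": len(included),
        "n_excluded": len(exclusions),
        "n_events": {
            f"{endpoint}/{mode}": int(endpoint_rows[(endpoint, mode)]["event"].sum())
            if len(endpoint_rows[(endpoint, mode)])
            else 0
            for endpoint in ENDPOINTS
            for mode in MODES
        },
    }
    bundle = ReportBundle(
        classifications=classifications,
        endpoint_rows=endpoint_rows,
        survival=survival,
        cox=cox,
        exclusions=exclusions,
        manifest=manifest,
    )
    if out_dir is not None:
        write_report(bundle, out_dir)
    return bundle


def _config_hash(*configs) -> str:
    payload = json.dumps([asdict(c) for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_report(bundle: ReportBundle, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mode, df in bundle.classifications.items():
        vio.write_table(df, out / f"classifications_{mode}.csv")
    vio.write_table(bundle.exclusions, out / "exclusions.csv")
    for (endpoint, mode), df in bundle.endpoint_rows.items():
        if len(df):
            vio.write_table(df, out / f"endpoint_{endpoint}_{mode}.csv")
    logrank_rows = []
    for (endpoint, mode), comp in bundle.survival.items():
        if comp is None:
            continue
        vio.write_table(comp.curves, out / f"km_{endpoint}_{mode}.csv")
        logrank_rows.append(
            {
                "endpoint": endpoint,
                "mode": mode,
                "logrank_statistic": comp.logrank_statistic,
                "logrank_p": comp.logrank_p,
                **{f"median_days_{arm}": m for arm, m in comp.medians.items()},
                **{f"events_{arm}": v for arm, v in comp.n_events.items()},
            }
        )
    if logrank_rows:
        vio.write_table(pd.DataFrame(logrank_rows), out / "logrank_summary.csv")
    for endpoint, tables in bundle.cox.items():
        for mode, df in tables.items():
            if len(df):
                vio.write_table(df, out / f"cox_{endpoint}_{mode}.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    return out
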
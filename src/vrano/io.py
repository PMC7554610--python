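"""Plain-CSV input/output and record assembly.

Schemas (long format, one row per observation):

* measurements: lesion_id, t_days, volume_cm3 [, patient_id,
  diameter_mm, intervening_treatment (0/1)]
* events: lesion_id, event_type {resection}, t_days, histology
  {tumor, necrosis, both}
* lesions (metadata): lesion_id [, patient_id, arm, n_fractions,
  dose_per_fraction, histology, former_wbrt, wbrt_gap_days,
  concurrent_wbrt, checkpoint_inhibitor]
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .errors import SchemaError
from .radbio import FractionationScheme
from .records import ClinicalEvent, Histology, LesionRecord, VolumeMeasurement
from .response_unidimensional import DiameterCriteriaConfig
from .response_volumetric import CriteriaConfig

MEASUREMENT_COLUMNS = ("lesion_id", "t_days", "volume_cm3")
EVENT_COLUMNS = ("lesion_id", "event_type", "t_days", "histology")


def _require(df: pd.DataFrame, columns, what: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing required column '{col}'")


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, MEASUREMENT_COLUMNS, "measurements")
    return df


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, EVENT_COLUMNS, "events")
    return df


def read_lesions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ("lesion_id",), "lesions")
    return df


def _opt_float(value) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _opt_bool(value) -> bool:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return False
    return bool(int(value)) if not isinstance(value, bool) else value


def records_from_tables(
    measurements: pd.DataFrame,
    lesions: Optional[pd.DataFrame] = None,
    events: Optional[pd.DataFrame] = None,
) -> list[LesionRecord]:
    """Assemble one :class:`LesionRecord` per lesion from long tables."""
    _require(measurements, MEASUREMENT_COLUMNS, "measurements")
    if events is not None and not events.empty:
        _require(events, EVENT_COLUMNS, "events")
    meta = {}
    if lesions is not None and not lesions.empty:
        _require(lesions, ("lesion_id",), "lesions")
        meta = {str(row["lesion_id"]): row for _, row in lesions.iterrows()}
    event_map: dict[str, list[ClinicalEvent]] = {}
    if events is not None:
        for _, row in events.iterrows():
            event_map.setdefault(str(row["lesion_id"]), []).append(
                ClinicalEvent(
                    event_type=str(row["event_type"]),
                    t=float(row["t_days"]),
                    histology=Histology(str(row["histology"]))
                    if not pd.isna(row["histology"])
                    else None,
                )
            )

    records = []
    lesion_order = measurements["lesion_id"].astype(str).drop_duplicates().tolist()
    grouped = measurements.groupby(measurements["lesion_id"].astype(str), sort=False)
    for lesion_id in lesion_order:
        grp = grouped.get_group(lesion_id).sort_values("t_days")
        ms = [
            VolumeMeasurement(
                t=float(r["t_days"]),
                volume=float(r["volume_cm3"]),
                diameter=_opt_float(r.get("diameter_mm")),
                intervening_treatment=_opt_bool(r.get("intervening_treatment")),
            )
            for _, r in grp.iterrows()
        ]
        m = meta.get(lesion_id)
        scheme = None
        if m is not None and _opt_float(m.get("n_fractions")) and _opt_float(
            m.get("dose_per_fraction")
        ):
            scheme = FractionationScheme(
                int(m["n_fractions"]), float(m["dose_per_fraction"])
            )
        records.append(
            LesionRecord(
                lesion_id=lesion_id,
                measurements=ms,
                events=tuple(event_map.get(lesion_id, [])),
                patient_id=str(m["patient_id"]) if m is not None and "patient_id" in m else None,
                arm=str(m["arm"]) if m is not None and "arm" in m else None,
                scheme=scheme,
                histology=str(m["histology"]) if m is not None and "histology" in m else None,
                former_wbrt=_opt_bool(m.get("former_wbrt")) if m is not None else False,
                wbrt_gap_days=_opt_float(m.get("wbrt_gap_days")) if m is not None else None,
                concurrent_wbrt=_opt_bool(m.get("concurrent_wbrt")) if m is not None else False,
                checkpoint_inhibitor=_opt_bool(m.get("checkpoint_inhibitor"))
                if m is not None
                else False,
            )
        )
    return records


def classifications_to_frame(results) -> pd.DataFrame:
    rows = [
        {
            "lesion_id": r.lesion_id,
            "status": r.status.value,
            "event_t_days": r.event_t if r.event_t is not None else "",
            "reference_volume_at_event": r.reference_volume_at_event
            if r.reference_volume_at_event is not None
            else "",
            "trigger_volume": r.trigger_volume if r.trigger_volume is not None else "",
            "basis": r.basis.value if r.basis is not None else "",
            "grade4": int(r.grade4),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["lesion_id", "status", "event_t_days", "reference_volume_at_event",
                 "trigger_volume", "basis", "grade4"],
    )


def load_criteria_config(path) -> CriteriaConfig:
    return CriteriaConfig(**_load_yaml_section(path, "volumetric_criteria"))


def load_diameter_criteria_config(path) -> DiameterCriteriaConfig:
    return DiameterCriteriaConfig(**_load_yaml_section(path, "unidimensional_criteria"))


def _load_yaml_section(path, section: str) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if section in data:
        return dict(data[section])
    return dict(data)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
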
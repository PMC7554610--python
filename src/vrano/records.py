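"""Domain types shared across the response, survival and pipeline modules."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .errors import DataOrderError, IncompleteEventError, InvalidInputError
from .radbio import FractionationScheme


class Status(str, Enum):
    """Adjudicated lesion status."""

    CONTROLLED = "controlled"
    PROGRESSION = "progression"
    RADIONECROSIS = "radionecrosis"
    PROGRESSION_AND_RADIONECROSIS = "progression_and_radionecrosis"


class Basis(str, Enum):
    """What a non-controlled classification rests on."""

    VOLUMETRIC = "volumetric"
    HISTOLOGIC = "histologic"
    BOTH = "both"


class Histology(str, Enum):
    """Histologic finding of a resection specimen."""

    TUMOR = "tumor"
    NECROSIS = "necrosis"
    BOTH = "both"


@dataclass(frozen=True)
class VolumeMeasurement:
    """One timed observation of a lesion.

    ``t`` is in days from the start of stereotactic radiotherapy
    (negative for the baseline MRI), ``volume`` in cm³, ``diameter``
    (longest axial diameter, optional) in mm.  ``intervening_treatment``
    flags any new local or systemic therapy delivered between the
    previous measurement and this one.
    """

    t: float
    volume: float
    diameter: Optional[float] = None
    intervening_treatment: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.volume) or self.volume < 0:
            raise InvalidInputError(f"volume must be finite and ≥ 0, got {self.volume!r}")
        if self.diameter is not None and (
            not math.isfinite(self.diameter) or self.diameter < 0
        ):
            raise InvalidInputError(f"diameter must be finite and ≥ 0, got {self.diameter!r}")


@dataclass(frozen=True)
class ClinicalEvent:
    """A dated clinical intervention; currently only resection is modelled."""

    event_type: str
    t: float
    histology: Optional[Histology] = None

    def __post_init__(self) -> None:
        if self.event_type == "resection" and self.histology is None:
            raise IncompleteEventError(
                f"resection event at t={self.t} has no histology label"
            )


@dataclass
class LesionRecord:
    """A lesion's full trajectory plus treatment metadata and events."""

    lesion_id: str
    measurements: Sequence[VolumeMeasurement]
    events: Sequence[ClinicalEvent] = field(default_factory=tuple)
    patient_id: Optional[str] = None
    arm: Optional[str] = None  # "SRS" | "FSRT"
    scheme: Optional[FractionationScheme] = None
    histology: Optional[str] = None  # primary-tumor histology
    former_wbrt: bool = False
    wbrt_gap_days: Optional[float] = None
    concurrent_wbrt: bool = False
    checkpoint_inhibitor: bool = False

    def sorted_measurements(self) -> list[VolumeMeasurement]:
        """Measurements in time order; rejects duplicate timestamps."""
        ms = list(self.measurements)
        for a, b in zip(ms, ms[1:]):
            if not (b.t > a.t):
                raise DataOrderError(
                    f"lesion {self.lesion_id}: measurements not strictly ordered "
                    f"in time at t={a.t} / t={b.t}"
                )
        return ms

    def baseline(self) -> Optional[VolumeMeasurement]:
        pre = [m for m in self.measurements if m.t < 0]
        if len(pre) > 1:
            raise DataOrderError(
                f"lesion {self.lesion_id}: {len(pre)} baseline (t<0) measurements; "
                "expected exactly one"
            )
        return pre[0] if pre else None

    def post_measurements(self) -> list[VolumeMeasurement]:
        return [m for m in self.sorted_measurements() if m.t >= 0]

    def resection(self) -> Optional[ClinicalEvent]:
        res = sorted((e for e in self.events if e.event_type == "resection"),
                     key=lambda e: e.t)
        return res[0] if res else None

    def last_imaging_t(self) -> Optional[float]:
        if not self.measurements:
            return None
        return max(m.t for m in self.measurements)


@dataclass(frozen=True)
class ClassificationResult:
    """Adjudicated status of one lesion.

    ``event_t`` is present iff the status is not controlled; for a
    volumetric event it is the date of the first MRI fulfilling both
    progression thresholds, for a resection without prior volumetric
    progression it is the intervention date.  ``grade4`` marks
    radionecrosis requiring resection (histologically proven).
    """

    lesion_id: str
    status: Status
    event_t: Optional[float] = None
    reference_volume_at_event: Optional[float] = None
    trigger_volume: Optional[float] = None
    basis: Optional[Basis] = None
    grade4: bool = False
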
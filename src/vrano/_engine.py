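"""Shared scan/reclassification engine behind both response classifiers.

The volumetric and unidimensional criteria differ only in which quantity
they threshold (volume in cm³ vs longest diameter in mm) and in the
threshold values themselves.  The adjudication architecture is
identical:

1. walk the post-treatment measurements in time order, testing each
   against the running nadir (minimum of baseline and all strictly
   earlier post-treatment values); the first measurement passing the
   progression test sets the candidate event;
2. if the remaining follow-up shows spontaneous regression — a later
   measurement at or below the nadir reference active at the trigger,
   or a partial-response-depth reduction relative to baseline, with no
   intervening treatment anywhere between trigger and regression — the
   event is reclassified as radionecrosis;
3. a resection event overrides the imaging-based status with histology
   (viable tumor → progression, necrosis → radionecrosis, both → both);
   necrosis requiring resection is grade IV.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

from .errors import InvalidInputError, MissingBaselineError
from .records import (
    Basis,
    ClassificationResult,
    Histology,
    LesionRecord,
    Status,
    VolumeMeasurement,
)

ValueFn = Callable[[VolumeMeasurement], float]
ProgressionFn = Callable[[float, float], bool]
# (post-trigger trajectory, reference at trigger, baseline value) -> regressed?
RegressionFn = Callable[[Sequence[VolumeMeasurement], float, float], bool]

_HISTOLOGY_STATUS = {
    Histology.TUMOR: Status.PROGRESSION,
    Histology.NECROSIS: Status.RADIONECROSIS,
    Histology.BOTH: Status.PROGRESSION_AND_RADIONECROSIS,
}


def classify_trajectory(
    record: LesionRecord,
    value_of: ValueFn,
    progression_fn: ProgressionFn,
    regression_fn: RegressionFn,
) -> ClassificationResult:
    ms = record.sorted_measurements()  # raises on unordered/tied timestamps
    resection = record.resection()
    baseline = record.baseline()

    if baseline is None:
        if resection is not None:
            return _histologic_result(record, resection, None, None, None)
        raise MissingBaselineError(
            f"lesion {record.lesion_id}: no baseline (t<0) measurement"
        )

    post = [m for m in ms if m.t >= 0]
    if resection is not None:
        post = [m for m in post if m.t <= resection.t]
    if not post and resection is None:
        raise InvalidInputError(
            f"lesion {record.lesion_id}: no post-treatment measurement "
            "and no resection event"
        )

    baseline_value = value_of(baseline)
    nadir = baseline_value
    trigger: Optional[VolumeMeasurement] = None
    reference_at_trigger: Optional[float] = None
    trigger_index = -1
    for i, m in enumerate(post):
        v = value_of(m)
        if progression_fn(v, nadir):
            trigger, reference_at_trigger, trigger_index = m, nadir, i
            break
        nadir = min(nadir, v)

    regressed = False
    if trigger is not None:
        regressed = regression_fn(
            post[trigger_index + 1 :], reference_at_trigger, baseline_value
        )

    if resection is not None:
        return _histologic_result(
            record,
            resection,
            trigger,
            reference_at_trigger,
            value_of(trigger) if trigger is not None else None,
        )

    if trigger is None:
        return ClassificationResult(record.lesion_id, Status.CONTROLLED)

    return ClassificationResult(
        lesion_id=record.lesion_id,
        status=Status.RADIONECROSIS if regressed else Status.PROGRESSION,
        event_t=trigger.t,
        reference_volume_at_event=reference_at_trigger,
        trigger_volume=value_of(trigger),
        basis=Basis.VOLUMETRIC,
    )


def scan_regression(
    post_event_trajectory: Sequence[VolumeMeasurement],
    value_of: ValueFn,
    qualifies: Callable[[float], bool],
) -> bool:
    """True iff some later measurement qualifies as spontaneous regression.

    Any interval flagged with intervening treatment breaks the chain:
    the flagged measurement and everything after it are disqualified,
    because the treatment could explain the shrinkage.
    """
    for m in post_event_trajectory:
        if m.intervening_treatment:
            return False
        if qualifies(value_of(m)):
            return True
    return False


def _histologic_result(
    record: LesionRecord,
    resection,
    trigger,
    reference_at_trigger,
    trigger_value,
) -> ClassificationResult:
    status = _HISTOLOGY_STATUS[resection.histology]
    return ClassificationResult(
        lesion_id=record.lesion_id,
        status=status,
        event_t=trigger.t if trigger is not None else resection.t,
        reference_volume_at_event=reference_at_trigger,
        trigger_volume=trigger_value,
        basis=Basis.BOTH if trigger is not None else Basis.HISTOLOGIC,
        grade4=resection.histology in (Histology.NECROSIS, Histology.BOTH),
    )
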
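"""Conventional unidimensional (longest-diameter) RANO-BM comparator.

Progression: ≥20 % increase in longest diameter over the nadir
reference, with a minimum absolute increase of 3 mm required while the
reference is below 10 mm.  Radionecrosis adjudication mirrors the
volumetric classifier: spontaneous regression back to the nadir
reference, or a partial response (≥30 % diameter reduction relative to
baseline), without intervening treatment, reclassifies the event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._engine import classify_trajectory, scan_regression
from .errors import (
    IncompleteDataError,
    InvalidInputError,
    InvalidReferenceError,
)
from .records import ClassificationResult, LesionRecord, VolumeMeasurement


@dataclass(frozen=True)
class DiameterCriteriaConfig:
    """Thresholds of the unidimensional criteria (diameters in mm)."""

    rel_progression_threshold: float = 0.20
    abs_progression_threshold_mm: float = 3.0
    small_lesion_cutoff_mm: float = 10.0
    pr_reduction_threshold: float = 0.30

    def __post_init__(self) -> None:
        for name in (
            "rel_progression_threshold",
            "abs_progression_threshold_mm",
            "small_lesion_cutoff_mm",
            "pr_reduction_threshold",
        ):
            if not (getattr(self, name) > 0):
                raise InvalidInputError(f"{name} must be > 0, got {getattr(self, name)!r}")


DEFAULT_1D_CONFIG = DiameterCriteriaConfig()


def progression_test_1d(
    diameter: float, reference: float, config: DiameterCriteriaConfig = DEFAULT_1D_CONFIG
) -> bool:
    """True iff ``diameter`` ≥ reference × 1.20 and, for references below
    the small-lesion cutoff (10 mm), the absolute increase is ≥ 3 mm."""
    if not (reference > 0):
        raise InvalidReferenceError(f"reference diameter must be > 0, got {reference!r}")
    rel_ok = diameter >= reference * (1.0 + config.rel_progression_threshold)
    abs_ok = (
        reference >= config.small_lesion_cutoff_mm
        or diameter - reference >= config.abs_progression_threshold_mm
    )
    return rel_ok and abs_ok


def spontaneous_regression_test_1d(
    post_event_trajectory: Sequence[VolumeMeasurement],
    reference: float,
    baseline: float,
    config: DiameterCriteriaConfig = DEFAULT_1D_CONFIG,
) -> bool:
    if not (reference > 0) or not (baseline > 0):
        raise InvalidReferenceError(
            f"reference and baseline must be > 0, got ({reference!r}, {baseline!r})"
        )
    pr_level = baseline * (1.0 - config.pr_reduction_threshold)
    return scan_regression(
        post_event_trajectory,
        value_of=_diameter_of,
        qualifies=lambda d: d <= reference or d <= pr_level,
    )


def classify_lesion_1d(
    record: LesionRecord, config: DiameterCriteriaConfig = DEFAULT_1D_CONFIG
) -> ClassificationResult:
    """Diameter-based adjudication; same scan/reclassification
    architecture as the volumetric classifier."""

    def regression(post, reference, baseline_value):
        return spontaneous_regression_test_1d(post, reference, baseline_value, config)

    return classify_trajectory(
        record,
        value_of=_diameter_of,
        progression_fn=lambda d, ref: progression_test_1d(d, ref, config),
        regression_fn=regression,
    )


def _diameter_of(m: VolumeMeasurement) -> float:
    if m.diameter is None:
        raise IncompleteDataError(f"measurement at t={m.t} has no diameter")
    return m.diameter
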
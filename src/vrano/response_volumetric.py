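"""Volumetric response classification for irradiated brain metastases.

The unidimensional RANO-BM criteria are translated to volumes through
spherical geometry: a ≥20 % diameter increase of a sphere corresponds to
a ≥72.8 % volume increase, so volumetric progression requires the volume
to reach ≥172.8 % of the nadir reference (minimum of baseline and all
earlier post-treatment volumes).  Because RANO-BM treats lesions of
5–10 mm as unchanged unless the diameter grows by ≥3 mm, an additional
absolute increase of ≥0.2 cm³ — the volume a 5 mm sphere gains when
growing to 8 mm — is required as well.

A lesion that fulfils these progression criteria but subsequently shows
spontaneous regression — return to the nadir/baseline volume, or a
volumetric partial response (≥65 % volume reduction relative to
baseline) — without any intervening local or systemic treatment is
reclassified as radionecrosis.  Resection histology overrides the
imaging-based call; necrosis requiring resection is grade IV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from ._engine import classify_trajectory, scan_regression
from .errors import InvalidInputError, InvalidReferenceError, MissingBaselineError
from .radbio import sphere_volume
from .records import ClassificationResult, LesionRecord, VolumeMeasurement


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds of the volumetric progression/regression criteria.

    ``rel_progression_threshold`` is the fractional volume increase over
    the nadir reference required for progression (default 0.728, the
    spherical equivalent of +20 % diameter).  ``abs_progression_threshold``
    is the additional absolute increase in cm³ (default 0.2, a 5→8 mm
    sphere).  ``pr_reduction_threshold`` is the partial-response depth
    relative to baseline used by the spontaneous-regression clause
    (default 0.65).  When ``apply_abs_threshold_to_all_sizes`` is False
    the absolute guard is only enforced while the reference is below the
    volume of a 10 mm sphere (≈0.524 cm³), mirroring the small-lesion
    clause of the unidimensional criteria.
    """

    rel_progression_threshold: float = 0.728
    abs_progression_threshold: float = 0.2
    pr_reduction_threshold: float = 0.65
    apply_abs_threshold_to_all_sizes: bool = True

    def __post_init__(self) -> None:
        for name in (
            "rel_progression_threshold",
            "abs_progression_threshold",
            "pr_reduction_threshold",
        ):
            if not (getattr(self, name) > 0):
                raise InvalidInputError(f"{name} must be > 0, got {getattr(self, name)!r}")


_SMALL_LESION_VOLUME_CM3 = sphere_volume(10.0)

DEFAULT_CONFIG = CriteriaConfig()


def nadir_reference(
    trajectory: Sequence[VolumeMeasurement], t: float
) -> float:
    """Reference volume at time ``t``: minimum of baseline and all
    post-treatment volumes strictly before ``t``.

    Non-increasing as ``t`` advances.
    """
    baseline = [m for m in trajectory if m.t < 0]
    if not baseline:
        raise MissingBaselineError("trajectory has no baseline (t<0) measurement")
    if len(baseline) > 1:
        raise MissingBaselineError(f"{len(baseline)} baseline measurements; expected one")
    if t < baseline[0].t:
        raise InvalidInputError(f"t={t} precedes the baseline at t={baseline[0].t}")
    prior = [m.volume for m in trajectory if 0 <= m.t < t]
    return min([baseline[0].volume] + prior)


def progression_test(
    volume: float, reference: float, config: CriteriaConfig = DEFAULT_CONFIG
) -> bool:
    """True iff ``volume`` meets both the relative (≥ reference × 1.728)
    and the absolute (≥ reference + 0.2 cm³) progression thresholds.
    Threshold equality counts as meeting the criterion.
    """
    if not (reference > 0):
        raise InvalidReferenceError(f"reference volume must be > 0, got {reference!r}")
    rel_ok = volume >= reference * (1.0 + config.rel_progression_threshold)
    if config.apply_abs_threshold_to_all_sizes or reference < _SMALL_LESION_VOLUME_CM3:
        abs_ok = volume - reference >= config.abs_progression_threshold
    else:
        abs_ok = True
    return rel_ok and abs_ok


def spontaneous_regression_test(
    post_event_trajectory: Sequence[VolumeMeasurement],
    reference: float,
    baseline: float,
    config: CriteriaConfig = DEFAULT_CONFIG,
) -> bool:
    """True iff a later measurement regresses to the nadir reference or to
    a partial-response volume (≤ baseline × 0.35 by default) with no
    intervening treatment between the trigger and that measurement."""
    if not (reference > 0) or not (baseline > 0):
        raise InvalidReferenceError(
            f"reference and baseline must be > 0, got ({reference!r}, {baseline!r})"
        )
    pr_level = baseline * (1.0 - config.pr_reduction_threshold)
    return scan_regression(
        post_event_trajectory,
        value_of=lambda m: m.volume,
        qualifies=lambda v: v <= reference or v <= pr_level,
    )


def classify_lesion(
    record: LesionRecord, config: CriteriaConfig = DEFAULT_CONFIG
) -> ClassificationResult:
    """Adjudicate one lesion as controlled / progression / radionecrosis.

    Post-treatment measurements are scanned in time order; the first one
    passing :func:`progression_test` against the running nadir dates the
    event (``event_t`` = that MRI's time).  The remaining follow-up is
    then tested with :func:`spontaneous_regression_test`: if it holds,
    the event is radionecrosis, else progression.  Resection histology
    overrides the imaging call; a lesion resected without prior
    volumetric progression is dated at the intervention.
    """

    def regression(post, reference, baseline_value):
        return spontaneous_regression_test(post, reference, baseline_value, config)

    return classify_trajectory(
        record,
        value_of=lambda m: m.volume,
        progression_fn=lambda v, ref: progression_test(v, ref, config),
        regression_fn=regression,
    )
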
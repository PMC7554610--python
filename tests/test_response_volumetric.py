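"""Volumetric classifier: thresholds, nadir tracking, reclassification."""

import pytest

from vrano.errors import (
    DataOrderError,
    IncompleteEventError,
    InvalidInputError,
    InvalidReferenceError,
    MissingBaselineError,
)
from vrano.records import (
    Basis,
    ClinicalEvent,
    Histology,
    LesionRecord,
    Status,
    VolumeMeasurement,
)
from vrano.response_volumetric import (
    CriteriaConfig,
    classify_lesion,
    nadir_reference,
    progression_test,
    spontaneous_regression_test,
)


def record(volumes_by_t, lesion_id="L1", events=(), **kwargs):
    ms = [VolumeMeasurement(t=t, volume=v) for t, v in volumes_by_t]
    return LesionRecord(lesion_id=lesion_id, measurements=ms, events=events, **kwargs)


class TestNadirReference:
    def test_minimum_of_prior_values(self):
        traj = [VolumeMeasurement(-8, 1.0), VolumeMeasurement(60, 0.5),
                VolumeMeasurement(150, 0.9)]
        assert nadir_reference(traj, 150) == 0.5

    def test_baseline_is_reference_without_post_measurements(self):
        traj = [VolumeMeasurement(-8, 1.0)]
        assert nadir_reference(traj, 60) == 1.0

    def test_running_minimum(self):
        traj = [VolumeMeasurement(-8, 0.3), VolumeMeasurement(42, 0.4),
                VolumeMeasurement(133, 0.2), VolumeMeasurement(224, 0.6)]
        assert nadir_reference(traj, 300) == 0.2

    def test_non_increasing_in_time(self):
        traj = [VolumeMeasurement(-8, 1.0), VolumeMeasurement(42, 0.8),
                VolumeMeasurement(133, 0.4), VolumeMeasurement(224, 1.5)]
        refs = [nadir_reference(traj, t) for t in (0, 100, 200, 300)]
        assert refs == sorted(refs, reverse=True)

    def test_missing_baseline_rejected(self):
        with pytest.raises(MissingBaselineError):
            nadir_reference([VolumeMeasurement(42, 1.0)], 100)


class TestProgressionTest:
    def test_both_thresholds_met(self):
        assert progression_test(0.9, 0.5)  # ratio 1.8, increment 0.4

    def test_small_lesion_guard_blocks_relative_only_increase(self):
        assert not progression_test(0.13, 0.07)  # ratio 1.857, increment 0.06

    def test_unchanged_volume_is_not_progression(self):
        assert not progression_test(0.5, 0.5)

    def test_threshold_equality_counts(self):
        assert progression_test(0.5 * 1.728, 0.5)  # ratio exactly 1.728
        assert progression_test(1.728, 1.0)

    def test_small_lesion_guard_active_in_both_config_variants(self):
        # below a 10 mm-sphere reference the absolute rule always applies
        config = CriteriaConfig(apply_abs_threshold_to_all_sizes=False)
        assert not progression_test(0.13, 0.07, config)
        assert progression_test(1.04, 0.6, config)  # ratio 1.733, ref above cutoff

    def test_invalid_reference(self):
        with pytest.raises(InvalidReferenceError):
            progression_test(1.0, 0.0)


class TestSpontaneousRegression:
    def test_regression_to_pr_level(self):
        post = [VolumeMeasurement(300, 0.3)]
        assert spontaneous_regression_test(post, reference=1.0, baseline=1.0)

    def test_intervening_treatment_disqualifies(self):
        post = [VolumeMeasurement(300, 0.3, intervening_treatment=True)]
        assert not spontaneous_regression_test(post, reference=1.0, baseline=1.0)

    def test_no_sufficient_regression(self):
        post = [VolumeMeasurement(300, 1.2), VolumeMeasurement(400, 1.3)]
        assert not spontaneous_regression_test(post, reference=1.0, baseline=1.0)

    def test_regression_to_nadir_reference(self):
        post = [VolumeMeasurement(300, 0.45)]
        assert spontaneous_regression_test(post, reference=0.5, baseline=10.0)


class TestClassifyLesion:
    def test_decline_then_sustained_regrowth_is_progression(self):
        rec = record([(-8, 1.0), (42, 0.6), (133, 0.95), (224, 1.25), (315, 1.6)])
        res = classify_lesion(rec)
        assert res.status is Status.PROGRESSION
        assert res.event_t == 224  # first MRI with ≥x1.728 of nadir 0.6 and +0.2
        assert res.reference_volume_at_event == 0.6
        assert res.basis is Basis.VOLUMETRIC

    def test_pulse_with_untreated_regression_is_radionecrosis(self):
        rec = record([(-8, 1.0), (42, 1.8), (133, 0.3)])
        res = classify_lesion(rec)
        assert res.status is Status.RADIONECROSIS
        assert res.event_t == 42
        assert res.basis is Basis.VOLUMETRIC

    def test_monotone_shrinkage_is_controlled(self):
        rec = record([(-8, 1.0), (42, 0.7), (133, 0.4), (224, 0.2)])
        res = classify_lesion(rec)
        assert res.status is Status.CONTROLLED
        assert res.event_t is None

    def test_treated_regression_stays_progression(self):
        ms = [VolumeMeasurement(-8, 1.0), VolumeMeasurement(42, 1.8),
              VolumeMeasurement(133, 0.3, intervening_treatment=True)]
        res = classify_lesion(LesionRecord("L1", ms))
        assert res.status is Status.PROGRESSION

    def test_resection_histology_overrides_imaging(self):
        events = (ClinicalEvent("resection", 200.0, Histology.NECROSIS),)
        rec = record([(-8, 1.0), (42, 1.8)], events=events)
        res = classify_lesion(rec)
        assert res.status is Status.RADIONECROSIS
        assert res.grade4
        assert res.basis is Basis.BOTH
        assert res.event_t == 42  # prior volumetric progression keeps the MRI date

    def test_resection_without_prior_progression_dated_at_intervention(self):
        events = (ClinicalEvent("resection", 200.0, Histology.TUMOR),)
        rec = record([(-8, 1.0), (42, 0.9)], events=events)
        res = classify_lesion(rec)
        assert res.status is Status.PROGRESSION
        assert res.event_t == 200.0
        assert res.basis is Basis.HISTOLOGIC
        assert not res.grade4

    def test_mixed_histology_is_both(self):
        events = (ClinicalEvent("resection", 100.0, Histology.BOTH),)
        rec = record([(-8, 1.0), (42, 0.9)], events=events)
        res = classify_lesion(rec)
        assert res.status is Status.PROGRESSION_AND_RADIONECROSIS
        assert res.grade4

    def test_duplicate_timestamps_rejected(self):
        rec = record([(-8, 1.0), (42, 0.9), (42, 1.0)])
        with pytest.raises(DataOrderError):
            classify_lesion(rec)

    def test_missing_baseline_rejected(self):
        rec = record([(42, 0.9), (133, 1.0)])
        with pytest.raises(MissingBaselineError):
            classify_lesion(rec)

    def test_baseline_without_followup_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_lesion(record([(-8, 1.0)]))

    def test_resection_requires_histology(self):
        with pytest.raises(IncompleteEventError):
            ClinicalEvent("resection", 100.0, None)


class TestInvariants:
    base = [(-8, 1.0), (42, 0.6), (133, 0.95), (224, 1.25)]

    def test_appending_followup_never_changes_event_time(self):
        rec = record(self.base)
        first = classify_lesion(rec)
        assert first.status is Status.PROGRESSION and first.event_t == 224
        for extra in [(300, 2.0), (380, 0.2)]:
            rec = record(self.base + [extra] if extra[0] == 300 else
                         self.base + [(300, 2.0), extra])
            res = classify_lesion(rec)
            assert res.event_t == 224
            assert res.status in (Status.PROGRESSION, Status.RADIONECROSIS)

    def test_late_untreated_regression_reclassifies_to_radionecrosis(self):
        res = classify_lesion(record(self.base + [(380, 0.2)]))
        assert res.status is Status.RADIONECROSIS
        assert res.event_t == 224

    def test_rescaling_volumes_and_absolute_threshold_together(self):
        rec = record(self.base + [(380, 0.2)])
        ref = classify_lesion(rec)
        for k in (1e-2, 10.0, 1e3):
            scaled = record([(t, v * k) for t, v in self.base + [(380, 0.2)]])
            config = CriteriaConfig(abs_progression_threshold=0.2 * k)
            res = classify_lesion(scaled, config)
            assert res.status is ref.status
            assert res.event_t == ref.event_t

    def test_trigger_satisfies_both_threshold_inequalities(self):
        res = classify_lesion(record(self.base))
        ref, trig = res.reference_volume_at_event, res.trigger_volume
        assert trig >= ref * 1.728
        assert trig - ref >= 0.2

    def test_determinism(self):
        rec = record(self.base + [(380, 0.2)])
        assert classify_lesion(rec) == classify_lesion(rec)
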
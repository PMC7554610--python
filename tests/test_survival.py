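"""Endpoint construction, Kaplan–Meier/log-rank and Cox machinery."""

import numpy as np
import pandas as pd
import pytest

from vrano.errors import InconsistentRecordError
from vrano.records import (
    ClinicalEvent,
    Histology,
    LesionRecord,
    VolumeMeasurement,
)
from vrano.response_volumetric import classify_lesion
from vrano.survival import build_endpoint_rows, cox_fit, km_logrank
from vrano.synthetic_data import simulate_two_arm_exponential


def make_record(volumes_by_t, lesion_id="L1", events=(), **kwargs):
    ms = [VolumeMeasurement(t=t, volume=v) for t, v in volumes_by_t]
    kwargs.setdefault("arm", "SRS")
    kwargs.setdefault("histology", "melanoma")
    return LesionRecord(lesion_id=lesion_id, measurements=ms, events=events, **kwargs)


def hand_logrank(times, groups, events):
    """Independent hypergeometric tally of the two-sample log-rank test."""
    times, groups, events = map(np.asarray, (times, groups, events))
    labels = np.unique(groups)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestBuildEndpointRows:
    def test_controlled_lesion_censored_at_last_imaging(self):
        rec = make_record([(-8, 1.0), (400, 0.5)])
        rows = build_endpoint_rows([classify_lesion(rec)], [rec], "local_progression")
        assert rows.loc[0, "time"] == 400 and not rows.loc[0, "event"]

    def test_progression_event_censors_radionecrosis_endpoint(self):
        rec = make_record([(-8, 1.0), (150, 1.95), (300, 2.5)])
        cls = [classify_lesion(rec)]
        lp = build_endpoint_rows(cls, [rec], "local_progression")
        rn = build_endpoint_rows(cls, [rec], "radionecrosis_any")
        assert lp.loc[0, "event"] and lp.loc[0, "time"] == 150
        assert not rn.loc[0, "event"] and rn.loc[0, "time"] == 300

    def test_resected_radionecrosis_dated_at_intervention_for_grade4(self):
        events = (ClinicalEvent("resection", 210.0, Histology.NECROSIS),)
        rec = make_record([(-8, 1.0), (150, 1.95)], events=events)
        cls = [classify_lesion(rec)]
        g4 = build_endpoint_rows(cls, [rec], "radionecrosis_grade4")
        rn = build_endpoint_rows(cls, [rec], "radionecrosis_any")
        assert g4.loc[0, "event"] and g4.loc[0, "time"] == 210.0
        assert rn.loc[0, "event"] and rn.loc[0, "time"] == 150.0  # first MRI

    def test_bed_covariates_recomputed_from_scheme(self):
        from vrano.radbio import FractionationScheme

        rec = make_record([(-8, 1.0), (400, 0.5)], scheme=FractionationScheme(10, 4.0))
        rows = build_endpoint_rows([classify_lesion(rec)], [rec], "local_progression")
        assert rows.loc[0, "bed12_lqc"] == pytest.approx(52.35, abs=0.01)
        assert rows.loc[0, "bed2_lq"] == pytest.approx(120.0)

    def test_event_after_last_imaging_rejected(self):
        from vrano.records import ClassificationResult, Status, Basis

        rec = make_record([(-8, 1.0), (150, 1.95)])
        bad = ClassificationResult("L1", Status.PROGRESSION, event_t=999.0,
                                   basis=Basis.VOLUMETRIC)
        with pytest.raises(InconsistentRecordError):
            build_endpoint_rows([bad], [rec], "local_progression")


class TestKaplanMeierLogrank:
    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(100.0, size=200)
        rows = pd.DataFrame({"arm": "SRS", "time": times, "event": True})
        comp = km_logrank(rows)
        for t in (20.0, 80.0, 200.0):
            empirical = (times > t).mean()
            assert comp.survival_at(t)["SRS"] == pytest.approx(empirical, abs=1e-12)

    def test_all_censored_gives_flat_curves_and_no_test(self):
        rows = pd.DataFrame(
            {"arm": ["SRS"] * 3 + ["FSRT"] * 3, "time": [100, 200, 300] * 2,
             "event": [False] * 6}
        )
        comp = km_logrank(rows)
        assert (comp.curves["survival"] == 1.0).all()
        assert comp.medians["SRS"] is None
        assert comp.logrank_statistic is None

    def test_six_lesion_hand_example(self):
        rows = pd.DataFrame(
            {
                "arm": ["A", "A", "A", "B", "B", "B"],
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [True] * 6,
            }
        )
        comp = km_logrank(rows)
        expected = hand_logrank(rows["time"], rows["arm"], rows["event"])
        assert expected == pytest.approx(5.0517, abs=1e-3)  # frozen hand tally
        assert comp.logrank_statistic == pytest.approx(expected, rel=1e-6)

    def test_identical_arms_give_zero_statistic(self):
        base = pd.DataFrame({"time": [10.0, 20, 30, 40], "event": [True] * 4})
        rows = pd.concat(
            [base.assign(arm="A"), base.assign(arm="B")], ignore_index=True
        )
        comp = km_logrank(rows)
        assert comp.logrank_statistic == pytest.approx(0.0, abs=1e-9)
        assert comp.logrank_p == pytest.approx(1.0)

    def test_median_is_first_time_survival_reaches_half(self):
        rows = pd.DataFrame(
            {"arm": "A", "time": [1.0, 2.0, 3.0, 4.0], "event": [True] * 4}
        )
        comp = km_logrank(rows)
        assert comp.medians["A"] == 2.0

    def test_permuted_labels_of_exchangeable_data_give_uniform_p(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(100.0, size=60)
        events = rng.random(60) < 0.8
        rejections = 0
        n_perm = 200
        for _ in range(n_perm):
            arms = rng.permutation(["A"] * 30 + ["B"] * 30)
            comp = km_logrank(
                pd.DataFrame({"arm": arms, "time": times, "event": events})
            )
            rejections += comp.logrank_p < 0.05
        assert 0.0 <= rejections / n_perm <= 0.12


class TestCox:
    def test_hazard_ratio_recovery_two_arm_exponential(self):
        rows = simulate_two_arm_exponential(1000, hazard_ratio=0.5, seed=11)
        rows["arm_ind"] = (rows["arm"] == "FSRT").astype(float)
        table = cox_fit(rows, ["arm_ind"], mode="univariate")
        hr = table.loc[table.parameter == "arm_ind", "hr"].iloc[0]
        assert 0.4 <= hr <= 0.6

    def test_cox_agrees_with_exponential_mle(self):
        rows = simulate_two_arm_exponential(1500, hazard_ratio=0.5, seed=5)
        rows["arm_ind"] = (rows["arm"] == "FSRT").astype(float)
        table = cox_fit(rows, ["arm_ind"], mode="univariate")
        hr = table.loc[table.parameter == "arm_ind", "hr"].iloc[0]
        # closed-form exponential MLE: rate = events / person-time, per arm
        rates = {}
        for arm, grp in rows.groupby("arm"):
            rates[arm] = grp["event"].sum() / grp["time"].sum()
        mle_ratio = rates["FSRT"] / rates["SRS"]
        assert hr == pytest.approx(mle_ratio, rel=0.10)

    def test_constant_covariate_flagged_not_fitted(self):
        rows = simulate_two_arm_exponential(50, hazard_ratio=1.0, seed=2)
        rows["flat"] = 1.0
        rows["arm_ind"] = (rows["arm"] == "FSRT").astype(float)
        table = cox_fit(rows, ["flat", "arm_ind"], mode="multivariate")
        flat = table.loc[table.parameter == "flat"].iloc[0]
        assert "constant" in flat["note"]
        assert np.isnan(flat["hr"])

    def test_univariate_mode_fits_each_covariate_alone(self):
        rows = simulate_two_arm_exponential(200, hazard_ratio=0.6, seed=4)
        rows["arm_ind"] = (rows["arm"] == "FSRT").astype(float)
        rows["noise_cov"] = np.random.default_rng(0).normal(size=len(rows))
        table = cox_fit(rows, ["arm_ind", "noise_cov"], mode="univariate")
        assert set(table["parameter"]) == {"arm_ind", "noise_cov"}
        assert (table["mode"] == "univariate").all()
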
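"""Synthetic two-arm lesion cohorts with known ground-truth fates.

No patient-level data are distributed with this package, so every
pipeline stage is exercised on simulated cohorts that emulate the study
design the classifiers were built for: two treatment arms (single-
session SRS vs fractionated FSRT) whose baseline-volume, fractionation,
histology and prior-WBRT distributions match the published cohort
characteristics; MRI at baseline (~8 days before radiotherapy), 6 weeks
after, and every 3 months thereafter with schedule jitter; and three
latent lesion fates — controlled, progression, radionecrosis — with
arm-dependent frequencies.

Trajectory kinetics are deliberately minimal (the simplest forms that
express the three fate archetypes):

* controlled:      V(t) = V0 · (r + (1−r) e^{−t/τ})   — exponential
  shrinkage to a residual fraction r;
* progression:     the controlled curve until onset, then exponential
  regrowth at rate λ;
* radionecrosis:   the controlled curve plus a transient pulse that
  crosses both progression thresholds at exactly one scheduled MRI and
  then decays below the partial-response level (35 % of baseline).

Event times are calibrated on the *detected* event — the first MRI on
which the thresholds are crossed — because that is how the clinical
endpoint is dated.  Each event-fated lesion draws a target detection
time from an exponential law whose 12-month mass reproduces the
configured 12-month local-control / radionecrosis rates; the regrowth
onset is then back-solved so the latent curve first crosses the
thresholds at the scheduled visit nearest that target.

Measurements carry multiplicative log-normal noise; diameters are the
spherical-equivalent of the noiseless latent volume with independent
noise.  Follow-up is truncated at a patient-level death/censoring time
shared by all of a patient's lesions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import InvalidInputError
from .radbio import sphere_diameter
from .response_volumetric import DEFAULT_CONFIG as _CRITERIA

FATES = ("controlled", "progression", "radionecrosis")


@dataclass(frozen=True)
class ArmSettings:
    """Per-arm cohort composition and designed outcome rates."""

    name: str
    n_lesions: int
    #: median baseline volume (cm³) of the truncated log-normal sampler
    baseline_median: float
    #: log-scale sd of the baseline-volume log-normal
    baseline_sigma: float
    #: hard truncation range (cm³); the lower bound sits just above the
    #: measurability cutoff so the inclusion filter keeps every lesion
    baseline_range: tuple[float, float]
    #: designed 12-month local-control probability (KM scale)
    lc_12m: float
    #: designed 12-month radionecrosis rate (KM scale)
    rn_12m: float
    #: fractionation sampler: (probability, n_fractions, dose_per_fraction)
    fractionation: tuple[tuple[float, int, float], ...]
    histology_probs: tuple[tuple[str, float], ...]
    p_former_wbrt: float
    #: probability that a radionecrosis lesion is resected (grade IV)
    p_resect_given_rn: float


def _srs_default() -> ArmSettings:
    return ArmSettings(
        name="SRS",
        n_lesions=92,
        baseline_median=0.23,
        baseline_sigma=1.06,
        baseline_range=(0.066, 3.0),
        lc_12m=0.556,
        rn_12m=0.148,
        fractionation=((0.55, 1, 20.0), (0.35, 1, 18.0), (0.10, 1, 16.0)),
        histology_probs=(
            ("melanoma", 0.554), ("lung", 0.098), ("breast", 0.043),
            ("renal", 0.163), ("other", 0.142),
        ),
        p_former_wbrt=0.207,
        p_resect_given_rn=0.26,
    )


def _fsrt_default() -> ArmSettings:
    return ArmSettings(
        name="FSRT",
        n_lesions=98,
        baseline_median=1.42,
        baseline_sigma=1.90,
        baseline_range=(0.066, 65.0),
        lc_12m=0.702,
        rn_12m=0.034,
        fractionation=(
            (0.55, 10, 4.0), (0.12, 5, 6.0), (0.08, 6, 5.0), (0.06, 7, 5.0),
            (0.05, 10, 3.5), (0.04, 12, 3.0), (0.04, 6, 7.0), (0.03, 4, 7.0),
            (0.03, 14, 2.0),
        ),
        histology_probs=(
            ("melanoma", 0.327), ("lung", 0.173), ("breast", 0.163),
            ("renal", 0.153), ("other", 0.184),
        ),
        p_former_wbrt=0.153,
        p_resect_given_rn=0.0,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the cohort generator.

    The defaults encode the emulated study conditions: arm sizes 92/98,
    baseline-volume medians 0.23/1.42 cm³, MRI at −8 d / 42 d / every
    91 d with 7 d jitter, median time to death ≈ 316 d, designed
    12-month local control 55.6 %/70.2 % and radionecrosis 14.8 %/3.4 %
    for SRS/FSRT respectively.
    """

    srs: ArmSettings = field(default_factory=_srs_default)
    fsrt: ArmSettings = field(default_factory=_fsrt_default)

    # conditional detection-time hazard (1/day) given an event fate;
    # ln(4)/365 puts 75 % of event mass inside the first year
    event_time_rate: float = math.log(4.0) / 365.0

    # controlled-trajectory kinetics
    shrink_tau_days: float = 80.0
    residual_fraction: float = 0.55
    # exponential regrowth rate of progressing lesions (1/day)
    regrowth_rate: float = 0.025
    # radionecrosis pulse: post-peak residual and hard floor (× baseline)
    rn_residual_fraction: float = 0.20
    rn_floor_fraction: float = 0.12
    # factor by which the latent value overshoots the progression
    # threshold at the designed detection visit
    trigger_margin: float = 1.3

    # measurement model
    noise_cv: float = 0.10
    diameter_noise_cv: float = 0.10

    # MRI schedule (days from start of radiotherapy)
    baseline_offset_days: float = -8.0
    first_followup_days: float = 42.0
    followup_interval_days: float = 91.0
    schedule_jitter_sd_days: float = 7.0
    min_visit_gap_days: float = 14.0
    max_followup_days: float = 1095.0

    # patient-level follow-up truncation
    survival_median_days: float = 316.0
    lesion_count_probs: tuple[tuple[int, float], ...] = ((1, 0.6), (2, 0.3), (3, 0.1))

    # clinical-event plumbing
    p_resect_given_progression: float = 0.05
    resection_delay_days: float = 30.0
    p_intervening_treatment: float = 0.0
    p_checkpoint_inhibitor: float = 0.068

    seed: int = 0

    def fate_probs(self, arm: ArmSettings) -> tuple[float, float, float]:
        """Lifetime (controlled, progression, radionecrosis) fate
        probabilities implied by the designed 12-month rates and the
        detection-time law."""
        f365 = 1.0 - math.exp(-self.event_time_rate * 365.0)
        p_prog = (1.0 - arm.lc_12m) / f365
        p_rn = arm.rn_12m / f365
        p_ctrl = 1.0 - p_prog - p_rn
        if p_ctrl < 0 or p_prog < 0 or p_rn < 0:
            raise InvalidInputError(
                f"arm {arm.name}: designed 12-month rates are not reachable with "
                f"event_time_rate={self.event_time_rate:g} (fate probabilities "
                f"{p_ctrl:.3f}/{p_prog:.3f}/{p_rn:.3f})"
            )
        return (p_ctrl, p_prog, p_rn)


@dataclass
class CohortTables:
    """The generator's output: the same CSV schemas the pipeline consumes,
    plus ground truth that the classifiers never read."""

    measurements: pd.DataFrame
    lesions: pd.DataFrame
    events: pd.DataFrame
    ground_truth: pd.DataFrame


def _truncated_lognormal_mu(median: float, sigma: float, lo: float, hi: float) -> float:
    """Log-scale location such that the [lo, hi]-truncated log-normal has
    the requested median."""
    log_med, log_lo, log_hi = math.log(median), math.log(lo), math.log(hi)

    def median_error(mu: float) -> float:
        a, b = (log_lo - mu) / sigma, (log_hi - mu) / sigma
        z_med = norm.ppf(0.5 * (norm.cdf(a) + norm.cdf(b)))
        return mu + sigma * z_med - log_med

    return brentq(median_error, log_med - 5 * sigma, log_med + 5 * sigma)


def _sample_truncated_lognormal(rng, mu, sigma, lo, hi) -> float:
    for _ in range(1000):
        v = math.exp(rng.normal(mu, sigma))
        if lo < v <= hi:
            return v
    return min(max(math.exp(mu), lo * 1.001), hi)


def _noise_factor(rng, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return math.exp(rng.normal(-0.5 * sigma * sigma, sigma))


def _visit_schedule(rng, config: SimulationConfig, death_t: float) -> list[float]:
    visits: list[float] = []
    nominal = config.first_followup_days
    prev = 0.0
    while nominal <= config.max_followup_days:
        t = nominal + rng.normal(0.0, config.schedule_jitter_sd_days)
        t = max(t, prev + config.min_visit_gap_days)
        if t >= death_t:
            break
        visits.append(t)
        prev = t
        nominal += config.followup_interval_days
    return visits


def simulate_cohort(config: SimulationConfig, seed: Optional[int] = None) -> CohortTables:
    """Generate one cohort; identical seed and config give identical tables."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    meas_rows, lesion_rows, event_rows, truth_rows = [], [], [], []
    lesion_no = 0
    patient_no = 0

    counts, count_p = zip(*config.lesion_count_probs)
    for arm in (config.srs, config.fsrt):
        mu = _truncated_lognormal_mu(
            arm.baseline_median, arm.baseline_sigma, *arm.baseline_range
        )
        pi = config.fate_probs(arm)
        frac_p = [p for p, _, _ in arm.fractionation]
        hist_names = [h for h, _ in arm.histology_probs]
        hist_p = np.array([p for _, p in arm.histology_probs], dtype=float)
        hist_p /= hist_p.sum()

        remaining = arm.n_lesions
        while remaining > 0:
            k = min(int(rng.choice(counts, p=count_p)), remaining)
            patient_no += 1
            patient_id = f"P{patient_no:04d}"
            death_t = min(
                rng.exponential(config.survival_median_days / math.log(2.0)),
                config.max_followup_days,
            )
            for _ in range(k):
                lesion_no += 1
                lesion_id = f"L{lesion_no:04d}"
                _simulate_lesion(
                    rng, config, arm, mu, pi, frac_p, hist_names, hist_p,
                    lesion_id, patient_id, death_t,
                    meas_rows, lesion_rows, event_rows, truth_rows,
                )
            remaining -= k

    measurements = pd.DataFrame(
        meas_rows,
        columns=["lesion_id", "patient_id", "t_days", "volume_cm3",
                 "diameter_mm", "intervening_treatment"],
    )
    lesions = pd.DataFrame(
        lesion_rows,
        columns=["lesion_id", "patient_id", "arm", "n_fractions",
                 "dose_per_fraction", "histology", "former_wbrt",
                 "wbrt_gap_days", "concurrent_wbrt", "checkpoint_inhibitor",
                 "death_t_days"],
    )
    events = pd.DataFrame(
        event_rows, columns=["lesion_id", "event_type", "t_days", "histology"]
    )
    ground_truth = pd.DataFrame(
        truth_rows,
        columns=["lesion_id", "patient_id", "arm", "true_fate",
                 "expressed_fate", "true_event_t", "boosted_growth",
                 "resected", "n_visits"],
    )
    return CohortTables(measurements, lesions, events, ground_truth)


def _simulate_lesion(
    rng, config, arm, mu, pi, frac_p, hist_names, hist_p,
    lesion_id, patient_id, death_t,
    meas_rows, lesion_rows, event_rows, truth_rows,
) -> None:
    v0 = _sample_truncated_lognormal(rng, mu, arm.baseline_sigma, *arm.baseline_range)
    r, tau = config.residual_fraction, config.shrink_tau_days

    def controlled(t: float) -> float:
        if t <= 0:
            return v0
        return v0 * (r + (1.0 - r) * math.exp(-t / tau))

    visits = _visit_schedule(rng, config, death_t)
    fate = FATES[int(rng.choice(3, p=pi))]

    latent = controlled
    expressed = "controlled"
    event_t = math.nan
    boosted = False
    resected = False
    resection_t = None
    resection_histology = None

    if fate != "controlled" and visits:
        target_t = rng.exponential(1.0 / config.event_time_rate)
        half = config.followup_interval_days / 2.0
        idx = int(np.searchsorted(visits, target_t - half))
        if idx < len(visits):
            v_k = visits[idx]
            v_prev = visits[idx - 1] if idx > 0 else 0.0
            nadir = controlled(v_prev) if idx > 0 else v0
            threshold = max(
                nadir * (1.0 + _CRITERIA.rel_progression_threshold),
                nadir + _CRITERIA.abs_progression_threshold,
            )
            peak = config.trigger_margin * threshold
            event_t = v_k

            if fate == "progression":
                latent, boosted = _progression_latent(
                    controlled, config.regrowth_rate, v_prev, v_k, peak
                )
                expressed = "progression"
                if rng.random() < config.p_resect_given_progression:
                    t_r = v_k + config.resection_delay_days
                    if t_r < death_t:
                        resected = True
                        resection_t, resection_histology = t_r, "tumor"
                        visits = [t for t in visits if t <= v_k]
            else:  # radionecrosis
                v_next = visits[idx + 1] if idx + 1 < len(visits) else None
                latent = _radionecrosis_latent(
                    controlled, config, v0, v_prev, v_k, peak, v_next
                )
                expressed = "radionecrosis" if v_next is not None else "progression"
                if rng.random() < arm.p_resect_given_rn:
                    t_r = v_k + config.resection_delay_days
                    if t_r < death_t:
                        resected = True
                        resection_t, resection_histology = t_r, "necrosis"
                        visits = [t for t in visits if t <= v_k]
                        expressed = "radionecrosis"

    # sample the trajectory at the MRI schedule
    times = [config.baseline_offset_days] + visits
    for i, t in enumerate(times):
        v_lat = latent(t)
        meas_rows.append(
            {
                "lesion_id": lesion_id,
                "patient_id": patient_id,
                "t_days": round(t, 3),
                "volume_cm3": v_lat * _noise_factor(rng, config.noise_cv),
                "diameter_mm": sphere_diameter(v_lat)
                * _noise_factor(rng, config.diameter_noise_cv),
                "intervening_treatment": int(
                    i > 0 and rng.random() < config.p_intervening_treatment
                ),
            }
        )

    n_frac, dose = _draw_scheme(rng, arm.fractionation, frac_p)
    former_wbrt = bool(rng.random() < arm.p_former_wbrt)
    lesion_rows.append(
        {
            "lesion_id": lesion_id,
            "patient_id": patient_id,
            "arm": arm.name,
            "n_fractions": n_frac,
            "dose_per_fraction": dose,
            "histology": hist_names[int(rng.choice(len(hist_names), p=hist_p))],
            "former_wbrt": int(former_wbrt),
            "wbrt_gap_days": round(float(rng.uniform(56.0, 365.0)), 1) if former_wbrt else "",
            "concurrent_wbrt": 0,
            "checkpoint_inhibitor": int(rng.random() < config.p_checkpoint_inhibitor),
            "death_t_days": round(death_t, 3),
        }
    )
    if resected:
        event_rows.append(
            {
                "lesion_id": lesion_id,
                "event_type": "resection",
                "t_days": round(resection_t, 3),
                "histology": resection_histology,
            }
        )
    truth_rows.append(
        {
            "lesion_id": lesion_id,
            "patient_id": patient_id,
            "arm": arm.name,
            "true_fate": fate,
            "expressed_fate": expressed,
            "true_event_t": round(event_t, 3) if not math.isnan(event_t) else math.nan,
            "boosted_growth": bool(boosted),
            "resected": bool(resected),
            "n_visits": len(visits),
        }
    )


def _draw_scheme(rng, fractionation, frac_p) -> tuple[int, float]:
    i = int(rng.choice(len(fractionation), p=frac_p))
    _, n_frac, dose = fractionation[i]
    return n_frac, dose


def _progression_latent(controlled, lam, v_prev, v_k, peak):
    """Controlled curve until onset, then exponential regrowth; onset is
    back-solved so the curve first reaches ``peak`` exactly at ``v_k``.
    When the configured rate cannot bridge the interval, growth starts at
    the preceding visit with a per-lesion boosted rate."""

    def crossing_gap(t: float) -> float:
        return math.log(controlled(t)) + lam * (v_k - t) - math.log(peak)

    boosted = False
    if crossing_gap(v_prev) >= 0.0:
        t_on = brentq(crossing_gap, v_prev, v_k)
        rate = lam
    else:
        t_on, boosted = v_prev, True
        rate = math.log(peak / controlled(v_prev)) / (v_k - v_prev)
    v_on = controlled(t_on)

    def latent(t: float) -> float:
        if t <= t_on:
            return controlled(t)
        return v_on * math.exp(rate * (t - t_on))

    return latent, boosted


def _radionecrosis_latent(controlled, config, v0, v_prev, v_k, peak, v_next):
    """Transient pulse: geometric rise from the preceding visit to the
    peak at the detection visit, then exponential decay reaching the
    post-pulse residual (well below the 35 % partial-response level) by
    the following visit."""
    residual = config.rn_residual_fraction * v0
    floor = config.rn_floor_fraction * v0
    base = controlled(v_prev)
    interval = (v_next - v_k) if v_next is not None else config.followup_interval_days
    tau_d = interval / math.log(peak / residual)

    def latent(t: float) -> float:
        if t <= v_prev:
            return controlled(t)
        if t <= v_k:
            frac = (t - v_prev) / (v_k - v_prev)
            return base * (peak / base) ** frac
        return max(peak * math.exp(-(t - v_k) / tau_d), floor)

    return latent


def calibration_report(config: SimulationConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Simulated per-arm summaries for comparison against the configured
    targets: baseline-volume median/IQR/mean, BED distributions, fate
    frequencies and the designed 12-month event rates."""
    from .radbio import FractionationScheme, bed_lq, bed_lqc, NORMAL_BRAIN_ALPHA_BETA

    tables = simulate_cohort(config, seed=seed)
    if tables.lesions.empty:
        return pd.DataFrame(columns=["arm", "metric", "value"])
    rows = []
    truth = tables.ground_truth.set_index("lesion_id")
    for arm_name, grp in tables.lesions.groupby("arm", sort=True):
        base = (
            tables.measurements[
                tables.measurements["lesion_id"].isin(grp["lesion_id"])
                & (tables.measurements["t_days"] < 0)
            ]["volume_cm3"]
        )
        bed12 = [
            bed_lqc(FractionationScheme(int(n), float(d))).bed
            for n, d in zip(grp["n_fractions"], grp["dose_per_fraction"])
        ]
        bed2 = [
            bed_lq(FractionationScheme(int(n), float(d), alpha_beta=NORMAL_BRAIN_ALPHA_BETA)).bed
            for n, d in zip(grp["n_fractions"], grp["dose_per_fraction"])
        ]
        arm_truth = truth.loc[grp["lesion_id"]]
        arm_cfg = config.srs if arm_name == "SRS" else config.fsrt
        entries = {
            "n_lesions": len(grp),
            "baseline_volume_median": base.median(),
            "baseline_volume_q1": base.quantile(0.25),
            "baseline_volume_q3": base.quantile(0.75),
            "baseline_volume_mean": base.mean(),
            "bed12_lqc_median": float(np.median(bed12)),
            "bed12_lqc_mean": float(np.mean(bed12)),
            "bed2_lq_median": float(np.median(bed2)),
            "bed2_lq_mean": float(np.mean(bed2)),
            "designed_prog_12m": 1.0 - arm_cfg.lc_12m,
            "designed_rn_12m": arm_cfg.rn_12m,
            "frac_fate_progression": float((arm_truth["true_fate"] == "progression").mean()),
            "frac_fate_radionecrosis": float((arm_truth["true_fate"] == "radionecrosis").mean()),
            "frac_former_wbrt": float(grp["former_wbrt"].mean()),
        }
        rows.extend({"arm": arm_name, "metric": k, "value": v} for k, v in entries.items())
    return pd.DataFrame(rows, columns=["arm", "metric", "value"])


def simulate_two_arm_exponential(
    n_per_arm: int,
    hazard_ratio: float,
    base_rate: float = 1.0 / 365.0,
    censor_rate: float = 0.25 / 365.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Plain two-arm exponential survival data with a designed hazard
    ratio, for parameter-recovery checks of the Cox machinery."""
    rng = np.random.default_rng(seed)
    rows = []
    for arm, rate in (("SRS", base_rate), ("FSRT", base_rate * hazard_ratio)):
        t_event = rng.exponential(1.0 / rate, size=n_per_arm)
        t_cens = rng.exponential(1.0 / censor_rate, size=n_per_arm)
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
        for i in range(n_per_arm):
            rows.append({"arm": arm, "time": float(time[i]), "event": bool(event[i])})
    return pd.DataFrame(rows)
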
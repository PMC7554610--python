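# vrano

Volumetric response assessment and lesion-level outcome comparison for
brain metastases treated with stereotactic radiotherapy.

After single-session radiosurgery (SRS) or fractionated stereotactic
radiotherapy (FSRT), serial contrast MRI must distinguish three lesion
fates: durable control, true local progression, and radionecrosis — a
treatment effect that transiently enlarges and enhances like a
recurrence but regresses spontaneously.  The conventional RANO-BM
criteria rate the longest axial diameter; this package implements their
volumetric extension, derived by spherical geometry, together with the
radiobiology and survival machinery needed to compare the two treatment
modalities lesion by lesion.  It is aimed at radiation oncologists and
outcome researchers working with longitudinal tumor volumetry.

## The criteria and models

**Volumetric progression.**  A ≥20 % diameter increase of a sphere is a
≥72.8 % volume increase ((1.2)³ − 1), so progression requires

&nbsp;&nbsp;&nbsp;&nbsp;V ≥ 1.728 × V_nadir  **and**  V − V_nadir ≥ 0.2 cm³,

where V_nadir is the running minimum of baseline and all earlier
post-treatment volumes, and 0.2 cm³ is the volume a 5 mm sphere gains
when growing to 8 mm (the RANO-BM "+3 mm for lesions <10 mm" guard).
The measurability cutoff >0.065 cm³ is a >5 mm sphere.

**Radionecrosis.**  A lesion that fulfils the progression criteria but
subsequently regresses — back to the nadir reference, or by ≥65 % of
baseline (the volumetric partial-response depth, a 30 % diameter
reduction) — without any intervening local or systemic treatment is
reclassified as radionecrosis.  Resection histology overrides the
imaging call; necrosis requiring resection is grade IV.

**Radiobiology.**  The biologically effective dose of n fractions of
d Gy is computed as BED = n·d·[1 + d/(α/β)] (linear-quadratic, α/β =
2 Gy for normal brain) and BED = n·d·[1 + d/(α/β) − d²/(α/γ)]
(linear-quadratic-cubic, α/β = 12 Gy and α/γ = 648 Gy² for metastases).
Fractionation therefore raises the tumor BED while sharply lowering the
normal-brain BED — the therapeutic-ratio argument for FSRT.

**Survival comparison.**  Per-lesion endpoints (local progression,
any-grade radionecrosis, grade-IV radionecrosis) are dated at the first
MRI fulfilling the criteria (or at resection), censored at last
imaging, and compared between arms with Kaplan–Meier estimates, the
log-rank test and Cox proportional-hazards models (Efron ties;
melanoma-referenced histology dummies; BED measures univariate-only
because they are collinear with the arm).

Because no patient-level data are distributed, a synthetic cohort
generator (`vrano.synthetic_data`) reproduces the study design — arm
sizes, baseline-volume and fractionation distributions, the MRI
schedule, and designed arm-level 12-month outcome rates — with known
ground-truth fates, so every pipeline stage is testable end to end.

## Worked example

```python
from vrano import (FractionationScheme, bed_lqc, bed_lq,
                   classify_lesion, LesionRecord, VolumeMeasurement)

srs = FractionationScheme(1, 20.0)
print(f"SRS 1 x 20 Gy: tumor BED = {bed_lqc(srs).bed:.1f} Gy")
brain = FractionationScheme(1, 20.0, alpha_beta=2.0)
print(f"SRS 1 x 20 Gy: normal-brain BED = {bed_lq(brain).bed:.1f} Gy")

lesion = LesionRecord(
    lesion_id="M01",
    measurements=[
        VolumeMeasurement(t=-8, volume=1.00),   # baseline MRI
        VolumeMeasurement(t=44, volume=1.85),   # 6-week MRI: past both thresholds
        VolumeMeasurement(t=135, volume=0.30),  # untreated regression
    ],
)
result = classify_lesion(lesion)
print(f"{result.lesion_id}: {result.status.value} at day {result.event_t:g} "
      f"(reference {result.reference_volume_at_event} cm3, "
      f"trigger {result.trigger_volume} cm3)")
```

prints

```
SRS 1 x 20 Gy: tumor BED = 41.0 Gy
SRS 1 x 20 Gy: normal-brain BED = 220.0 Gy
M01: radionecrosis at day 44 (reference 1.0 cm3, trigger 1.85 cm3)
```

The lesion crossed both progression thresholds at the 6-week MRI
(1.85 ≥ 1.728 × 1.0 and +0.85 cm³ ≥ 0.2 cm³) but then regressed below
35 % of baseline without new treatment, so the event is adjudicated as
radionecrosis, dated at the triggering MRI.

## Analysis scripts

The `analysis/` directory holds the narrative drivers, to be run in
order from the repository root (outputs under `results/`):

1. `01_simulate_cohort.py` — generate the synthetic cohort and check
   its calibration against the configured targets;
2. `02_bed_characteristics.py` — BED tables per fractionation scheme
   and per arm;
3. `03_classify_lesions.py` — inclusion filters plus both
   classification modes;
4. `04_survival_comparison.py` — Kaplan–Meier / log-rank / Cox
   comparison of FSRT vs SRS for all three endpoints.

On the default simulated cohort (92 SRS / 98 FSRT lesions, seed
20260925) step 4 prints, among others:

```
local_progression (volumetric):
  FSRT: 12-month local control 71.2%, median time to progression not reached, 22/87 events
  SRS: 12-month local control 50.2%, median time to progression 16.1 mo, 35/81 events
  log-rank p = 0.0066

radionecrosis_any (volumetric):
  FSRT: 12-month rate 4.5%, 3/87 events
  SRS: 12-month rate 13.9%, 9/81 events
  log-rank p = 0.0354
```

i.e. the pipeline recovers the generator's designed arm contrast:
better local control and less radionecrosis with fractionated
treatment.  A `vrano` command-line interface (`vrano bed | simulate |
classify | analyze`) wraps the same library calls.

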
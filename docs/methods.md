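# Methods

This note documents the models implemented in `vrano`, the design
choices made where the methodology left room, and what the synthetic
cohort does and does not establish about real data.

## Response classification

### Volumetric criteria

All thresholds are spherical-geometry translations of the
unidimensional RANO-BM rules, computed by `vrano.radbio` and used as
defaults in `CriteriaConfig`:

| quantity | value | derivation |
|---|---|---|
| relative progression threshold | +72.8 % volume | (1 + 0.20)³ − 1 |
| absolute progression guard | 0.2 cm³ | (π/6)(8³ − 5³) mm³ |
| partial-response depth | −65 % volume | (1 − 0.30)³ − 1 |
| measurability cutoff | >0.065 cm³ | (π/6)·5³ mm³ |

Units are fixed package-wide (diameters mm, volumes cm³, doses Gy) and
all conversions are centralised in `radbio`, so no other module
multiplies by 10³.

The classifier scans post-treatment measurements in time order and
tests each against the running nadir — the minimum of the baseline
volume and all strictly earlier post-treatment volumes.  Design choices
that the criteria themselves do not fix:

* **One reference for both thresholds.**  The relative criterion is
  defined against "nadir/baseline"; the absolute 0.2 cm³ increment uses
  the same running-nadir reference, keeping the two conditions coherent.
* **Absolute guard for all sizes.**  The 0.2 cm³ requirement applies to
  lesions of every size (switchable via
  `apply_abs_threshold_to_all_sizes`).  Note that with the default
  thresholds the guard is only binding below a ~0.52 cm³ (10 mm-sphere)
  reference: above it, any +72.8 % increase already exceeds 0.2 cm³.
* **Regression clause.**  Spontaneous regression is an OR of two
  conditions: return to the nadir reference active at the trigger, or a
  ≥65 % reduction *relative to baseline* (partial response is defined
  against baseline; using the trigger peak instead would be more
  permissive and is not what a partial-response criterion means).  Any
  interval flagged with intervening treatment breaks the chain — the
  flagged measurement and everything after it are disqualified, since
  the treatment could explain the shrinkage.
* **Event dating.**  `event_t` is the time of the first MRI fulfilling
  both progression conditions; radionecrosis inherits that date because
  it is a retrospective reclassification of the same event.  A lesion
  resected without prior imaging progression is dated at the
  intervention.
* **Histology overrides imaging.**  Resection specimens classify the
  lesion as progression (viable tumor), radionecrosis, or both;
  necrosis requiring resection is grade IV.  Grades I–III are clinical
  and not algorithmically derivable, so the classifier distinguishes
  only any-grade vs grade IV.
* **Degenerate data.**  Tied timestamps are a data error, not a
  tie-break; a value exactly at a threshold meets it (all criteria are
  "≥"); a missing baseline is an error unless histology alone can
  classify the lesion.

The unidimensional comparator (`response_unidimensional`) shares the
scan/reclassification engine with diameter thresholds (+20 %, +3 mm
while the reference is <10 mm, −30 % partial response).  The 3 mm
guard's size gate uses the reference diameter at test time (the nadir),
mirroring the volumetric logic.

## Radiobiology

BED(LQ) = n·d·[1 + d/(α/β)]; BED(LQC) = n·d·[1 + d/(α/β) − d²/(α/γ)].
Defaults: α/β = 12 Gy with α/γ = 648 Gy² for metastases (LQC), α/β =
2 Gy for normal brain (LQ); both overridable for sensitivity analyses.
The LQC bracket turns negative beyond d ≈ 46 Gy at the default
parameters; such doses are rejected as outside the model's validity
range rather than returning a negative BED.  BED values are carried
unrounded and rounded only at the report layer.

## Survival analysis

* Analyses are at the level of individual metastases; within-patient
  correlation is ignored by default, with a cluster-robust variance
  option available (`cluster_col`).
* Events are dated at the first qualifying MRI (or intervention);
  censoring is at the last imaging assessment.  Radionecrosis is a
  censoring-based Kaplan–Meier endpoint, not a competing-risk analysis.
* Cox models use the Efron tie approximation — the ~3-monthly MRI grid
  makes ties common — and Wald confidence intervals.  Histology is
  dummy-coded against a melanoma reference.  BED covariates are offered
  univariate-only by default because they are nearly collinear with
  the treatment arm.  Constant covariates and non-convergence are
  reported in the output table, never silently dropped.
* Time runs in days internally; `days_to_months` (days/30.44) is the
  report-layer conversion.  Two-sided p < 0.05, no multiplicity
  adjustment.

## Synthetic cohort generator

The generator emulates the study *design*, not any patient's data:

* **Arms and composition.**  92 SRS / 98 FSRT lesions; baseline volumes
  from per-arm truncated log-normals whose location is solved
  numerically so the truncated median hits the target (0.23 cm³ SRS,
  1.42 cm³ FSRT; log-sd 1.06 and 1.90 from the target interquartile
  ranges).  Volumes are drawn per arm with fixed arm sizes rather than
  assigning arms from one pooled distribution: that is the only way to
  match both arms' published medians and IQRs simultaneously.
  Fractionation, histology and prior-WBRT samplers match the published
  per-arm frequencies; ~1.6 lesions per patient share a patient-level
  death/censoring time (median 316 d, exponential, capped at 3 years).
* **Schedule.**  Baseline at −8 d; follow-up at 42 d and every 91 d
  with 7 d Gaussian jitter, truncated at death.
* **Fates and event times.**  Each lesion draws a lifetime fate
  (controlled / progression / radionecrosis).  Because the clinical
  endpoint is dated at the first MRI demonstrating progression, the
  designed hazards are placed on the *detected* event time: an
  event-fated lesion draws a target time from an exponential law with
  rate ln(4)/365 (75 % of event mass inside the first year), and the
  lifetime fate probabilities are chosen as (designed 12-month event
  rate)/0.75 so that the censoring-based KM estimate at 12 months
  reproduces the configured rates (local control 55.6 %/70.2 %,
  radionecrosis 14.8 %/3.4 % for SRS/FSRT).  The detection target is
  snapped to the nearest scheduled visit and the regrowth onset is
  back-solved (Brent root-finding) so the latent curve first crosses
  both thresholds exactly at that visit, with a ×1.3 margin over the
  threshold so 10 % measurement noise rarely masks the crossing.  When
  the configured regrowth rate (0.025/day) cannot bridge the interval,
  the lesion gets a boosted per-lesion rate (flagged in ground truth).
* **Kinetics.**  Controlled: V(t) = V0·(r + (1−r)e^(−t/τ)) with r =
  0.55, τ = 80 d — monotone shrinkage to a residual plateau, the
  simplest curve matching the controlled archetype.  Progression:
  controlled curve until onset, then exponential regrowth.
  Radionecrosis: geometric rise from the previous visit to the peak,
  then exponential decay tuned to reach 20 % of baseline by the next
  visit (below the 35 % partial-response level), floored at 12 %.
* **Measurement model.**  Multiplicative mean-one log-normal noise
  (CV 0.10 by default) on volumes; diameters are the
  spherical-equivalent of the noiseless latent volume with independent
  noise of the same CV — which makes the diameter reading relatively
  noisier (d ∝ V^{1/3}) and reproduces the qualitative pattern that
  unidimensional assessment calls at least as many events.
* **Ground truth.**  Alongside the designed fate, the generator records
  the *expressed* fate — what the noiseless trajectory supports at the
  sampled visits.  A radionecrosis-fated lesion with no MRI after its
  detection visit (death, resection-free) expresses as progression,
  because the adjudication requires later imaging; an event whose
  designed detection falls after the last visit expresses as
  controlled.  Label-recovery checks compare classifications against
  expressed fates.  26 % of SRS radionecrosis lesions are resected
  (grade IV), none in the FSRT arm, matching the published grade-IV
  contrast; 5 % of progressing lesions are resected with viable-tumor
  histology.

### What the simulations do and do not show

Passing tests establish that the classifiers, endpoint builders and
survival stack implement the stated rules exactly and recover designed
effects at realistic noise.  They do not establish performance on real
volumetry: the generator has no segmentation or reader variability
structure, no correlated within-patient biology beyond shared
censoring, no dose-volume-driven arm assignment (a planning-system
quantity, out of scope), and its trajectory shapes are stylised.  The
expressed-vs-designed fate gap is itself a faithful property of the
method — radionecrosis cannot be adjudicated without follow-up — and
shifts end-to-end 12-month KM estimates roughly 2–3 points from the
configured rates, within the ±5-point band used by the end-to-end
check.

## Problem sizes and numerical choices

Unit and property tests run on trajectories of ≤8 points (brute-force
oracle agreement on 10,000 random trajectories plus 3,000 in the unit
suite); label recovery uses 250 lesions/arm; Cox parameter recovery
averages 15 replicates of 2,000 lesions (bias, not single-draw error);
the end-to-end two-arm comparison uses 500 lesions/arm with fixed
seeds.  The calibration checks use 2,000–4,000 lesions/arm.  All
randomness flows through `numpy.random.default_rng` with explicit
seeds; identical seed and configuration give byte-identical tables.
Root-finding uses `scipy.optimize.brentq`; truncated-log-normal
sampling is by rejection.

## Known limitations

* No DICOM/NIfTI or contour ingestion; inputs are long-format CSV of
  pre-computed volumes/diameters.
* Corticosteroid use, clinical status and distant lesions are outside
  the progression definition by construction.
* Perfusion/PET-based necrosis adjudication is not modelled; the
  radionecrosis call rests on spontaneous regression or histology only.
* The competing-risk structure between progression, radionecrosis and
  death is simplified to independent latent draws plus censoring; a
  cumulative-incidence variant of the radionecrosis endpoint is not the
  default, matching the censoring-based design it mirrors.
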
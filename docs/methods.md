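# Methods

`sczmets` implements a registry-style pharmacoepidemiological analysis of
metabolic syndrome (MetS) development in schizophrenia-spectrum (SSD)
patients, together with a synthetic-cohort generator that stands in for the
access-restricted biobank data such analyses normally run on.  This note
documents the models, the conventions behind every derived quantity, the
generator's assumptions, and the numerical choices.

## Data model and conventions

Five person-level tables (persons, drug dispensings, ICD-10 diagnoses,
BMI/smoking measurements, polygenic scores) are read from CSV/TSV with
ISO-8601 dates.  All day arithmetic uses half-open intervals `[start, end)`
counted in whole days; "years" always means days / 365.25; fixed-length
adherence windows use a 365-day year.  Validation is total: every input row
is accepted or written to a rejection report with a reason code, and the
counts sum to the input size.  Smoking is reduced to one ever/never status
per person (any "ever" wins); BMI enters survival models as WHO range
categories of the per-person median.

## Treatment exposure

All exposure metrics derive from a per-person **supply timeline**: each
dispensing contributes `days_supplied` days starting, under the default
stockpiling (carry-forward) convention, at `max(purchase date, end of the
previous supply)` — standard proportion-of-days-covered (PDC) practice.
With stockpiling off, supply starts on the purchase date and overlaps
merge.  Coverage is truncated at the end of follow-up (the death date for
decedents).

* **PDC windows.**  `pdc_1year`: `[first purchase, +365d)` clipped at
  follow-up end; `pdc_lastyear`: `[supply end − 365d, supply end)`,
  anchored at the last covered day so the final supply tail counts;
  `pdc_purchase`: first purchase to supply end; `pdc_followup`: first
  purchase to follow-up end.  Each PDC is covered-days ∩ window divided by
  window length, clipped to [0, 1].  `pdc_followup ≤ pdc_purchase` holds
  identically.
* **Treatment lengths.**  `ty_purchase` = (supply end − first purchase) /
  365.25; `ty_supply` = covered days / 365.25; the gap between their
  medians is the cohort's treatment-gap signal.
* **Discontinuation.**  Last supply ending more than 365 days (configurable)
  before end of follow-up or death.
* **Median chlorpromazine-equivalent dose.**  Each covered day carries the
  sum of concurrently active dispensings' `daily_dose_mg × factor(drug)`;
  the statistic is the median over all covered days, with purchases
  organised in batches separated by uncovered gaps > 90 days (configurable)
  and gap days excluded.  Equivalence factors for all 20 recognised
  antipsychotics ship as an editable TSV of consensus-style equivalents
  (chlorpromazine ≡ 1.0); the table is data, not code, and can be swapped.
* **Windowed exposure.**  For each BMI measurement date, PDC and median
  dose over the prior 2 years (intersected with the treated period) and
  cumulative supply years up to the measurement.

Every coverage quantity is checked for *exact* equality against a day-grid
brute force (`sczmets.validation.daygrid_metrics`) that replays the
conventions day by day with a FIFO supply queue — a deliberately different
algorithm from the interval arithmetic it checks.

## Cohort construction

A case's onset is the earlier of the first antipsychotic dispensing (ATC
`N05A*`, lithium excluded) and the first SSD diagnosis (F20–F29), required
to fall at age 15–40 and strictly after 2006 (a two-year buffer after the
registry's start).  Same-day ties resolve to "prescription".  Each case
receives k = 4 controls from a pool purged of any `F*` diagnosis or
antipsychotic dispensing: exact sex stratification, greedy nearest
neighbour on |birth-year difference| without replacement, in k round-robin
passes (one control per case per pass — the semantics of ratio matching in
the standard matching tools), cases ordered scarcest-first, distance ties
broken by a seeded shuffle fixed at pool construction.  Greedy matching is
benchmarked against the optimal assignment (`linear_sum_assignment`); on
adversarial pools it can exceed the optimum, which the benchmark detects
and reports.  Controls inherit their case's onset date as the index date —
the time origin for incidence — because controls have no onset of their
own; this is a documented artifact convention.

## Association

Each of the 15 standardized polygenic scores (SCZ plus 14 MetS traits) is
first modelled singly — logistic for case status, linear for the continuous
median-dose outcome — adjusted for sex, birth year (continuous) and 10
genotype PCs; then scores are added forward-stepwise, lowest Wald p first,
rescanning after each entry, until none clears the entry threshold
(Bonferroni 0.05/15 by default; both Bonferroni and nominal flags are
reported).  Wald tests are two-sided.  Singular or separated fits are
recorded per candidate and the scan continues.

## Survival

Six endpoints are analysed via ICD-10 prefix sets (defaults: T2D = E11;
hypercholesterolemia = E78.0; essential hypertension = I10; CHD = I20–I25;
CVD = I60–I69; any-metabolic = union; the sets are configuration).  Records
run from the index date to the first qualifying diagnosis, death or
follow-up end; persons with the endpoint on or before index are excluded as
prevalent, with bookkeeping such that eligible + prevalent + missing
covariates = cohort size.  Cox models use the Efron tie correction
(day-resolution registry ties), pooled over matched sets with covariate
adjustment.  The polygenic stepwise scan reuses the association engine with
the 6-endpoint Bonferroni family.  First-year adherence (`pdc_1year`) is
tested among treated cases only.

## BMI trajectories

The model ladder, all maximum likelihood (not REML, because the
likelihood-ratio tests compare fixed-effect structures):

1. baseline: intercept, sex, BMI PRS, 10 PCs, smoking, age, disease status,
   plus per-subject random intercept and random age slope;
2. \+ disease × age interaction;
3. \+ quartic polynomial in accumulated treatment-supply years.

Age is centered at 27 (the median onset age); the quartic enters through an
orthogonalized basis (thin QR of the scaled power basis, no constant term,
so it vanishes at zero treatment) whose transform is stored for prediction.
Successive models are compared by likelihood-ratio tests.  Optimisation is
warm-started from OLS (or the previous nested model); if a nested model's
likelihood ever drops below its parent's, the fit is retried with more
robust optimisers and the best likelihood kept.  A singular random-effects
covariance triggers a diagonal-structure refit with a warning.

Scenario predictions are population-level (random effects at zero) over an
age grid; treated scenarios accrue treatment years piecewise-linearly
(e.g. 180 days per year from age 27).  Confidence bands use the
fixed-effect covariance through the linear predictor at the normal quantile
`z = Φ⁻¹((1+0.83)/2) ≈ 1.372`; two means are flagged different at roughly
α = 0.05 where their 83% bands are disjoint (verified by Monte Carlo:
non-overlap rate ≈ 0.052 under the null).  The decade gain is the predicted
mean at `start age + 10` minus the mean at start age.

## The synthetic cohort

The generator emulates the structure the analysis assumes, with a single
root seed split into named substreams (persons, scores, dispensing,
outcomes, measurements, smoking) so adding a stage never perturbs earlier
draws.  Defaults are the study conditions:

* 677 cases, 4 controls per case (matched from a 1.5× candidate pool built
  by perturbing case birth years so exact matching is feasible), 54%
  female (deterministic count), onset age ~ N(27, 6.9²) truncated to
  [15, 40], onset dates uniform over 2007–2018, follow-up to 2023-03-31,
  death fractions 1.9% / 0.2%.
* **Scores:** multivariate normal with a correlation matrix assembled from
  the empirical trait clusters (blood pressure, lipids, glycaemic,
  adiposity/inflammation; CRP–BMI = 0.40) and projected to be
  well-conditioned.  Cases' score vectors are shifted by
  `log(1.75)·R[:, SCZ]`, which makes the multivariate logistic coefficient
  on the SCZ score exactly log 1.75 and induces realistic secondary
  case-control differences in correlated scores (e.g. protective marginal
  odds ratios ≈ 0.88 for BMI and CRP).
* **Dispensing:** 87.9% of cases treated; first purchase 0–90 days after
  onset; person-level adherence ~ Beta(3.5, 1.9) (mean ≈ 0.65, matching the
  cohort's PDC over purchases); supplies of 30/60/90 days; inter-purchase
  gap = supply/adherence with log-normal noise; drug switching with
  probability 0.08 per purchase across the 20 agents (metabolically active
  drugs most common); person-level dose targets log-normal with median
  190 CPZ-mg/day; forced discontinuation with probability 0.41 at a
  log-normal stop time (median 2.1 years).
* **Endpoints:** constant (memoryless) hazards in age from 15, so hazards
  are equally proportional on the time-since-index scale and prevalent-case
  exclusion is unbiased; per-endpoint rates sized to the cohort's event
  counts and case hazard ratios 4.19/1.43/1.92/3.35/3.48, whose
  event-weighted union gives ≈ 1.95 for any metabolic disorder.
* **BMI:** generated from the trajectory model itself (closed loop):
  controls gain 0.15 BMI/yr, cases 0.18/yr plus a quartic in accumulated
  treatment years calibrated so a 180-days-per-year treated case gains
  4.6 BMI points over a decade (coefficients 1.06, −0.16, 0.014, −0.00035);
  case level offset −0.6, BMI-PRS effect 1.2/SD, sex +0.3, smoking −0.3;
  random intercept SD 3.8, random age-slope SD 0.07, residual SD 1.3.
  The visit process is overdispersed, as registry utilisation is: most
  persons have ~3 measurements at a ~330-day median spacing, a 15%
  frequent-attender minority has many, which keeps long treatment
  durations represented among observed measurements.
* A truth table records all latent quantities (case status, random effects,
  latent index dates, event ages) for parameter-recovery tests.

What the generator does **not** emulate: informative missingness or
measurement timing linked to health state, in-hospital medication,
genotype-level data (scores are drawn, not computed), competing risks of
death, secular trends in prescribing, and pharmacokinetic differences
between agents beyond the dose-equivalence table.  Passing recovery tests
therefore demonstrates that the estimators recover the generating process
at realistic scale and censoring — not that real registry data meet these
assumptions.

## Validation problem sizes

The recovery experiments (shared by the test suite and
`scripts/acceptance.py`) use: 1,000 random histories for the exact
exposure-oracle check; 50 replicates of 677/2,708 survival cohorts for Cox
recovery; 100 replicates at n = 3,385 for the logistic odds ratio; 50
replicates of a 200-case (1:4-matched) cohort for the mixed-model ladder —
the smallest size at which likelihood-ratio selection is comfortably
powered — and 8 full-size (677-case) refits for the decade-gain closed
loop, averaging out the extrapolation variance of the quartic; 10,000
draws for the non-overlap rule; 100 random 5-case pools for the matching
benchmark.

## Known limitations

* The exact formulas behind some published exposure variables (window
  anchoring, batch threshold) are conventions documented here and
  configurable, not transcriptions.
* Greedy nearest-neighbour matching is order-dependent and not globally
  optimal; deviations from the optimal assignment are measured and
  reported rather than prevented.
* Index-date inheritance for controls is an analytic convention; real
  analyses might instead sample control index dates.
* The quartic treatment-years term is a smooth approximation; its
  behaviour beyond ~10 accumulated treatment years rests on few frequent
  attenders and should be read as extrapolation.
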
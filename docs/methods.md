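# Methods

This note documents the models and procedures implemented in `akdscreen`,
the parameter choices that matter, and what the synthetic cohorts do and do
not emulate.

## Risk scoring

The screening instrument is a purely additive integer score over seven
binary presentation symptoms with fixed points {vomiting-related dehydration
4, low-oral-intake dehydration 2, weakness 2, reported oliguria 8,
hypotension 8, appetite loss 8, swelling 5} and cutoff 10. The weights are
inputs to this package, not re-derived here. Scoring decisions:

* Missing symptom flags are **rejected**, not imputed as absent — imputation
  can only deflate the score and silently hide at-risk patients. A
  permissive `absent_if_missing` mode exists for messy field data.
* The hypotension item takes a clinician-supplied flag when present
  (covering "relative hypotension", which no threshold captures); otherwise
  it is derived from a measured blood pressure as systolic < 90 **or**
  diastolic < 60 mmHg, the conventional disjunctive reading of "< 90/60".
* The score route takes precedence over the judgment route, so the two
  inclusion routes partition the included cohort; clinical judgment can only
  add patients below the cutoff, never re-label those above it.
* Dehydration from vomiting and from low oral intake are independent
  additive items, and derived hypotension carries the same 8 points as the
  clinician flag.

## eGFR

Default equation is the 2021 race-free CKD-EPI refit (intercept 142,
κ = 0.7/0.9, α = −0.241/−0.302 for women/men, common slope −1.200, age decay
0.9938/yr, female multiplier 1.012). Because field deployments during
2018–2020 may have used the earlier equation, the 2009 CKD-EPI equation with
its race coefficient dropped ships as the variant `ckd_epi_2009_no_race`;
the choice is a config item, never silent. The equation is strictly
decreasing and continuous in creatinine (the two power branches agree at κ),
which the suite asserts; its numerical inverse (used by the generator) is a
bisection on [0.05, 40] mg/dL, accurate to well below 1e−6 in eGFR. The
package is adult-only (age ≥ 18); creatinine is handled in mg/dL with
µmol/L inputs divided by 88.42 at ingestion.

## Baseline creatinine and KDIGO staging

Baseline is the minimum of (a) the latest pre-admission value within a
365-day look-back and (b) the lowest value during the admission (enrollment,
in-admission and discharge contexts). No precedence between the two sources
is inherent, so the minimum is used — maximising AKI sensitivity — with
provenance recorded and a `pre_admission_preferred` policy switchable in
config. A singleton enrollment measurement is its own (degenerate) nadir.
Baselines are never imputed from an assumed eGFR; without any usable
candidate the patient's AKI status is "not assessable" (stage 0 with a
flag), not an exception.

AKI is present when creatinine rises ≥ 0.3 mg/dL between two measurements
≤ 48 h apart, or reaches ≥ 1.5× baseline within 7 days of the window
anchor. True onset is unobserved, so the anchor is:

* the pre-admission measurement's time, when that measurement defines the
  baseline — an old outpatient baseline therefore does *not* let a flat,
  elevated admission fire the ratio criterion (such patients are sub-acute,
  AKD without AKI);
* otherwise the first in-admission measurement's time (rolling,
  presumed-recent-onset) — ties between the two baseline candidates anchor
  in-admission, so a fully recovered admission (nadir equal to the
  pre-admission value) remains assessable.

Stages: 1 for peak/baseline in [1.5, 2.0) or the absolute-rise criterion
alone; 2 for [2.0, 3.0); 3 for ≥ 3.0, for SCr ≥ 4.0 mg/dL with an acute-rise
criterion also met (so stable advanced CKD is not staged as AKI), or when
KRT is initiated. The stage is the maximum attained across the non-follow-up
series. Urine-output criteria are out of scope (not recorded under this
protocol).

## Classification

Priority rules, exactly one category per classifiable patient:

1. any AKI stage → **AKD with AKI**;
2. kidney dysfunction (enrollment eGFR < 60 mL/min/1.73 m², or SCr > 1.5×
   baseline) with duration < 90 days **or unknown** → **AKD without AKI** —
   unknown-duration dysfunction defaults to acute, matching the screening
   intent and the small chronic fraction observed under it;
3. eGFR < 60 with documented duration ≥ 90 days (`chronicity_evidence`, an
   input label) → **CKD**;
4. otherwise **NKD**.

Recovery at discharge and at day 90 is graded against baseline: complete
below 1.25×, none at ≥ 1.5× or ≥ baseline + 0.3 mg/dL, incomplete between,
unknown when no repeat value exists. These thresholds are KDIGO-consistent
conventions, config-exposed; in the narrow regime baseline < 1.2 mg/dL the
"none" and "complete" bands can overlap, and "none" takes precedence. The
90-day window accepts the follow-up measurement nearest day 90 between days
60 and 120, measured from admission (discharge dates are not part of the
record schema). An AKD patient with day-90 eGFR < 60 is flagged as a new
CKD transition; a missing day-90 value is "not assessable", distinct from
negative.

## Synthetic cohorts

The generator emulates a pooled screening cohort of included (at-risk)
adults. Defaults, all config-exposed:

* **Mixture**: exact count ratios 634/2288/37/1352 of 4311 for
  AKD-with-AKI / AKD-without-AKI / CKD / NKD (14.7/53.1/0.9/31.4%); AKI
  stage mix 391/140/103 of 634.
* **Demographics**: 53.1% female; age from a reflected log-normal
  (154.5 − LogNormal(4.5799, 0.2122)) truncated to [18, 100], solved once
  from median 57 and IQR 42–70.
* **Kidney trajectories**: a true baseline eGFR is drawn per category
  (NKD 70–115; CKD 20–55; AKI baselines 65–110), inverted to creatinine, and
  multiplied by an acute excursion — U[1.5, 1.9], U[2.0, 2.9], U[3.0, 5.0]
  by AKI stage; U[1.5, 2.5] for sub-acute dysfunction. Sub-acute
  (baseline, multiplier) pairs are redrawn until the enrollment eGFR lands
  below 55: reduced function at presentation is what the category *means*,
  and the margin keeps device noise from flipping diseased patients across
  the 60 threshold. AKI courses carry an enrollment peak, a partial-recovery
  point at 48 h and a discharge value back at baseline; sub-acute courses
  are flat-elevated with spacing that defeats the 48-h and 7-day AKI
  windows, because the two AKD forms are operationally distinguished only
  through the KDIGO timing criteria. A pre-admission baseline measurement
  exists with probability 0.3, placed 2 weeks–6 months before admission.
* **Measurement**: 73.0% of patients are measured at the point of care;
  noise is proportional Gaussian with CV 7% (POC) and 3% (laboratory) —
  realistic for a handheld meter versus a central analyser, as no device
  error model is prescribed. Values are reported to 2 decimals (device
  precision; `scr_decimals=None` gives exact values).
* **Symptoms**: the three kidney-disease categories share one elevated
  Bernoulli vector and NKD a background vector. The pair was calibrated
  once — coordinate descent followed by a simplex polish on the *exact*
  score distribution (128 profiles), constrained to background ≤ disease
  per symptom — so the score attains AUROC 0.824, sensitivity 92.9% and
  specificity 58.9% at cutoff 10 essentially exactly; the frozen vectors
  ship as defaults. Three scalar targets under-determine fourteen
  probabilities, so this is one acceptable solution, not an estimate of the
  real symptom distribution. `calibrate_symptom_probs` re-runs the search
  for other targets, validating the result by seeded simulation.
* **Inclusion**: every generated patient is an included patient; those with
  score < 10 carry `clinical_judgment = 1` (that is how they entered),
  which reproduces the observed ~74/26 split between the two routes.
* **Outcomes**: death 0.5% (NKD), 2% (CKD), 2.8% (sub-acute AKD), 1/3/12%
  by AKI stage — jointly ≈ 2.9% of AKD; KRT indicated in 31.1% of stage 3
  (≈ 1.1% of AKD) and provided in 81.3% of those; transfer recommended in
  6.1% of AKD with 74.2% occurring; follow-up attended by 62.3% of
  surviving AKD patients, with a repeat creatinine in 90% of attendees and
  persistent dysfunction in half.

**What passing tests show — and don't.** The generator reproduces the
*marginal* structure the analysis assumes: mixture weights, stage bands,
score operating characteristics, noise magnitudes, outcome rates. It does
not model site heterogeneity (the four countries differ markedly in case
mix and inclusion practice), etiology-specific trajectories, correlated
symptoms, informative missingness of follow-up creatinine, or death-censored
trajectories. Pipeline concordance on synthetic data therefore demonstrates
internal correctness of the classification logic under the stated model,
not performance on real field data. One visible artefact: measurement noise
inflates the in-admission peak/nadir ratio, so classified stage mixes shift
toward stage 2 relative to latent truth in noisy cohorts; noiseless
configurations recover latent category and stage essentially exactly.

## Reporting conventions and numerics

Percentages are rounded **half away from zero** to one decimal — required
to reproduce printed values such as 26/32 → 81.3% — never banker's
rounding. Medians/IQRs use linearly interpolated (type-7) quartiles; the
quartile method of the original tables is unknowable, so it is
config-relevant only for display. AUROC uses the rank (Mann–Whitney)
formulation with ties counting one half, appropriate for an integer score;
the suite cross-checks it against exhaustive pair enumeration and
scikit-learn. A zero denominator renders as an em-dash rather than raising.

## Problem sizes

Default test and script sizes — 20 000 patients for operating
characteristics (binomial SE ≈ 0.3 points on sensitivity), 2 000 for
noise-free parameter recovery, 5 000 for prevalence and cohort summaries —
were chosen so every stochastic check has comfortable margin over its
sampling error while the whole suite runs in well under a minute.

## Known limitations

* Urinalysis/urine-output criteria, pediatric equations, structural AKD
  criteria and etiology inference are out of scope by design.
* The follow-up window is anchored at admission, not discharge.
* Site-level (per-country) simulation is not attempted; only the pooled
  cohort is modelled.
* The calibrated symptom vectors are not identifiable from three targets;
  they should not be interpreted as epidemiological estimates.
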
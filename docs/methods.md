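# Methods

`mortsens` quantifies how incomplete death ascertainment in an EHR-derived
cohort biases time-to-event analyses, by comparing every analysis against a
benchmark computed with a gold-standard mortality source on the same
patients. This note records the model, the study conditions encoded in the
defaults, the numerical conventions, and what the synthetic checks do and
do not demonstrate.

## Mortality-capture model

Each patient carries up to two death dates: one from the EHR-derived source
and one from the gold standard (a death-index linkage treated as complete).
Classification uses only the *presence* pattern:

| cell | EHR death | gold death | role |
|------|-----------|------------|------|
| A    | yes       | yes        | true positive |
| B    | yes       | no         | false positive |
| C    | no        | yes        | false negative |
| D    | no        | no         | true negative |

Capture sensitivity is `a/(a+c)`, specificity `d/(b+d)`. Patients whose two
sources disagree on the date value are still cell A; adjudication between
discrepant dates is out of scope — each analysis simply takes the date from
the source it is assigned.

Every analysis builds one survival row per patient. If the arm's assigned
source records a death, the patient contributes `(death − index, event)`;
otherwise `(last_activity − index, censored)`. Under the gold source the
event set is exactly cells A∪C; under the EHR source, A∪B — cell-B
false-positive dates are deliberately retained as events, since that is what
an analyst confined to the EHR source would use.

## Use cases and bias

* **Descriptive**: per-arm Kaplan–Meier median OS under one source.
* **Comparative effectiveness (CER)**: Cox HR (experimental vs control) with
  both arms on the same source; the EHR-source HR is compared with the
  gold-source HR.
* **External control**: experimental arm keeps gold dates (a single-arm
  trial with near-perfect mortality follow-up), control arm uses EHR dates
  (an external control assembled from routine data). The benchmark is the
  gold/gold HR — identical to the CER benchmark.

Bias is `estimate − benchmark` (months for medians, HR units for hazard
ratios) and `100·(estimate − benchmark)/benchmark` percent, the latter
rounded to one decimal. Report tables round medians and percent bias to one
decimal and HRs to two, matching how such results are conventionally
printed.

## Sensitivity degradation

To emulate a lower-sensitivity source, a fraction `p` of cell A is
reclassified to cell C: the EHR death date is removed and the patient is
re-censored at a date drawn uniformly on `[index, gold_death)`. The uniform
law is a modelling choice; the procedure it mimics says only that the censor
date is randomly assigned between diagnosis and death. Expected sensitivity
after reclassification is `(1−p)·a/(a+c)`: from 90.6% the fractions
p = 0.30 and p = 0.20 give 63.4% and 72.5%.

One run draws `round(p·|A|)` patients (round-half-to-even; a zero count
makes the iteration a logged no-op) by simple random sampling *without*
replacement — a patient cannot be reclassified twice within a run. Across
the study's iterations (default 1000) the subset and all censor dates are
redrawn independently; each iteration gets its own `SeedSequence` substream
of the master seed, so runs are reproducible and individually replayable.
A statistic evaluated per iteration is summarised by its median (point
estimate) and 2.5th/97.5th percentiles (interval). For external-control
analyses only the control arm's cell-A patients are eligible, since the
experimental arm keeps gold dates by construction.

## Survival estimation conventions

Estimation is delegated to lifelines behind the module surface. The KM
median is the smallest time where the survival curve reaches 0.5 or below
(smallest-t convention on flat segments); its 95% CI inverts the
log−log-transformed Greenwood pointwise bounds (Brookmeyer–Crowley style).
A curve that never reaches 0.5 has an open median, reported as `inf`
in-memory and `null` in JSON. With zero events the median is flagged open,
not raised. Cox models use a single binary arm covariate with the Efron tie
correction — integer-day data guarantees ties — and a 95% Wald interval;
arms with no events raise an explicit error rather than returning a
non-converged fit. Times are internally days; medians are reported in months
at 30.4375 days/month. Deaths on the index day are shifted to half a day so
no event is dropped.

## Synthetic cohort: what it emulates

The generator produces a two-arm cohort with the structure above. Dates are
integer days from a study origin (no calendar realism). Defaults are the
study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_per_arm` | 5000 | ~10⁴-patient cohort |
| `baseline_hazard` | ln 2/(9·30.4375) d⁻¹ | control-arm median OS 9 months, typical of first-line chemotherapy in advanced NSCLC |
| `true_hr` | 0.85 | ≈ inverse ratio of 9.0- vs 7.7-month arm medians |
| `accrual_window` | (0, 1826) d | five years of uniform accrual |
| `cutoff_day` | 1826 | administrative cutoff at accrual end |
| `target_sensitivity` | 0.906 | observed EHR death capture |
| `false_positive_rate` | 0.04 | ≈ 136/3399 among patients without a gold death |
| `gap_shape`, `gap_scale` | 0.723, 2.649 mo | two-point Weibull fit below |
| `loss_to_followup_rate` | 2·10⁻⁴ d⁻¹ | occasional network departure |

Survival is exponential per arm, so proportional hazards hold exactly and
parameter-recovery tests have analytic truths. Captured deaths carry an EHR
date equal to the gold date (source analyses vary the *source*, not date
error). False-positive EHR deaths are uniform on `[index, cutoff]`; no
mechanism is claimed for them — they are rare and only need to exist.

**Gap calibration.** For uncaptured deaths, last activity precedes death by
a gap `G` with `P(G ≤ 1 mo) = 0.39` and `P(G ≤ 4 mo) = 0.74`, the observed
clustering of last activity shortly before unrecorded deaths. A Weibull
solves both anchors in closed form (shape 0.723, scale 2.649 months); an
exponential cannot, since the implied shape differs from 1. The fitted
shape < 1 gives a long right tail: most hidden deaths are censored very
close to death (strongly informative censoring), a few long before.

**Truncation caveat.** In a generated cohort `last_activity = death − G` is
floored at the index date, so the *observed* gap `death − last_activity`
among cell-C patients is `min(G, death − index)` — stochastically smaller
than `G`. Under the defaults this inflates the observed ≤1-month fraction
from ~39% to ~45%. The gap-law checks therefore measure draws from
`draw_activity_gaps` (the exact routine the generator consumes), and a
separate directional test confirms that observed cell-C gaps cluster at
least as strongly as the drawn law.

## What the synthetic checks show — and do not

Passing tests show the machinery is internally consistent: classification
arithmetic is exact; the degradation engine realises its closed-form
expected sensitivities; estimators recover analytic truths on exponential
data; median-OS bias is positive and grows as sensitivity falls; CER HRs
are robust to *equal* missingness; external-control HRs shift against the
experimental arm and the shift grows as control-arm sensitivity drops.
They do not show how large those biases are in any real cohort: real data
have covariate-dependent hazards, non-proportional effects, calendar
artefacts, date disagreements between sources and richer loss-to-follow-up
behaviour, none of which the generator models.

One quantitative note: at 90% control-arm sensitivity with true HR 0.9, the
simulated external-control HR shift concentrates near +0.07, not under
0.05. That magnitude is forced by the mechanism — hiding ~10% of control
events while the gap-calibrated censoring retains almost all person-time
deflates the control hazard by ~8%, and `0.9·(1/0.92 − 1) ≈ 0.07` — and
matches the reported external-control example (gold HR 0.90 vs EHR 0.97).
The corresponding suite check asserts the stricter 0.05 bound and is
expected to fail under the default conditions; it is retained as a
documented tension rather than relaxed.

## Problem sizes

Default checks use cohorts of 10³–2·10⁴ patients, 200-replicate Monte-Carlo
loops for distributional properties, 1000 degradation iterations where the
percentile interval is the object of interest, and 10⁵ draws for the gap
law; these sizes put binomial/Monte-Carlo error well inside every asserted
tolerance.

## Known limitations

* Single binary covariate; no adjustment, stratification or matching.
* Specificity is never degraded; only sensitivity is studied.
* Exponential survival is a convenience, not a clinical claim.
* The gold standard is treated as complete; in reality no registry is.
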
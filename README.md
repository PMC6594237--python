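# mortsens

**How badly do missing deaths bias survival analyses built on EHR-derived
real-world data?**

Electronic-health-record (EHR) oncology databases capture most — but not
all — patient deaths. When an analysis censors a patient at their last
clinic visit because the death never reached the database, and that visit
happened shortly *before* the unrecorded death, the censoring is
informative and overall-survival estimates inflate. `mortsens` is a toolkit
for studying this, aimed at epidemiologists and RWE methodologists. It

1. **classifies** each patient's mortality capture against a gold-standard
   source into the four confusion cells — A (death in both sources),
   B (EHR only), C (gold only), D (neither) — giving capture sensitivity
   `a/(a+c)` and specificity `d/(b+d)`;
2. **degrades** sensitivity by stochastic reclassification: a fraction *p*
   of cell A loses its EHR death date and is re-censored uniformly between
   index and true death, dropping sensitivity to `(1−p)·a/(a+c)` in
   expectation, with statistics summarised over many independent draws by
   their median and 2.5/97.5 percentiles;
3. **quantifies bias** in Kaplan–Meier median OS (mOS) and Cox hazard
   ratios (HR) for three analytic use cases — descriptive mOS, comparative
   effectiveness (both arms one source), and an external control arm
   (experimental arm on gold dates, control arm on EHR dates) — each
   against the gold-standard benchmark on the same patients;
4. **generates** synthetic two-arm cohorts with the right statistical
   structure (exponential survival per arm, configurable capture
   sensitivity, rare false-positive deaths, and last-activity dates that
   cluster a Weibull-distributed gap before uncaptured deaths), so the
   whole pipeline is testable without proprietary data.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```bash
mortsens simulate --n-per-arm 2000 --seed 17 --out cohort.csv
mortsens classify --in cohort.csv --out classified.csv --counts-out counts.json
mortsens analyze  --in cohort.csv --fractions 0.2,0.3 --iterations 200 \
                  --seed 17 --out report.json
mortsens report   --in report.json
```

prints (abridged):

```
Cells A/B/C/D: 2671/34/272/1023  sensitivity 90.8%  specificity 96.8%

Median overall survival (months)
Arm           Simulated p=0.2   Bias, %  Simulated p=0.3   Bias, %  EHR-derived       Bias, %  Gold standard
experimental  13.1 (12.9-13.5)  25.1     14.5 (13.9-14.8)  38.2     11.3 (10.4-12.1)  7.5      10.5 (9.7-11.3)
control       11.2 (10.9-11.5)  26.9     12.3 (11.9-12.7)  39.2     9.4 (8.7-10.1)    6.3      8.8 (8.2-9.4)

Comparative effectiveness (HR)
Analysis          HR (95% CI)       Bias, %
benchmark (gold)  0.89 (0.83-0.95)  -
ehr               0.88 (0.82-0.95)  -0.9
simulated p=0.3   0.88 (0.84-0.91)  -1.5

External control arm (HR)
Analysis          HR (95% CI)       Bias, %
benchmark (gold)  0.89 (0.83-0.95)  -
ehr               0.94 (0.88-1.01)  6.1
simulated p=0.3   1.20 (1.19-1.22)  35.4
```

Reading it: at ~91% death capture, median OS is biased upward by a modest
~6–8% (control arm 9.4 vs 8.8 months); when capture is degraded to ~63%
(p = 0.3) the inflation reaches ~39%. The comparative-effectiveness HR
barely moves because both arms miss deaths equally. The external-control
HR, whose arms draw deaths from *different* sources, drifts against the
experimental arm — from 0.89 to 0.94 at observed capture, and past the
null to 1.20 at 63% — which is exactly the risk this framework measures: a
truly effective therapy can look inert against an external control with
incomplete mortality data.

The same run is available from Python:

```python
from mortsens import GeneratorConfig, generate_cohort, run_full_study

cohort = generate_cohort(GeneratorConfig(n_per_arm=2000, seed=17))
report = run_full_study(cohort, degradation_fractions=(0.2, 0.3),
                        n_iterations=200, seed=17)
```

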
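# filab

Laboratory frailty index (FI-Lab) scoring and survival analysis for
ICU cohorts, with a synthetic EHR cohort simulator.

## The problem

Frailty — depleted physiological reserve across organ systems — is a
strong prognostic marker in critical care, but classical frailty
instruments need bedside assessment (gait speed, grip strength) that is
impractical for sedated ICU patients.  The *laboratory* frailty index
sidesteps this: it counts deficits directly from admission data already
in the chart.  Given a registry of `k` items (routine blood tests,
arterial blood gases, urinalysis, vital signs), each measured item is
dichotomized against its reference interval and

```
FI-Lab = (number of out-of-range items) / (number of measured items)  ∈ [0, 1]
```

Stays missing more than 12 of the default 33 items are considered
unscorable.  The package is aimed at clinical epidemiologists who want
to build this score from MIMIC-style long-format extracts and reproduce
the standard analysis battery around it:

* Cox proportional-hazards models of 28-day, ICU and 90-day mortality
  with the score entered per 0.1 unit or as tertiles (T1 reference,
  trend test), under nested adjustment sets;
* restricted cubic spline dose-response curves with a Wald test for
  non-linearity;
* Kaplan–Meier curves by tertile with the log-rank test;
* stratified subgroup analysis with interaction tests;
* ROC comparison of FI-Lab against severity scores (SOFA, APACHE II)
  using DeLong variances, paired DeLong tests and Youden-index cutoffs;
* a Table-1-style baseline summary with distribution-aware tests.

Because credentialed EHR data cannot ship with code, the package
includes a first-class synthetic cohort generator
(`filab.simulate`) that emits raw stays / lab-events / vitals tables
with *known* ground truth: per-item deficit indicators, the true score,
and exponential survival times whose log-hazard is linear in the true
score plus covariate effects.  Every downstream stage is validated
against that truth.

## Worked example

Generate 20,000 synthetic stays whose true 28-day hazard ratio per
0.1 FI-Lab units is 1.32, then refit (see
`examples/02_simulate_and_recover_hr.py`):

```python
import math
from filab import SimulationConfig, generate_cohort, fit_cox

cfg = SimulationConfig(n_patients=20_000, seed=42,
                       beta_filab_per_0_1=math.log(1.32),
                       covariate_effects={})
tables = generate_cohort(cfg)
df = tables.stays.assign(filab_per_0_1=tables.truth["score_true"] / 0.1)
fit = fit_cox(df, outcome="mortality_28d", adjustment="unadjusted")
```

which prints

```
true HR per 0.1 unit      : 1.32
recovered HR (95% CI)     : 1.309 (1.251-1.371)
events / n                : 2367 / 20000
```

The recovered hazard ratio sits within sampling noise of the
generating value — the 28-day event rate (~13%) and score distribution
(mean ≈ 0.48) match the conditions the generator is calibrated to.
The other scripts in `examples/` cover single-stay scoring, the full
pipeline (exclusion cascade, adjusted Cox table), spline/KM analysis,
and ROC comparison; each prints a short annotated result.

The full pipeline is also exposed as a CLI:

```bash
filab run-all --seed 7 --out-dir filab_run        # all stages + report.md
filab simulate --seed 3 --n-patients 500 --out-dir data/
filab score --data-dir data/ --out scores.csv
```

## Layout

```
src/filab/
  registry.py   item registry (33-item default, user-overridable CSV)
  score.py      windowing, dichotomization, FI-Lab computation, tertiles
  simulate.py   synthetic cohort generator with ground truth
  cohort.py     exclusion cascade, imputation, VIF screening
  survival.py   Cox / splines / KM / subgroups
  roc.py        DeLong AUC machinery, Youden cutoffs
  report.py     baseline (Table-1 style) summaries, run report
  pipeline.py   orchestration + manifest
  cli.py        thin click CLI
docs/methods.md the model, its assumptions, and design choices
examples/       one narrative script per capability
```
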
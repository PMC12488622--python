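# Methods

## The score

The laboratory frailty index treats each out-of-range admission
measurement as one accumulated health deficit.  For a registry of
items (default 33: 20 blood tests, 4 arterial blood-gas values, 6
urinalysis items, 3 vital signs), the score is

    FI-Lab = n_deficits / n_measured ∈ [0, 1].

Item handling conventions, where the field's practice is not fully
standardized, are fixed as follows and are configurable:

* **Windows.** Laboratory items count from 6 h before to 24 h after
  ICU admission; vital signs over the first 24 h.  Window endpoints
  are inclusive — the least surprising reading of "within".
* **Aggregation.** Labs use the chronologically first in-window value
  (it reflects admission state), ties broken by input order; vitals
  use the arithmetic in-window mean.
* **Dichotomization.** Reference intervals are closed: a value equal
  to a bound is normal, matching conventional laboratory flagging.  A
  one-sided interval is unbounded on the missing side.  Categorical
  urinalysis items are deficits when the reported category is in the
  item's abnormal set (any trace/1+/2+/3+/positive report by default).
* **Denominator.** Measured items, not the fixed registry length.
  Allowing up to 12 missing items while dividing by 33 would compress
  the scale for missing-heavy stays; dividing by the measured count
  preserves the 0–1 range.  A `denominator="fixed_total"` switch
  exposes the alternative reading for sensitivity analyses.
* **Eligibility.** More than 12 missing items ⇒ no score.
* **Tertiles.** Half-open intervals: T1 = [0, c1), T2 = [c1, c2),
  T3 = [c2, 1].  Cutpoints may be supplied (the published ICU-asthma
  values are 0.43/0.54) or computed as cohort 33rd/67th percentiles.
* **Reference ranges.** The shipped registry uses conventional adult
  clinical reference intervals in US customary units; they are
  deliberate, documented substitutes for source-specific ranges and
  every row is user-overridable via a registry CSV.

## The synthetic cohort

The generator emulates the statistical structure of a MIMIC-style
ICU-asthma extract, not its surface detail.  Per stay:

* **Deficits.** Item deficits are Bernoulli draws with per-item
  probabilities chosen to give a mean score near 0.48 (the center of
  the score distribution in published ICU asthma cohorts) and
  plausible item-to-item variation.  An optional single latent
  frailty factor (Gaussian one-factor copula, `latent_correlation`)
  induces positive inter-item correlation; the default is independent
  items.  Neither mode is claimed to match any real dependence
  structure.
* **Records.** Non-deficit numeric values are uniform inside the
  reference interval; deficit values sit 10–50% of the interval width
  beyond a random bound (value magnitude is irrelevant after
  dichotomization).  Missing items emit no record.  Lab chart times
  are uniform on the lab window, vitals on [0, 24] h (three repeats of
  one value, so the mean equals it); a configurable fraction of lab
  records is displaced outside the window to exercise window
  filtering.
* **Survival.** Exponential proportional hazards: the log-hazard is
  `beta_filab_per_0_1 × (score − 0.48)/0.1` plus centered covariate
  effects.  The baseline rate 4.378 × 10⁻³/day was calibrated once,
  numerically, so that the marginal 28-day event rate under the
  default parameters is 13.2% — the published cohort's rate.  The
  exponential baseline is a deliberate simplification: Cox estimation
  is baseline-agnostic and a constant hazard gives closed-form checks.
  Its cost is that later-horizon event rates exceed those of real ICU
  cohorts (real hazards fall after the acute phase), so 90-day event
  counts are generous rather than realistic.
* **ICU mortality.** An independent exponential discharge clock (rate
  0.25/day, i.e. median LOS ln 2/0.25 ≈ 2.8 days, the published
  median) competes with death; ICU death = death before discharge.
  This is the simplest mechanism giving ICU mortality below 28-day
  mortality; it understates real ICU death fractions because the
  constant death hazard does not concentrate risk in the stay.
* **Covariates.** Age, sex, race, severity scores, comorbidity flags
  and interventions are drawn from fixed simple distributions whose
  locations/prevalences follow published ICU-asthma cohort summaries.
  They are generator inputs for parameter-recovery testing, not fits
  to any dataset; treatments are inert covariates (no treatment
  effects are simulated).
* **Rule violators.** Configured fractions of stays violate each
  inclusion rule (minors, <24 h stays, pregnancy, >12 missing items,
  repeat admissions, missing required first-day fields) so the filter
  cascade is exercised; ICU LOS for non-violators is floored at just
  over one day, emulating an admission cohort conditioned on a ≥24 h
  stay.

What passing tests on this generator do show: the scorer reproduces a
known truth exactly; the survival machinery recovers known hazard
ratios; the inferential tests hold their nominal error rates.  What
they do not show: robustness to unit mismatches, irregular sampling,
informative missingness, or dependence structures of real EHR data.

## Cohort assembly

Filters run in a fixed, logged order — repeat stays, age < 18, LOS
< 24 h, pregnancy, missing required first-day fields (respiratory
rate, bicarbonate, glucocorticoid, montelukast), FI-Lab ineligibility
— because cascade counts are order-dependent; the exclusion log makes
the order auditable and the cascade is idempotent.

Covariates with under 1% missingness are resolved by complete-case row
removal (a column-dropping mode exists behind a switch, default rows,
since the same variables appear in later models).  Heavier missingness
(PaO₂/FiO₂, ~15% by default) is completed by chained-equation single
imputation: scikit-learn's iterative imputer with a Bayesian ridge
regressor per round-robin step, max 10 cycles, tolerance 10⁻³ on the
maximum absolute cell change, deterministic given the seed.  Observed
cells are never altered.  Multicollinearity is screened by variance
inflation factors (1/(1−R²), flag above 2; perfect collinearity
reports an infinite VIF rather than raising).

## Survival analysis

* **Adjustment sets** are nested and configurable; the defaults layer
  demographics (model 1: age, sex, race), severity (model 2: + SOFA,
  APSIII, CCI) and comorbidities/interventions (model 3).  The
  allocation is a conventional choice, recorded in output metadata,
  not a claim about any particular study's unpublished sets.
* **Ties.** Efron (lifelines) by default; Breslow routes to
  statsmodels PHReg.
* **Tertile trend.** The trend p-value comes from refitting with the
  tertile index (0, 1, 2) as a single ordinal term, not from a Wald
  contrast on the categorical fit.
* **Splines.** Harrell's restricted-cubic basis with 4 knots at the
  5/35/65/95th percentiles (3–7 knots supported); non-linearity is the
  Wald chi-square that all non-linear coefficients vanish.  The curve
  is centered at a configurable reference (cohort median by default,
  where HR = 1 exactly — the reference point is inserted into the
  evaluation grid so the identity is exact, not interpolated).
* **Time origin** is ICU admission; 28/90-day outcomes are
  administratively censored at their horizons, ICU mortality at
  discharge.
* **Degenerate inputs.** Zero events or a constant exposure raise a
  fit error; a zero-event subgroup stratum is reported non-estimable
  rather than failing the whole analysis.

## Discrimination

AUC is the midrank Mann–Whitney statistic; variance and paired
covariance come from DeLong structural components (per-observation
placement values), with normal-approximation CIs truncated to [0, 1].
The Youden cutoff maximizes sensitivity + specificity − 1 over
observed thresholds under a "score ≥ cutoff ⇒ positive" rule, ties
broken toward the lower threshold.  Identical paired scores give a
degenerate variance and are reported as z = 0, p = 1.  Cutoffs are
reported on the raw score scale only; no claim is made about cutoffs
published on other (e.g. predicted-probability) scales.  These
routines are hand-written because no installed dependency exposes the
DeLong variance/covariance machinery; tests pin them to exhaustive
pair counting and to bootstrap variances.

## Baseline summaries

Continuous variables route to mean ± SD with one-way ANOVA when every
group passes Shapiro–Wilk at α = 0.05 (subsampled to 5,000 beyond
that size), otherwise median (IQR) with Kruskal–Wallis.  Categorical
variables use chi-square, except 2×2 tables with any expected cell
≤ 5, which use Fisher's exact test.  The normality rule is a fixed
decision where the field usually says only "as appropriate".

## Problem sizes in the test suite

Hazard-ratio recovery runs at n = 20,000 (the acceptance-scale
experiment).  Null-calibration suites use 100 replicates at
n ≈ 800–1,500 per replicate for the spline non-linearity and
interaction type-I error, 200 replicates at n = 300 for CI coverage,
and 1,000 replicates at n = 200 for the paired DeLong null — sizes at
which these n-free properties (error rates, coverage) are measured
with binomial precision a 3σ band can adjudicate.

## Known limitations

* The generator's constant baseline hazard overstates late mortality;
  calibration holds at the 28-day horizon it was fixed at.
* ICU death fractions are lower than in real ICU cohorts (see above).
* No unit conversion: inputs must match registry units.
* Single imputation only; no multiple-imputation pooling or MAR/MNAR
  sensitivity analysis.
* No time-dependent ROC, calibration analysis, competing-risks
  (Fine–Gray) models, or proportional-hazards diagnostics beyond what
  lifelines exposes.
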
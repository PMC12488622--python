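"""Generate a synthetic ICU cohort and recover the FI-Lab hazard ratio.

The generator draws per-item deficits, emits raw lab/vital records,
and assigns exponential survival times whose log-hazard rises by a
known amount per 0.1 FI-Lab units.  Refitting a Cox model on the true
score should recover that hazard ratio — the core validity check for
the whole pipeline.
"""

import math

from filab import SimulationConfig, fit_cox, generate_cohort

TRUE_HR = 1.32          # per 0.1 FI-Lab units

cfg = SimulationConfig(
    n_patients=20_000,
    seed=42,
    beta_filab_per_0_1=math.log(TRUE_HR),
    covariate_effects={},       # isolate the FI-Lab effect
)
tables = generate_cohort(cfg)

df = tables.stays.copy()
df["filab_per_0_1"] = tables.truth["score_true"] / 0.1

fit = fit_cox(df, outcome="mortality_28d", coding="per_0_1_unit",
              adjustment="unadjusted")
row = fit.terms.set_index("term").loc["filab_per_0_1"]
print(f"true HR per 0.1 unit      : {TRUE_HR:.2f}")
print(f"recovered HR (95% CI)     : {row['hr']:.3f} "
      f"({row['ci_low']:.3f}-{row['ci_high']:.3f})")
print(f"events / n                : {fit.n_events} / {fit.n}")
# the recovered HR should sit within a few percent of the generating
# value; its CI quantifies pure sampling noise at this cohort size.
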
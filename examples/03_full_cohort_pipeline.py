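"""Run the complete pipeline: simulate -> score -> filter -> analyze.

Produces every table a cohort study of FI-Lab and ICU mortality needs
(baseline characteristics by tertile, Cox models, spline curve, KM
curves, subgroup forest, ROC comparison) in one reproducible run, then
prints the exclusion cascade and the fully adjusted hazard ratios.
"""

import pandas as pd

from filab.pipeline import run_pipeline

config = {
    "simulation": {
        "n_patients": 2339,
        "filter_violation_fractions": {
            "repeat_stay": 0.03, "age_under_18": 0.02,
            "los_under_24h": 0.03, "pregnancy": 0.01,
            "excess_missing_items": 0.02, "missing_required_field": 0.02,
        },
    },
}

manifest = run_pipeline(config, out_dir="filab_run", seed=7)
print("stage timings (s):", manifest["stages"])

log = pd.read_csv("filab_run/exclusion_log.csv")
print("\nexclusion cascade:")
print(log.to_string(index=False))

cox = pd.read_csv("filab_run/cox_results.csv")
adj = cox[(cox["model"] == "model3") & (cox["coding"] == "per_0_1_unit")
          & (cox["term"] == "filab_per_0_1")]
print("\nfully adjusted HR per 0.1 FI-Lab units:")
print(adj[["outcome", "hr", "ci_low", "ci_high", "p"]].to_string(index=False))
# each row is the multiplicative increase in the death hazard per 0.1
# FI-Lab units after adjustment for demographics, severity scores,
# comorbidities and interventions; see filab_run/report.md for the
# full table set.
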
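"""Compare the discrimination of FI-Lab against severity scores.

Computes AUCs with DeLong confidence intervals for predicting 28-day
mortality, the Youden-index optimal cutoff for each score, and paired
DeLong tests between score pairs.
"""

from filab import SimulationConfig, generate_cohort, score_stays, roc_table
from filab.cohort import apply_filters, prepare_analysis_table
from filab.registry import load_registry

registry = load_registry()
tables = generate_cohort(SimulationConfig(n_patients=4000, seed=9))
scores = score_stays(tables.lab_events, tables.vitals, registry,
                     stay_ids=tables.stays["stay_id"],
                     tertile_cutpoints="empirical")
cohort, _ = apply_filters(tables.stays, scores)
cohort = prepare_analysis_table(cohort)

roc = roc_table(cohort, ["score", "sofa", "apache_ii"], outcome_col="death_28d")
print("per-score discrimination for 28-day mortality:")
for _, r in roc.per_score.iterrows():
    print(f"  {r['score']:<10} AUC {r['auc']:.3f} "
          f"({r['ci_low']:.3f}-{r['ci_high']:.3f})  "
          f"Youden cutoff {r['cutoff']:.3g} "
          f"(sens {r['sensitivity']:.2f}, spec {r['specificity']:.2f})")

print("\npairwise DeLong tests:")
for _, r in roc.pairwise.iterrows():
    print(f"  {r['score_a']} vs {r['score_b']}: "
          f"dAUC {r['auc_diff']:+.3f}, z {r['z']:+.2f}, p {r['p']:.3f}")
# in this synthetic cohort the severity scores are pure covariates
# (not causally tied to the simulated hazard through FI-Lab), so
# FI-Lab should discriminate best; a p above 0.05 means two scores'
# AUCs are statistically indistinguishable.
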
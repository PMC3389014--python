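"""Simulate a two-group volumetric cohort and classify it end to end.

Generates 20 meditators vs 20 non-meditators with 12 regional volumes, three
of which carry a standardized group difference of 2.0, then estimates
accuracy with the nested leave-one-subject-out procedure.
"""

from svmorph import (
    SyntheticConfig,
    consensus_features,
    generate_cohort,
    run_outer_loocv,
    summarize,
)

cfg = SyntheticConfig(
    n_group_pos=20, n_group_neg=20, n_regions=12,
    planted_regions=[1, 5, 9], effect_size=2.0, seed=7,
)
table = generate_cohort(cfg)
result = run_outer_loocv(table)
report = summarize(result, chance=0.5)

print(f"outer LOO accuracy : {report.accuracy_pct:.2f}% "
      f"({report.n_correct}/{report.n_total} subjects)")
print(f"binomial p-value   : {report.p_value:.2e} ({report.p_band})")
print(f"per-fold Q         : {report.per_fold_q}")
print(f"consensus regions  : {consensus_features(result)}")
print(f"planted regions    : {cfg.planted_region_names}")
print()
print("Accuracy is the fraction of held-out subjects classified correctly;")
print("the p-value is the exact binomial tail of that count under chance 0.5.")
print("Q (features kept) is re-chosen inside every outer fold, so it varies;")
print("consensus regions are those kept in every fold - the discriminative map.")
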
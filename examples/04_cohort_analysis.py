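"""Full cohort statistics: random forest ranking plus top-10 paired tests.

Uses the planted-parameter feature table of the default 35-subject paired
cohort (vision vs no-vision, three trials per subject-condition, effects in
the directions of the underlying study: lower peak angle, faster peak
flexion velocity, smaller anterior COP excursion and higher switch-phase
POz alpha/beta ratio without vision).  The forest's out-of-bag AUC on a
paired table is misleading (each row's near-twin carries the opposite
label), so subject-grouped cross-validation is used for the AUC; the
importance ranking and the Wilcoxon tests are unaffected by that choice.
"""

from posturekit import CohortConfig, planted_feature_table, run_analysis

table = planted_feature_table(CohortConfig(seed=0))
print(f"feature table: {table.shape[0]} subject-condition rows, "
      f"{table.shape[1] - 2} features")

report = run_analysis(table, k=10, seed=0, validation="grouped")
print(f"subject-grouped CV AUC = {report.ranking.auc:.2f}")
print("\ntop 10 features by Gini importance, with paired Wilcoxon results:")
for t in report.tests:
    star = "*" if t.p_value < report.alpha else " "
    print(f" {star} {t.feature:<24s} p={t.p_value:8.2e}  r={t.effect_size_r:+.2f}")
print("\n* significant at the two-sided 5% level (no multiplicity correction;"
      f" {report.n_tests} tests)")
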
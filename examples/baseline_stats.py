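"""Baseline-characteristics table for two diagnosis groups.

Compares continuous characteristics by t-test, binary ones by Fisher's exact
test (full hypergeometric enumeration) and multi-level ones by Pearson
chi-square — the row structure of a clinical Table 2.
"""

from breathomix import CohortConfig, fisher_exact_2x2, generate_cohort, baseline_table

_, metadata = generate_cohort(
    CohortConfig(class_sizes={"HNSCC": 100, "colon": 28}, seed=4)
)

table = baseline_table(metadata, "HNSCC", "colon")
print(table.to_string(index=False))

# The same machinery on a strongly imbalanced smoking contrast
# (57/100 smokers vs 4/28):
res = fisher_exact_2x2([[57, 43], [4, 24]])
print(f"\nFisher exact, smoking 57/100 vs 4/28: p = {res.p_value:.2e}, "
      f"odds ratio {res.odds_ratio:.1f}")
# p far below 0.001: a difference this large in smoking prevalence is
# essentially impossible under independence, so smoking is a confounder any
# breath-based classifier study must keep in mind.
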
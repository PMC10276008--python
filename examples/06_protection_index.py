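"""Per-gene protection index with a permutation null and planted truth.

Genes with top-decile amplification frequency and bottom-decile μ are planted
as "protected"; the permutation percentile of P = amp_scaled − μ_scaled
should recover them at the 94th-percentile rule. A three-cohort consensus
illustrates the cross-cohort call.
"""

from cnbuffer import consensus, make_protection_scores, protection_index

records = {}
planted_sets = {}
for i, cohort_name in enumerate(["lung-like", "breast-like", "colon-like"]):
    gene_df, planted = make_protection_scores(n_genes=400, seed=i)
    rec = protection_index(gene_df, n_perm=10_000, seed=100 + i,
                           cohort=cohort_name)
    records[cohort_name] = rec
    planted_sets[cohort_name] = set(planted)
    called = set(rec.loc[rec["klass"] == "protected", "gene"])
    sens = len(called & planted_sets[cohort_name]) / len(planted)
    print(f"{cohort_name}: {len(called)} protected calls, "
          f"sensitivity on planted set = {sens:.0%}")

cons = consensus(records, min_cohorts=3)
n_cons = (cons["consensus"] == "protected").sum()
print(f"\ngenes protected in all 3 cohorts (>=3-cohort consensus rule): {n_cons}")
print("Planted genes are shared across cohorts only by chance here, so the "
      "consensus is small; on real cohorts it isolates recurrently protected "
      "gene functions.")
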
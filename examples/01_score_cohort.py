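"""Score one synthetic cohort: per-bin frequencies, μ, and their association.

Generates a 100-patient cohort with a regional mutation-rate field coupled to
amplification placement (beta = 2), computes amplification/deletion
frequencies and the copy-neutral μ score on the 3 Mbp grid, and correlates
them.
"""

from cnbuffer import SimConfig, cohort_scores, cohort_summary, correlate, simulate_cohort

cohort = simulate_cohort(SimConfig(seed=1, coupling_beta=2.0))
scores, states = cohort_scores(cohort.cna, cohort.mutations, cohort.genes,
                               cohort.build, grid=cohort.truth["grid"])

print(scores[["bin_id", "amp_freq", "del_freq", "mu", "n_N"]].head(8).to_string())

summary = cohort_summary(scores, cohort.mutations, set(states["patient"]))
result = correlate(scores)

print(f"\ncohort pooled mu (log10 mutations/coding bp/patient): {summary.pooled_mu:.3f}")
print(f"mean amplification frequency: {summary.mean_amp_freq:.3f}")
print(f"coding mutation burden per patient: {summary.mutation_burden:.1f}")
print(f"Spearman rho(amp_freq, mu) = {result.rho:.3f}  (p = {result.p_value:.2e}, "
      f"{result.n_bins} bins)")
print("\nA positive rho means mutation-rich bins are amplified more often — "
      "the buffering signature this pipeline quantifies.")
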
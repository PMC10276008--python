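"""Time mutations against amplifications via allele-specific multiplicity.

Each clonal mutation's multiplicity m is estimated from VAF, purity and
allele-specific copy number. On an amplified segment, m equal to the major
allele count means the mutation predates the amplification (early); m below
it means it arrived after (late). A mutation is buffered when at least two
unmutated copies remain.
"""

from cnbuffer import SimConfig, multiplicity_calls, simulate_cohort, timing_association

cohort = simulate_cohort(SimConfig(seed=2, coupling_beta=1.0))
calls = multiplicity_calls(cohort.mutations, cohort.allele_segments)
amplified = calls[calls["cn_major"] >= 2]

per_class, pooled = timing_association(amplified)
cols = ["cn_class", "n", "coding_early", "coding_late",
        "noncoding_early", "noncoding_late", "p_value"]
print(per_class[cols].to_string(index=False))

print(f"\npooled early fraction (mutation-weighted): "
      f"{pooled['early_fraction_weighted']:.1%}")
print(f"pooled early fraction (class-averaged):   "
      f"{pooled['early_fraction_classes']:.1%}")
buffered = amplified["buffered"].mean()
print(f"buffered mutations on amplified segments:  {buffered:.1%}")

print("\nRoughly half of amplified-segment mutations predate the event — the "
      "other half land on already-amplified segments, where spare wild-type "
      "copies buffer them.")
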
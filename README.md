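# cnbuffer

Do somatic copy-number amplifications buffer deleterious mutations?

Tumors accumulate thousands of passenger mutations. If amplifying a genomic
segment keeps spare wild-type copies of its genes, mutation-rich regions
should be amplified more often than mutation-poor ones — a *buffering*
signature written into the joint structure of copy-number alteration (CNA)
and mutation calls. `cnbuffer` implements the full analysis pipeline for
testing this on cohorts of SEG-style CNA segments and MAF-style somatic
mutations, together with a synthetic-cohort generator that provides ground
truth for every stage.

## The statistics at the core

For each genomic segment *i* at scale *j* (fixed-length bins, genes,
chromosome arms or whole chromosomes), each patient is classified amplified,
deleted or copy-neutral from the `segment_mean` log2 ratio (cutoff ±0.2), and

* amplification frequency `= #pt_A / (#pt_A + #pt_D + #pt_N)`,
* μ score `= log10( Σ mutations in copy-neutral patients
  / (coding_bp · #pt_N) )`.

Counting only copy-neutral patients in μ removes the trivial confounder that
more copies of a segment can simply carry more mutations. The pipeline then
provides:

* **Association & scale sweep** — Spearman ρ(amp. frequency, μ) per cohort,
  swept over segment lengths to find the scale of the buffering signal.
* **Stratification** — μ recomputed from mutation subsets (haploinsufficient
  genes by pLI/GHIS, expressed genes, damaging mutations by CADD/PolyPhen,
  synonymous vs not, aggregation-prone, driver-free), with paired exact
  Wilcoxon comparisons across cohorts.
* **Combined amplification model** — per-bin oncogene (OG) and
  proliferation-driver (GO) densities, the unweighted OG + GO + μ_scaled
  predictor, and a cohort-swap control.
* **Mutation timing** — clonal multiplicity *m* from VAF, purity and
  allele-specific copy number; *m* = major allele count ⇒ the mutation
  predates the amplification (early); (CN_major + CN_minor) − m ≥ 2 ⇒
  buffered; per-CN-class Fisher tests of coding × early/late.
* **Protection index** — per expressed gene,
  `P = amp_freq_scaled − μ_scaled`, ranked against a 10,000-permutation
  re-pairing null; percentile > 94 ⇒ protected, < 6 ⇒ unprotected, with a
  ≥ 3-cohort consensus and CRISPR-essentiality / expression contrasts.

## A worked example

```python
from cnbuffer import SimConfig, simulate_cohort, cohort_scores, correlate

cohort = simulate_cohort(SimConfig(seed=1, coupling_beta=2.0))
scores, states = cohort_scores(cohort.cna, cohort.mutations, cohort.genes,
                               cohort.build, grid=cohort.truth["grid"])
print(correlate(scores))
```

Running `python examples/01_score_cohort.py` (this cohort: 100 patients,
3 × 100 Mbp autosomes, 3 Mbp bins, coupling β = 2) prints

```
cohort pooled mu (log10 mutations/coding bp/patient): -3.759
mean amplification frequency: 0.230
coding mutation burden per patient: 77.6
Spearman rho(amp_freq, mu) = 0.381  (p = 7.87e-05, 102 bins)
```

The positive ρ says mutation-rich bins are amplified more often — the
buffering signature. With `coupling_beta=0` the same pipeline returns ρ ≈ 0
and a calibrated p-value. The other `examples/` scripts walk through the
scale sweep, stratification, the OG+GO+μ model, mutation timing and the
protection index, each printing the numbers it computes and what they mean.

## Reading real data

`read_seg`, `read_mutations`, `read_gene_table` and `read_bed_mask` consume
the standard dialects (SEG and MAF-like TSV are 1-based inclusive; BED is
half-open; everything internal is 0-based half-open). `write_cohort` emits a
synthetic cohort in exactly these dialects, so the file round trip is tested
end to end. Sex chromosomes are excluded by a single central filter, and a
coverage mask discards mutations in regions the CNA assay cannot see.

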
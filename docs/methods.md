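# Methods

This note documents the models, estimators and numerical choices behind
`cnbuffer`, and what the synthetic test bed does and does not establish about
real tumor data.

## Segment states and scores

The genome (autosomes only; a single central filter drops X/Y everywhere) is
partitioned at one of four scales: fixed bins of `j` bp (the last bin of a
chromosome may be shorter), gene bodies, chromosome arms, or whole
chromosomes. CNA calls are classified from the DNACopy-style `segment_mean`
log2 ratio with a strict ±0.2 cutoff — values at exactly ±0.2 are neutral.
Separately, each CNA *event* is classed chromosomal (≥ 90% of the chromosome),
arm (≥ 50% of its arm, using the arm with the larger overlap for
centromere-spanning calls) or focal, so that frequencies can be restricted to
an event class.

A bin is amplified (deleted) for a patient when same-state calls cover at
least `overlap_frac` of the bin, as a union so overlapping calls are not
double-counted. The default `overlap_frac = 0.5` reads "amplified segment" as
majority coverage; `>0` (any overlap) and `1.0` (full coverage) are supported
because the construction is not uniquely determined by the definition of the
frequencies. When both states qualify, the larger coverage wins and exact
ties go to amplified with a warning.

Per bin, amplification frequency is `n_A / (n_A + n_D + n_N)` and

```
mu = log10( sum of coding mutations in copy-neutral patients
            / (coding_bp * n_N) )
```

Only copy-neutral patients contribute to the numerator — a patient whose bin
is amplified could trivially carry more copies of every mutation, and this
restriction is what makes the amp–μ association interpretable as buffering
rather than dosage. Mutations are assigned to bins by position (at the gene
scale, by their gene), `coding_bp` by summing annotated per-gene coding
lengths over genes assigned by midpoint. Bins with zero neutral mutations, no
neutral patients or zero coding bp have undefined μ (NaN) and are dropped
from correlations; there is no pseudocount by default because log10(0) is
undefined and a pseudocount would distort exactly the low-rate bins the
analysis ranks — a `mu_zero=("pseudocount", k)` policy exists for sensitivity
checks. Cohort-level pooling averages the *untransformed* per-bin rates and
re-applies log10, so one high-rate bin is not averaged away on the log scale.

The patient universe of a cohort is the intersection of CNA-profiled and
mutation-profiled patients (mismatches are logged); duplicate
(patient, chrom, pos) mutation rows are collapsed; an optional coverage mask
removes mutations in regions the CNA assay does not cover.

## Associations, sweeps and strata

All associations are Spearman rank correlations with midrank ties, two-sided
p-values from the standard t approximation, and no multiple-testing
correction; an exact permutation p is available for n ≤ 8 by full
enumeration. Results with fewer than three usable bins, or a constant
vector, are flagged undefined rather than reported as zero.

The scale sweep recomputes states and scores at each requested scale and
reports the argmax-ρ segment length. Stratified runs recompute only the μ
numerator from the mutation subset (frequencies never change); each built-in
stratum has a complement and, where the defining score has a discarded band
(no pLI/GHIS value, PolyPhen between 0.3 and 0.6, CADD exactly at the 3.5
cutoff, missing aggregation scores), the discarded rows belong to neither
side, and the three masks partition the mutation table by construction. The
coding-bp denominator keeps the all-gene value by default; a flag restricts
it to stratum genes, since either reading is defensible.

Paired stratum comparisons across cohorts use the two-sided Wilcoxon
signed-rank test. The exact null distribution is computed by dynamic
programming over doubled midranks (zero differences dropped; all-zero input
returns p = 1), because a uniform shift produces fully tied |differences|
for which library implementations fall back to a normal approximation — the
exact distribution gives p = 2/2⁹ ≈ 0.0039 for nine same-sign pairs. The
normal approximation is used above 25 pairs.

## The combined OG + GO + μ model

Per-bin OG and GO scores are the fractions of the bin's genes (midpoint
assignment, each gene counted once) in the supplied oncogene and
proliferation-driver sets; bins without genes are undefined. The combined
predictor is the plain sum OG + GO + μ_scaled with μ min–max scaled to [0,1]
within the cohort — the densities are already in [0,1] and are not rescaled,
and no weights are fitted. Min–max scaling is rank-preserving, so the
μ-alone correlation is unchanged by it; a constant μ scales to 0 and the
combined model degenerates to OG+GO exactly. The swap control correlates one
cohort's predictor against the other's amplification frequencies on a shared
grid.

## Mutation–amplification timing

For a clonal mutation on a segment with allele-specific copy number
(CN_major : CN_minor), purity ρ and variant allele frequency v at depth d,
the multiplicity estimate is

```
m = round( v * (rho * (CN_major + CN_minor) + 2 * (1 - rho)) / rho )
```

clamped to [1, CN_major], with round-half-even ties for cross-platform
determinism. Subclonality is out of scope: every mutation is treated as
clonal, and VAF-peak quality control belongs to dedicated allele-specific CN
tools.

Timing semantics: *m equal to the major allele count ⇒ early* (the mutation
was present on the allele before it was amplified), *m below it ⇒ late*.
A mutation is *buffered* when `(CN_major + CN_minor) − m ≥ 2`, i.e. at least
two copies remain wild type. Two consequences worth noting: on 2:0 segments
a late (m = 1) mutation is *not* buffered, while any segment with
CN_minor ≥ 2 buffers every m = 1 mutation; and m = 1 calls on amplified
segments are labelled late even though a pre-amplification single-copy
origin cannot be excluded — multiplicity alone cannot distinguish them,
which is why the buffered/unbuffered classification is carried alongside as
the alternative clock. The coding-vs-lateness association is tested per
CN class with a two-sided Fisher exact test (degenerate margins are skipped
with a note), and the pooled early fraction is reported both
mutation-weighted and class-averaged because the two weightings can differ
when class sizes are skewed.

## Protection index

Per expressed gene (median TPM > 0; cohort-specific medians), amplification
frequency and μ are computed at the gene scale and min–max scaled to [0,1]
within the cohort before the difference `P = amp_scaled − μ_scaled`: raw μ
is a log10 rate around −7…−4, so the unscaled difference would be dominated
by μ entirely; a `scale="raw"` mode preserves the literal difference for
comparison. The null re-pairs the amplification vector with the μ vector
across genes. Three constructions are available behind one option: `pooled`
(default; all null values pooled over genes and permutations), `per-gene`,
and the literal two-point per-gene swap `{P, −P}`. Two design details make
the percentile map *exactly* anti-symmetric under a global amp↔μ exchange
with a fixed seed, rather than only asymptotically: sampled permutations
come in inverse-closed pairs, and each re-pairing contributes both
amp[π]−μ and its negation. Percentiles count strictly-smaller null values
plus half the ties; >94 ⇒ protected, <6 ⇒ unprotected; cross-cohort
consensus requires the same call in ≥ 3 cohorts, and a gene meeting both
thresholds (possible only pathologically) is set to none with a warning.
Downstream contrasts use two-sided rank-sum tests on CRISPR gene effect and
expression, and a Fisher exact test against common-essential /
non-essential flags.

## The synthetic test bed

`simulate_cohort` generates cohorts whose joint CNA–mutation structure
contains, in controllable form, exactly the features the analysis assumes:

* **Regional mutation-rate field.** Block-constant log-normal rates λ
  (σ = 0.8) at 1 Mbp resolution, block length `block_length`, optionally
  offset so rate domains do not start at the origin. Mutation counts per
  (gene, patient) are Poisson with rate ∝ coding_bp × λ at the gene's
  position; non-coding mutations are placed proportional to λ.
* **CNA event mixture.** Per patient, Poisson(`events_per_patient`) events
  drawn from a focal/arm/chromosomal mixture; focal lengths are log-normal.
  Focal *amplification* placement is tilted by λ^β — this is the tunable
  coupling — while arm and whole-chromosome aneuploidies are placed
  uniformly, emulating their origin in segregation errors rather than any
  regional mutation process. Amplified events draw allele-specific CN from a
  mixture with total CN ≥ 3 (so they clear the +0.2 cutoff at any purity
  ≥ 0.6; copy-neutral LOH is deliberately absent because it is invisible to
  a total-CN cutoff); deletions are 1:0. Overlapping events are resolved to
  non-overlapping segments, and emitted `segment_mean` values are
  purity-attenuated log2 ratios with small noise.
* **Timing ground truth.** Each mutation on an amplified segment is early
  (m = CN_major) with probability `early_fraction`, else late (m = 1); VAF
  is binomial read sampling at the configured depth around the expected
  clonal VAF (zero-read draws are floored at one read). The truth record
  stores λ, per-(patient, bin) states computed by the generator's own
  interval arithmetic, and per-mutation true multiplicity and timing.

Default study conditions: 3 autosomes × 100 Mbp, 100 patients, 3 Mbp
analysis bins, rate blocks of 3 Mbp aligned with the bins, 8 events/patient
(0.80/0.15/0.05 focal/arm/chromosomal), focal lengths log-normal around
5 Mbp, purity U(0.6, 1), depth 100×, 150 coding mutations per coding Mbp per
patient (matching the 40–400 coding mutations per exome seen across solid
tumors). Aligning rate blocks with bins makes the per-bin statistics
exchangeable when β = 0, so the Spearman p-value is calibrated by
construction — measured type-I error 0.05 over 200 null cohorts. At lower
mutation rates the μ estimator's Poisson noise and small-count bias vary
with each bin's copy-neutral count, which is linked to the amplification
field, and the null becomes mildly anti-conservative; this is a property of
the estimator worth remembering when interpreting sparse real cohorts.

Two derived configurations fix the conditions of specific experiments:

* `make_sweep_config` — 6 autosomes × 150 Mbp, rate blocks of 30 Mbp offset
  by 15 Mbp (off-grid, avoiding bin/block alignment artifacts), coupled
  focal amplifications ~25 Mbp, rate 8/Mbp. The coupling then lives at a
  known ~30 Mbp scale: smaller bins pay a sampling-noise and misalignment
  penalty, larger bins are diluted by the uniformly placed aneuploidies, so
  the sweep's argmax segment length recovers the injected scale (within
  ±10 Mbp in 17/20 calibration seeds; median ρ at 30 Mbp ≈ 0.6).
* `make_stratified_config` — coupling restricted to haploinsufficient genes
  (pLI > 0.2), 15 autosomes (500 bins), rate 20/Mbp. The
  stratum > control > complement ordering of ρ is resolvable only with
  finite counting noise: as counts grow, the control μ (a monotone function
  of the same λ) converges to the stratum μ in rank, so the contrast is a
  noise-attenuation effect by nature, and the moderate rate is part of the
  experiment's design, not a fitting knob.

Score-level generators (`make_additive_score_tables`,
`make_protection_scores`) construct bin and gene tables with additive
OG+GO+μ structure and with planted protected genes (top-decile
amplification, bottom-decile μ, bounded uniform baselines so min–max
scaling is stable across seeds) for the combined-model and protection
experiments.

**What the generator does not emulate:** mutational signatures and
trinucleotide context, kataegis/chromothripsis, whole-genome doubling,
subclonal structure, germline variation, and realistic gene-length or
expression distributions. Passing the suite therefore shows the estimators
and tests behave correctly under the assumed structure — calibrated nulls,
recovery of injected couplings, exact oracle agreement — not that real
tumors exhibit buffering; that question requires real cohorts read through
`io_formats`.

## Numerical and engineering choices

* Coordinates: SEG/MAF-like inputs are 1-based inclusive, BED half-open;
  everything internal is 0-based half-open, converted only at I/O.
  `segment_mean` is serialized via shortest round-trip repr and parsed in
  round-trip mode, so write→read is bit-identical.
* The MAF consequence vocabulary → (is_coding, is_synonymous) mapping is a
  fixed documented table; unknown terms become non-coding with a warning.
  Splice-site records are treated as non-coding (the position lies outside
  the CDS) and so enter only the timing analysis.
* Union coverage per (patient, bin, state) is computed by a sort +
  running-maximum scan, vectorized across all groups at once.
* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical cohorts and protection tables.
* Interval lookup uses sorted arrays with binary search; for the small
  per-cohort tables involved (≤ thousands of calls) no interval-tree
  dependency is warranted.

## Problem sizes

The test and acceptance runs use desk-scale cohorts: 100 patients, genomes
of 0.3–2.3 Gbp, 10²–10³ genes, ~10³–10⁴ mutations per cohort, 200 null
replicates, 20 seeds per stochastic experiment and 10,000 permutations for
the protection null. These sizes were chosen so the whole suite completes in
minutes while each check retains the statistical resolution its property
needs (e.g. a binomial 95% band of ±3 points around a 5% type-I rate at 200
replicates).

## Known limitations

* Bin-state assignment from overlapping CNA calls is a design choice
  (majority coverage); results at `overlap_frac` extremes differ for
  fragmented genomes.
* μ's small-count bias couples weakly to the copy-neutral denominator; very
  sparse cohorts inherit a slightly anti-conservative amp–μ test.
* The timing clock cannot separate pre-amplification single-copy mutations
  from late ones (m = 1 in both cases); conclusions should lean on the
  buffered/unbuffered classification where that matters.
* The protection percentile depends on the chosen null construction
  (pooled / per-gene / swap); all three are exposed, and the pooled default
  is the most conservative against per-gene score quirks.
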
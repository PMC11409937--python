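# Methods

## Overview

`rbtnfit` is a pooled-fitness pipeline for randomly barcoded transposon
libraries (RB-TnSeq/BarSeq) grown under several ecological conditions, plus
the plate-count statistics that accompany such experiments. The package has
six stages: a synthetic community generator (`simulate`), insertion-pool
construction from junction reads (`mapping`), barcode counting and
filtering (`counting`), fitness and t-score estimation (`fitness`),
cross-condition comparison (`compare`), and growth statistics (`growth`).
The generator is first-class code: it defines the statistical structure the
estimator assumes, and the test suite checks that the estimator inverts it.

## The fitness model

**Strain fitness.** Each barcode surviving the filters contributes
`f_s = log2(((n3 + ε)/N3) / ((n0 + ε)/N0))`, the log2 change in
within-sample relative abundance between the T0 reference and a day-3
sample. The pseudocount ε = 0.5 guarantees finiteness for vanished strains;
relative abundances make the statistic invariant to sequencing depth.
Any residual constant offset (from ε or depth) is absorbed by mode
normalization, so only the pseudocount's effect on low-count strains
matters, and those strains carry low weight.

**Weights.** `w_s = 2/(1/(1+n0) + 1/(1+n3))` is the inverse of the
approximate variance of a count log-ratio (delta method on two Poisson
counts, up to the constant (1/ln 2)²); a strain observed 100× at both
timepoints carries ~50× the weight of one observed once. Gene fitness is
the w-weighted mean of its strains.

**Position normalization.** Genes nearer the replication origin have a
higher copy number in growing cells, inflating their apparent abundance.
A centered circular running median of gene fitness along the chromosome is
subtracted. Window: 251 genes (odd; configurable), truncated to the largest
odd number ≤ n when fewer genes exist — at the default desk scale of 150
genes this degrades gracefully to subtracting the global median. The median
(not mean) keeps sparse true effects from leaking into the trend estimate.

**Mode normalization.** Assuming most insertions are neutral, the mode of
the per-replicate fitness distribution is subtracted. The mode is the
center of the fullest bin of a histogram with 0.05-wide bins spanning the
central 95% of values; ties break toward the center nearest 0 (then the
lower center), making the estimate deterministic. Resolution is therefore
half a bin (0.025) and tests treat any shift below that as exact.

**Moderated t-score.** `t = f / sqrt(V)` with
`V = max(V_between/n_eff, V_floor)`, where `V_between` is the w-weighted
between-strain variance, `n_eff = (Σw)²/Σw²` the effective strain number,
and `V_floor = (1/ln 2)²(1/(1+N0,gene) + 1/(1+N3,gene))` the count-limited
minimum variance from the gene's total reads. The floor stops single-strain
or low-read genes from reaching huge |t| when their strains happen to
agree; it is the "moderation" in the statistic.

**Aggregation.** Fitness and t are averaged arithmetically across
biological replicates (no pooled recomputation). A gene has a strong effect
when |mean t| ≥ 3; the sign comes from the mean fitness, and a strong
positive call additionally requires mean fitness > 0. Genes missing from
some replicates are averaged over the replicates where defined, with the
count reported.

## Pool construction and filters

Mapping reads are junction tag (19 bp) + barcode (20 bp) + genomic flank.
The flank is located by exact unique matching against the circular genome
and its reverse complement (20-mer seed, full-flank verification); reads
with no junction, a flank under 20 bp, no match, or more than one match are
discarded with tallied reasons. No mismatch-tolerant aligner is used: at
the synthetic scale flanks are error-free, and the contract that matters
downstream is *unique placement or discard*.

A barcode enters the pool at its modal (position, strand) only when that
site holds ≥ 75% of its reads with ≥ 2 supporting reads; anything else is
ambiguous or chimeric. Gene assignment is strand-aware — relative position
is measured along the coding strand — and an insertion is *central* when
that position is in [0.1, 0.9], boundaries inclusive (declared explicitly
so boundary tests are exact). Coordinates are 0-based half-open in memory;
GFF3 on disk is 1-based inclusive, converted only at the I/O boundary.

Count filters, in order: (1) barcodes absent from the pool are dropped
(reported, never silently); (2) barcodes with raw T0 count < 3 are dropped;
(3) gene-level analysis uses central insertions only, and a gene is
excluded when its retained central barcodes sum to < 30 T0 reads. The
gene threshold is applied to T0 because T0 is the common denominator across
all condition samples. Filtering is idempotent and order-independent, and
the audit log's barcode-level entries sum to the rows removed.

## Pleiotropy classification

Per condition, the strong-effect set carries each gene's sign. Membership
counts enumerate every nonempty condition subset exclusively (UpSet
semantics; they sum to the union). A gene with strong calls of opposite
sign in ≥ 2 conditions is *antagonistic*; the separate boolean
`phage_fungi_axis` marks the trade-off of interest — strong-positive in a
phage-containing condition and strong-negative in a fungi-without-phage
condition, or vice versa. Which conditions contain phage or fungi is a
declared mapping (carried on the sample sheet as `has_phage`/`has_fungi`),
never inferred from label strings. Category tallies from the annotation
table report both countings — share of total annotations and share of
annotated genes — because the two differ for multi-annotated genes; both
are emitted rather than choosing one.

## Growth statistics

Titer = count/(dilution × volume) per ml. Averaging is hierarchical:
technical replicates are averaged within each biological replicate, and
only biological-replicate means (typically n = 3 per group) enter Tukey's
HSD — technical replicates are never treated as independent samples.
Counts outside the conventional 30–300 countable range are flagged for QC
but never excluded. Tukey HSD is computed in-package from the pooled
within-group mean square and the studentized-range distribution
(`scipy.stats.studentized_range`); group comparisons of titers default to
log10(titer + 1), which spans the decades involved and keeps extinct
(titer 0) samples finite. MOI = pfu/cfu at inoculation; EOP = pfu on a test
lawn / pfu on the wild-type lawn, so 0 is complete resistance. QQ normality
is a diagnostic: normal quantiles at plotting positions (i − 0.5)/n and
their correlation with the ordered sample, not a formal test.

## The synthetic generator

**What it emulates.** A 200-kb random genome packed with 150
non-overlapping genes on both strands totalling exactly 85% of the genome;
10,000 uniformly placed insertions with unique random 20-bp barcodes;
lognormal initial strain abundances (σ = 0.5); multinomial sequencing at
5 × 10⁵ reads per sample (one pooled T0 + 4 conditions × 3 replicates);
and a day-3 composition in which strain abundance is reweighted by
`2^f` for the planted per-gene, per-condition fitness. Optional knobs
inject chimeric barcodes, junction-free mapping reads, and per-base BarSeq
errors for negative testing. Plate counts are Poisson around true titers at
an auto-chosen dilution targeting ~100 colonies; the default scenario
encodes steady growth alone or with fungi, a phage-induced dip and
recovery, and extinction by day 3 with phage and fungi together.

**Planted effects.** 8 antagonistic genes (+2 in phage-containing
conditions, −1.5 with fungi only), 5 phage-benefit (+2), 5 fungus-cost
(−1.5), 7 generally deleterious (−2), the remaining 125/150 (83%) exactly
neutral — satisfying the ≥ 80% neutral-majority assumption behind mode
normalization. Magnitudes were chosen once so that true effects are
comfortably above the |t| ≥ 3 calling boundary at the default depth while
remaining realistic single-condition log2 changes for a 3-day competition.

**What it does not emulate** (and what passing tests therefore cannot
show about real data): Tn5 insertion-site bias; PCR duplicates and
amplification noise; strain-to-strain fitness variation within a gene
(polar effects, domain-specific truncations); phage population dynamics or
resistance evolution during the experiment; multi-contig assemblies;
index-hopping or demultiplexing errors. Recovery correlations near 0.998
reflect the generator's clean multinomial noise — real libraries are
noisier in ways the generator deliberately omits.

## Numerical choices and problem sizes

- Pseudocount 0.5; mode-bin width 0.05 (resolution 0.025); running-median
  window 251 genes; t threshold 3. All exposed as `FitnessParams`.
- Degenerate inputs: mode estimation requires ≥ 10 genes; a near-constant
  fitness vector returns its central midpoint as the mode; Tukey HSD with
  zero pooled variance reports p = 0 for unequal means and p = 1 otherwise;
  a constant vector's QQ correlation is reported as NaN.
- Deterministic tie-breaks everywhere randomness is not intended: modal
  pool sites (lowest position — retention is unaffected because tied sites
  can never reach 75% modal share), mode bins (toward 0), gene order (by
  chromosomal midpoint).
- Default problem sizes (desk scale) were chosen so the entire test suite
  and the acceptance script each finish in well under a minute: 10k
  insertions / 150 genes for pipeline runs, 10 seeds for the stochastic
  recovery and growth checks, reduced read depth (5 × 10⁴/sample) for the
  FASTQ round trip, whose exactness does not depend on depth. The study
  scale (~4.5 Mb, 160k insertions) remains configurable.
- Determinism: all stages draw from numpy Generators spawned from the
  single config seed; identical configs give byte-identical files.

## Known limitations

- Exact flank matching cannot map reads from repetitive regions a real
  aligner might rescue with paired information; such reads are discarded.
- The `< 30 reads per gene` threshold is applied to T0 totals; a condition
  sample could in principle lose a gene's coverage without tripping it.
- Replicate t-scores share the single T0 reference, so they are positively
  correlated; the arithmetic replicate mean does not model this, which is
  conservative for calling but understates the effective noise floor.
- The EOP/MOI helpers operate on supplied pfu/cfu values; they do not model
  plaque overlap or lawn effects at high phage density.
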
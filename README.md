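# rbtnfit

**RB-TnSeq community fitness analysis** — from a barcoded transposon
insertion library to per-gene fitness values, moderated t-score effect
calls, cross-condition pleiotropy classification, and dilution-plating
growth statistics.

## The problem

Random-barcode transposon sequencing (RB-TnSeq / BarSeq) tracks hundreds of
thousands of insertion mutants in one pooled competition: every Tn5
insertion carries a unique 20-bp DNA barcode, and counting barcodes in
amplicon sequencing before (T0) and after selection measures each mutant's
relative fitness. Grown under different ecological conditions — here
modeled after a bacterium competing alone, under phage predation, with
antagonistic fungi, or with both — the same library reveals genes whose
disruption helps in one context and hurts in another (*antagonistic
pleiotropy*). The canonical example is O-antigen / LPS biosynthesis:
losing the phage's surface receptor confers resistance but exposes the cell
to fungal antagonism.

`rbtnfit` reimplements this analysis as a tested, reusable pipeline, and
ships a synthetic community generator so every stage runs and is verified
without any sequencing downloads.

## The model

For strain *s* of a gene, with barcode counts *n₀*, *n₃* at T0 and day 3
and sample totals *N₀*, *N₃*:

    f_s = log2( ((n₃ + ½)/N₃) / ((n₀ + ½)/N₀) )            strain fitness
    w_s = 2 / ( 1/(1+n₀) + 1/(1+n₃) )                       strain weight
    f_gene = Σ w_s f_s / Σ w_s                              gene fitness

Gene fitness is then normalized twice per replicate: a circular running
median along the chromosome (window 251 genes) removes the copy-number
trend toward the replication origin, and the mode of the resulting
distribution (0.05-wide histogram bins over the central 95%, ties broken
toward 0) is subtracted, anchoring the neutral majority at 0. The
moderated t-score divides fitness by a standard deviation floored at the
count-limited minimum:

    t = f / sqrt( max( V_between / n_eff , V_floor ) )
    V_floor = (1/ln 2)² ( 1/(1+N₀,gene) + 1/(1+N₃,gene) )

Fitness and t are averaged over biological replicates; |mean t| ≥ 3 flags a
*strong* effect, signed by the mean fitness. A gene strong-positive in a
phage-containing condition and strong-negative with fungi alone (or vice
versa) is classified antagonistically pleiotropic.

Before any of that, the pipeline builds the insertion pool from
transposon-junction reads (exact unique flank matching; a barcode is kept
at its modal site only with ≥ 2 reads and ≥ 75% modal share) and applies
the count filters: unknown barcodes out, T0 count < 3 out, genes with < 30
retained central-insertion T0 reads out. Growth assays are handled
separately: colony/plaque counts become titers (`count/(dilution·volume)`,
technical replicates averaged within biological replicates), compared with
Tukey's HSD, with MOI, EOP (efficiency of plaquing), and QQ-normality
diagnostics alongside.

## Worked example

```python
import numpy as np
from rbtnfit import (SimConfig, simulate_community,
                     run_fitness_pipeline, planted_vs_estimated)
from rbtnfit.compare import classify_pleiotropy

sim = simulate_community(SimConfig(seed=1))      # 200 kb, 150 genes, 10k insertions
res = run_fitness_pipeline(sim)                  # filter -> fitness -> t -> aggregate
table = res["table"]                             # gene x condition fitness table

merged = planted_vs_estimated(sim, table)
sub = merged[merged["n_strains"] >= 10]
r = np.corrcoef(sub["fitness_true"], sub["fitness"])[0, 1]
print(f"strong gene-condition calls: {int(table['strong'].sum())}")
print(f"planted-vs-estimated Pearson r: {r:.3f}")

calls = classify_pleiotropy(table, sim.config.composition)
print(calls[calls["pleiotropy_class"] == "antagonistic"].head(3).to_string(index=False))
```

prints

```
strong gene-condition calls: 72
planted-vs-estimated Pearson r: 0.998
locus_tag pleiotropy_class  phage_fungi_axis  n_strong                            calls
 HAF_0003     antagonistic              True         3 fungi:-1;phage:+1;phage_fungi:+1
 HAF_0036     antagonistic              True         3 fungi:-1;phage:+1;phage_fungi:+1
 HAF_0056     antagonistic              True         3 fungi:-1;phage:+1;phage_fungi:+1
```

The 72 strong calls are the planted non-neutral genes across their affected
conditions; the estimator recovers the planted fitness values at r = 0.998,
and every planted "LPS-like" gene is classified antagonistic with the
phage-up / fungi-down trade-off pattern (e.g. HAF_0003: fitness +1.95 under
phage, −1.49 with fungi, ~0 alone).

A command-line interface mirrors the library:

```sh
rbtnfit simulate --seed 1 --out-dir sim/
rbtnfit map-library sim/mapping_reads.fastq sim/genome.fasta --gff sim/genes.gff --out pool.tsv
rbtnfit count-barcodes --sample-sheet sim/sample_sheet.tsv --pool pool.tsv --out-dir counts/
rbtnfit fitness --counts counts/counts.tsv --pool pool.tsv \
    --sample-sheet sim/sample_sheet.tsv --gff sim/genes.gff --out-dir fit/
rbtnfit compare --fitness-table fit/fitness_table.tsv \
    --sample-sheet sim/sample_sheet.tsv --annotations sim/annotations.tsv --out-dir cmp/
rbtnfit growth-stats sim/plate_counts.tsv --out-dir growth/
```

## Documentation

`docs/methods.md` describes the model, its assumptions, every tunable
parameter with its default and rationale, what the synthetic generator does
and does not emulate, and known limitations.
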
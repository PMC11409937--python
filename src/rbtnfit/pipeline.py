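"""End-to-end conveniences wiring the simulator into the analysis stages."""

from __future__ import annotations

import pandas as pd

from .counting import CountMatrix, FilteredCounts, filter_counts
from .fitness import FitnessParams, aggregate_replicates, compute_fitness
from .simulate import SimOutput


def count_matrix_from_sim(sim: SimOutput) -> CountMatrix:
    """Wrap the simulator's true count matrix as a :class:`CountMatrix`."""
    known = pd.Series(
        sim.counts.index.isin(set(sim.pool["barcode"])),
        index=sim.counts.index,
        name="known",
    )
    return CountMatrix(
        counts=sim.counts.copy(), sample_sheet=sim.sample_sheet.copy(), known=known
    )


def run_fitness_pipeline(
    sim: SimOutput,
    params: FitnessParams = FitnessParams(),
    min_t0: int = 3,
    min_gene_reads: int = 30,
) -> dict:
    """Filter, estimate, and aggregate fitness from a simulated experiment.

    Returns ``{"filtered": FilteredCounts, "per_replicate": DataFrame,
    "table": DataFrame}``.
    """
    matrix = count_matrix_from_sim(sim)
    filtered: FilteredCounts = filter_counts(
        matrix, sim.pool, min_t0=min_t0, min_gene_reads=min_gene_reads
    )
    per_rep = compute_fitness(filtered, sim.genes, params)
    table = aggregate_replicates(per_rep, params)
    return {"filtered": filtered, "per_replicate": per_rep, "table": table}


def planted_vs_estimated(sim: SimOutput, table: pd.DataFrame) -> pd.DataFrame:
    """Merge planted and estimated gene fitness per gene x condition."""
    truth = sim.effects.rename(columns={"fitness": "fitness_true"})
    return table.merge(truth, on=["locus_tag", "condition"], how="inner")
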
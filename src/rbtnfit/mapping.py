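"""Build and characterize the barcode -> insertion pool from junction reads.

Mapping reads carry a fixed transposon-junction tag, the 20-bp random
barcode, and a genomic flank. The flank is located in the (circular) genome
by exact unique substring matching; reads whose flank is missing, too short,
absent from the genome, or non-unique are discarded with tallied reasons.
Barcodes are then collapsed into an insertion pool with a chimera filter:
a barcode is kept at its modal location only if that location holds at
least 75% of its reads and at least 2 reads support it.

Gene assignment is strand-aware: the relative position within a gene is
measured along the coding strand, and an insertion is "central" when that
relative position lies in [0.1, 0.9] (boundaries inclusive), the usual
disruptive-insertion window for Tn-seq.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import read_fastq
from .layout import MappingReadLayout, revcomp

POOL_COLUMNS = [
    "barcode", "position", "strand", "n_reads", "locus_tag", "rel_pos", "central",
]

CENTRAL_LO = 0.1
CENTRAL_HI = 0.9


class InputError(ValueError):
    """Raised for malformed genomes / inconsistent coordinates."""


def _check_alphabet(genome: str) -> None:
    letters = set(genome)
    if not letters <= set("ACGTN"):
        bad = "".join(sorted(letters - set("ACGTN")))[:10]
        raise InputError(f"genome contains non-nucleotide characters: {bad!r}")


class _FlankIndex:
    """Seed-and-verify index of a circular genome for exact flank lookup.

    Seeds are ``k``-mers (``k`` = minimum flank length) of both the genome
    and its reverse complement; a candidate hit is verified against the full
    flank. For a minus-strand insertion at position ``p`` the flank is the
    reverse complement of the sequence immediately upstream of ``p``, so a
    flank found at offset ``j`` of the reverse-complemented genome maps back
    to insertion position ``(L - j) mod L``.
    """

    def __init__(self, genome: str, k: int):
        _check_alphabet(genome)
        self.L = len(genome)
        if k > self.L:
            raise InputError(f"min flank {k} exceeds genome length {self.L}")
        self.k = k
        self.fwd = genome + genome  # circular verification buffer
        rc = revcomp(genome)
        self.rev = rc + rc
        seeds: dict[str, list[tuple[int, str]]] = {}
        for i in range(self.L):
            seeds.setdefault(self.fwd[i : i + k], []).append((i, "+"))
        for j in range(self.L):
            seeds.setdefault(self.rev[j : j + k], []).append((j, "-"))
        self.seeds = seeds

    def locate(self, flank: str) -> list[tuple[int, str]]:
        """All (insertion position, strand) sites whose flank equals ``flank``."""
        n = len(flank)
        hits = []
        for off, strand in self.seeds.get(flank[: self.k], ()):
            buf = self.fwd if strand == "+" else self.rev
            if n <= self.L and buf[off : off + n] == flank:
                pos = off if strand == "+" else (self.L - off) % self.L
                hits.append((pos, strand))
        return hits


def map_insertions(
    reads,
    genome: str,
    layout: MappingReadLayout | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map junction reads to (barcode, position, strand) observations.

    ``reads`` is a FASTQ path or an iterable of ``(name, sequence)`` pairs.
    Returns the observation table (one row per distinct barcode/site with a
    read-support count) and a tally of discard reasons.
    """
    layout = layout or MappingReadLayout()
    index = _FlankIndex(genome, layout.min_flank)
    jlen = len(layout.junction)
    blen = layout.barcode_length

    if not hasattr(reads, "__iter__") or isinstance(reads, (str, bytes)):
        reads = read_fastq(reads)

    # identical reads are common (several reads per insertion); dedupe first
    seq_counts: Counter[str] = Counter(seq for _, seq in reads)
    tallies = {"no_junction": 0, "short_flank": 0, "no_match": 0, "multi_mapped": 0}
    obs: Counter[tuple[str, int, str]] = Counter()
    for seq, n in seq_counts.items():
        if not seq.startswith(layout.junction):
            tallies["no_junction"] += n
            continue
        barcode = seq[jlen : jlen + blen]
        flank = seq[jlen + blen :]
        if len(barcode) < blen or len(flank) < layout.min_flank:
            tallies["short_flank"] += n
            continue
        hits = index.locate(flank)
        if not hits:
            tallies["no_match"] += n
        elif len(hits) > 1:
            tallies["multi_mapped"] += n
        else:
            pos, strand = hits[0]
            obs[(barcode, pos, strand)] += n

    if not obs and sum(tallies.values()) == 0:
        warnings.warn("no mapping reads supplied; empty observation set")
    table = pd.DataFrame(
        [(b, p, s, n) for (b, p, s), n in obs.items()],
        columns=["barcode", "position", "strand", "n_reads"],
    ).sort_values(["barcode", "position", "strand"], ignore_index=True)
    return table, tallies


def design_pool(
    observations: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    genome_length: int | None = None,
    min_reads: int = 2,
    min_modal_frac: float = 0.75,
) -> pd.DataFrame:
    """Collapse observations into the insertion pool.

    A barcode is retained at its modal (position, strand) when that site
    holds ``>= min_modal_frac`` of the barcode's reads with
    ``>= min_reads`` supporting reads; otherwise it is dropped as
    ambiguous/chimeric. If ``genes`` is given, retained barcodes are
    annotated against the gene model.
    """
    if observations.empty:
        pool = pd.DataFrame(columns=POOL_COLUMNS[:4])
    else:
        obs = observations.sort_values(
            ["barcode", "position", "strand"], ignore_index=True
        )
        totals = obs.groupby("barcode")["n_reads"].sum()
        modal = obs.loc[obs.groupby("barcode")["n_reads"].idxmax()].set_index("barcode")
        keep = (modal["n_reads"] >= min_reads) & (
            modal["n_reads"] / totals >= min_modal_frac
        )
        pool = modal[keep].reset_index()[["barcode", "position", "strand", "n_reads"]]
    if genes is not None:
        ann = assign_genes(pool["position"].to_numpy(dtype=int), genes, genome_length)
        pool = pd.concat([pool.reset_index(drop=True), ann], axis=1)
    return pool


def assign_genes(
    positions: np.ndarray,
    genes: pd.DataFrame,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Vectorized gene assignment for 0-based insertion positions.

    Returns columns ``locus_tag`` (None when intergenic), ``rel_pos``
    (position within the gene along the coding strand, NaN when
    intergenic), and ``central``.
    """
    positions = np.asarray(positions, dtype=int)
    if genome_length is not None and positions.size and (
        positions.min() < 0 or positions.max() >= genome_length
    ):
        raise InputError("insertion position outside the genome")
    genes = genes.sort_values("start", ignore_index=True)
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    idx = np.searchsorted(starts, positions, side="right") - 1
    safe = np.clip(idx, 0, max(len(genes) - 1, 0))
    if len(genes):
        inside = (idx >= 0) & (positions < ends[safe])
    else:
        inside = np.zeros(len(positions), dtype=bool)

    rel = np.full(len(positions), np.nan)
    if len(genes):
        length = (ends - starts)[safe].astype(float)
        fwd = genes["strand"].to_numpy()[safe] == "+"
        off = positions - starts[safe]
        rel_in = np.where(fwd, off / length, (ends[safe] - positions) / length)
        rel[inside] = rel_in[inside]
    central = inside & (rel >= CENTRAL_LO) & (rel <= CENTRAL_HI)
    locus = np.where(inside, genes["locus_tag"].to_numpy()[safe], None)
    return pd.DataFrame({"locus_tag": locus, "rel_pos": rel, "central": central})


def assign_gene(
    position: int,
    genes: pd.DataFrame,
    genome_length: int | None = None,
) -> tuple[str | None, float, bool]:
    """Scalar convenience wrapper around :func:`assign_genes`."""
    row = assign_genes(np.array([position]), genes, genome_length).iloc[0]
    return row["locus_tag"], row["rel_pos"], bool(row["central"])


def expected_insertions(total: int, coding_fraction: float) -> tuple[int, float]:
    """Expected in-gene insertions and central mutants for a random library.

    Under uniform insertion, ``floor(coding_fraction * total)`` insertions
    land in genes, and 80% of those (the central 10%-90% window) are
    expected disruptive mutants.
    """
    in_gene = math.floor(coding_fraction * total)
    return in_gene, 0.8 * in_gene


@dataclass
class LibraryStats:
    """Summary statistics of an annotated insertion pool."""

    total: int
    central: int
    distinct_locations: int
    in_gene: int
    genes_with_central: int
    n_genes: int
    fraction_genes_with_central: float
    mean_mutants_per_represented_gene: float
    expected_in_gene: int
    expected_central: float


def library_stats(
    pool: pd.DataFrame, genes: pd.DataFrame, coding_fraction: float
) -> LibraryStats:
    """Characterize an annotated pool (insertion counts vs. expectations).

    "Insertions" counts retained barcodes; "distinct locations" counts
    unique (position, strand) sites — the two are reported separately and
    never conflated.
    """
    total = len(pool)
    central = int(pool["central"].sum())
    distinct = len(pool[["position", "strand"]].drop_duplicates())
    in_gene = int(pool["locus_tag"].notna().sum())
    hit = pool.loc[pool["central"], "locus_tag"].nunique()
    represented = pool["locus_tag"].nunique()
    exp_in, exp_central = expected_insertions(total, coding_fraction)
    return LibraryStats(
        total=total,
        central=central,
        distinct_locations=distinct,
        in_gene=in_gene,
        genes_with_central=hit,
        n_genes=len(genes),
        fraction_genes_with_central=hit / len(genes) if len(genes) else 0.0,
        mean_mutants_per_represented_gene=in_gene / represented if represented else 0.0,
        expected_in_gene=exp_in,
        expected_central=exp_central,
    )
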
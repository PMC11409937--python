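"""Barcode extraction, count-matrix assembly, and the count filters.

BarSeq amplicon reads are reduced to barcode tallies per sample, assembled
into a barcode x sample matrix against the insertion pool, and filtered
with three rules before fitness estimation:

1. barcodes absent from the characterized pool are dropped (``unknown``);
2. barcodes seen fewer than 3 times in the T0 reference are dropped
   (``low_t0``, strict less-than);
3. gene-level analysis uses only central insertions, and a gene is excluded
   when its retained central barcodes carry fewer than 30 T0 reads in total
   (strict less-than).

Every removal is tallied in an audit log.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import read_fastq
from .layout import BarseqReadLayout

SAMPLE_SHEET_COLUMNS = ["sample", "condition", "replicate", "timepoint"]


class SampleSheetError(ValueError):
    """Raised for duplicate labels or a missing/ambiguous T0 sample."""


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check label uniqueness and the single-T0 convention; return a copy."""
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise SampleSheetError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample"].duplicated().any():
        dups = sheet.loc[sheet["sample"].duplicated(), "sample"].tolist()
        raise SampleSheetError(f"duplicate sample labels: {dups}")
    n_t0 = int((sheet["timepoint"] == "T0").sum())
    if n_t0 != 1:
        raise SampleSheetError(f"expected exactly one T0 sample, found {n_t0}")
    return sheet.copy()


def t0_sample(sheet: pd.DataFrame) -> str:
    """Label of the single T0 reference sample."""
    return str(validate_sample_sheet(sheet).loc[sheet["timepoint"] == "T0", "sample"].iloc[0])


def _hamming_le(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def extract_barcodes(
    reads,
    layout: BarseqReadLayout | None = None,
) -> tuple[Counter, dict[str, int]]:
    """Tally barcodes from one sample's BarSeq reads.

    ``reads`` is a FASTQ path or an iterable of ``(name, sequence)``.
    A read yields a barcode only if both fixed flanks match within
    ``layout.max_mismatches``; otherwise it is tallied as rejected.
    """
    layout = layout or BarseqReadLayout()
    left, right, blen = layout.left, layout.right, layout.barcode_length
    ll, rl = len(left), len(right)
    mm = layout.max_mismatches

    if not hasattr(reads, "__iter__") or isinstance(reads, (str, bytes)):
        reads = read_fastq(reads)

    tally: Counter[str] = Counter()
    rejected = {"too_short": 0, "bad_left_flank": 0, "bad_right_flank": 0}
    for _, seq in reads:
        if len(seq) < ll + blen + rl:
            rejected["too_short"] += 1
            continue
        if mm == 0:
            left_ok = seq[:ll] == left
            right_ok = seq[ll + blen : ll + blen + rl] == right
        else:
            left_ok = _hamming_le(seq[:ll], left, mm)
            right_ok = _hamming_le(seq[ll + blen : ll + blen + rl], right, mm)
        if not left_ok:
            rejected["bad_left_flank"] += 1
        elif not right_ok:
            rejected["bad_right_flank"] += 1
        else:
            tally[seq[ll : ll + blen]] += 1
    return tally, rejected


@dataclass
class CountMatrix:
    """Barcode x sample read counts plus sample metadata.

    ``known`` flags barcodes present in the insertion pool; unknown
    barcodes are retained (for QC visibility) but flagged.
    """

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    known: pd.Series

    @property
    def t0(self) -> str:
        return t0_sample(self.sample_sheet)


def build_matrix(
    tallies: Mapping[str, Counter],
    sample_sheet: pd.DataFrame,
    pool: pd.DataFrame,
) -> CountMatrix:
    """Assemble per-sample tallies into a :class:`CountMatrix`."""
    sheet = validate_sample_sheet(sample_sheet)
    missing = set(sheet["sample"]) - set(tallies)
    if missing:
        raise SampleSheetError(f"no tally supplied for samples: {sorted(missing)}")
    barcodes = sorted(set().union(*[set(t) for t in tallies.values()]) or set())
    counts = pd.DataFrame(
        {s: [tallies[s].get(b, 0) for b in barcodes] for s in sheet["sample"]},
        index=pd.Index(barcodes, name="barcode"),
        dtype=int,
    )
    known = pd.Series(
        counts.index.isin(set(pool["barcode"])), index=counts.index, name="known"
    )
    return CountMatrix(counts=counts, sample_sheet=sheet, known=known)


@dataclass
class FilteredCounts:
    """Output of :func:`filter_counts`.

    ``counts`` holds barcodes surviving the barcode-level rules (known and
    T0-abundant). ``strains`` lists the central, gene-assigned barcodes of
    retained genes — the rows that feed gene fitness. ``gene_t0_reads`` are
    the per-gene T0 read totals used by the gene threshold.
    """

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    strains: pd.DataFrame
    gene_t0_reads: pd.Series
    audit: dict[str, int] = field(default_factory=dict)

    @property
    def t0(self) -> str:
        return t0_sample(self.sample_sheet)


def filter_counts(
    matrix: CountMatrix,
    pool: pd.DataFrame,
    min_t0: int = 3,
    min_gene_reads: int = 30,
) -> FilteredCounts:
    """Apply the count filters; see the module docstring for the rules."""
    if matrix.t0 not in matrix.counts.columns:
        raise SampleSheetError(f"T0 sample {matrix.t0!r} missing from matrix")
    t0_counts = matrix.counts[matrix.t0]

    known = matrix.known.reindex(matrix.counts.index, fill_value=False)
    low_t0 = known & (t0_counts < min_t0)
    retained = known & ~low_t0
    audit = {
        "unknown": int((~known).sum()),
        "low_t0": int(low_t0.sum()),
    }
    counts = matrix.counts.loc[retained]

    ann = (
        pool.drop_duplicates("barcode")
        .set_index("barcode")[["locus_tag", "central"]]
        .reindex(counts.index)
    )
    central = ann["central"].fillna(False).astype(bool) & ann["locus_tag"].notna()
    audit["noncentral_for_genes"] = int((~central).sum())
    strains = pd.DataFrame(
        {"barcode": counts.index[central], "locus_tag": ann.loc[central, "locus_tag"]}
    ).reset_index(drop=True)

    gene_t0 = (
        counts.loc[strains["barcode"], matrix.t0]
        .groupby(strains["locus_tag"].to_numpy())
        .sum()
    )
    keep_genes = gene_t0[gene_t0 >= min_gene_reads]
    audit["genes_low_reads"] = int(len(gene_t0) - len(keep_genes))
    strains = strains[strains["locus_tag"].isin(keep_genes.index)].reset_index(drop=True)

    return FilteredCounts(
        counts=counts,
        sample_sheet=matrix.sample_sheet,
        strains=strains,
        gene_t0_reads=keep_genes,
        audit=audit,
    )
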
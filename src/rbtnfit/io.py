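"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython, FASTQ parsing through pysam's C parser, and
GFF3 / TSV tables through pandas. All genomic coordinates are 0-based
half-open in memory; GFF3 on disk is 1-based inclusive, converted at the
boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]

#: canonical in-memory gene-table columns (start 0-based, end exclusive)
GENE_COLUMNS = ["locus_tag", "seqid", "start", "end", "strand"]


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file as ``{record id: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gff(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file into the canonical gene table.

    Only ``gene``/``CDS`` features are kept. The returned ``start`` is
    0-based and ``end`` exclusive. ``locus_tag`` is taken from the
    ``locus_tag=`` attribute, falling back to ``ID=``.
    """
    raw = pd.read_csv(
        str(path), sep="\t", comment="#", header=None, names=GFF_COLUMNS,
        dtype={"start": int, "end": int},
    )
    feats = raw[raw["type"].isin(["gene", "CDS"])].copy()

    def _tag(attrs: str) -> str:
        fields = dict(
            kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
        )
        return fields.get("locus_tag", fields.get("ID", ""))

    genes = pd.DataFrame(
        {
            "locus_tag": feats["attributes"].map(_tag),
            "seqid": feats["seqid"],
            "start": feats["start"] - 1,
            "end": feats["end"],
            "strand": feats["strand"],
        }
    )
    return genes.sort_values("start", ignore_index=True)


def write_gff(path, genes: pd.DataFrame, source: str = "rbtnfit") -> None:
    """Write the canonical gene table as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.locus_tag};locus_tag={row.locus_tag}"
            fh.write(
                f"{row.seqid}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield ``(name, sequence)`` for each FASTQ record.

    A malformed record raises ``ValueError`` carrying the index of the
    record where parsing failed.
    """
    if os.path.getsize(str(path)) == 0:
        return
    i = 0
    try:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                yield entry.name, entry.sequence.upper()
                i += 1
    except OSError as exc:  # pysam raises OSError on truncated/bad records
        raise ValueError(f"malformed FASTQ record near index {i} in {path}") from exc


def write_fastq(path, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(name, sequence)`` pairs as Phred+33 FASTQ (constant Q40)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(str(path), sep="\t", index=index)
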
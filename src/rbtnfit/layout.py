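"""Read layouts shared by the simulator and the extraction stages.

Transposon-junction mapping reads look like::

    [junction tag][barcode][genomic flank ...]

and BarSeq amplicon reads look like::

    [left flank][barcode][right flank]

The tag/flank sequences are fixed properties of the amplicon design; the
defaults below are the layout the simulator emits. Real data with a
different design can be processed by constructing a custom layout.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Fixed 19-bp transposon-junction tag at the start of every mapping read.
JUNCTION_TAG = "CGGTACGGTTAACGGTTCA"

#: Fixed flanks surrounding the barcode in BarSeq amplicon reads.
BARSEQ_LEFT = "GATGTCCACGAGGTCTCT"
BARSEQ_RIGHT = "CGTACGCTGCAGGTCGAC"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MappingReadLayout:
    """Layout of transposon-junction mapping reads.

    ``min_flank`` is the minimum genomic-flank length required for a read to
    be mappable; shorter flanks are discarded.
    """

    junction: str = JUNCTION_TAG
    barcode_length: int = 20
    min_flank: int = 20


@dataclass(frozen=True)
class BarseqReadLayout:
    """Layout of BarSeq amplicon reads.

    ``max_mismatches`` is the number of mismatches tolerated in *each* flank
    when locating the barcode (default 0: exact flank match).
    """

    left: str = BARSEQ_LEFT
    right: str = BARSEQ_RIGHT
    barcode_length: int = 20
    max_mismatches: int = 0

    @property
    def read_length(self) -> int:
        return len(self.left) + self.barcode_length + len(self.right)
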
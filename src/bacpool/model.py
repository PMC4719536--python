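"""Core domain types shared by every pipeline stage.

Coordinate convention: all positions are 0-based, half-open ``[start,
end)``.  Strand '+' points toward increasing coordinates.  Minus-strand
alignment hits are stored with ascending subject coordinates plus a
strand flag, so a single ordering serves edge-distance and orientation
arithmetic.  Converters to and from 1-based formats (BLAST tabular,
SSPACE tab) are the only places offsets change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SeqRecord:
    """A named DNA sequence (BAC insert, contig, contaminant reference or BES).

    ``sequence`` is an uppercase string over {A, C, G, T, N}.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"SeqRecord {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """A read pair (Read A and B), optionally carrying simulator ground truth.

    ``truth`` is one of ``insert:<clone_id>``, ``ecoli``, ``vector`` or
    ``clonal`` when the pair came from the simulator, else ``None``.
    """

    pair_id: str
    read1: str
    read2: str
    quality1: Optional[str] = None
    quality2: Optional[str] = None
    truth: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.read1 or not self.read2:
            raise ValueError(f"pair {self.pair_id!r}: reads must be non-empty")
        for q, r, name in ((self.quality1, self.read1, "quality1"),
                           (self.quality2, self.read2, "quality2")):
            if q is not None and len(q) != len(r):
                raise ValueError(
                    f"pair {self.pair_id!r}: {name} length {len(q)} != read length {len(r)}"
                )


@dataclass
class AlignmentHit:
    """One local alignment between a query and a subject sequence.

    Coordinates are 0-based half-open on both axes and always ascending;
    ``strand`` records subject orientation.  ``bit_score`` is the aligner's
    bit score *b* consumed as-is (it already folds identity and aligned
    length together).
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    percent_identity: float
    aligned_length: int
    bit_score: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: query start >= end")
        if self.subject_start >= self.subject_end:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: subject start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must lie in [0, 100]")
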
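"""Pair-atomic contaminant filtering, clonal removal and coverage accounting.

BAC preps carry three read classes that must go before assembly: cloning
vector backbone, E. coli host genome, and clonal (amplification duplicate)
pairs.  The contaminant screen is an exact full-read match against the
reference at zero mismatches: if either read of a pair matches singly to
E. coli or the vector, the whole pair is removed.  Clonal pairs are
byte-identical duplicates (also under mate swap + reverse complement);
one representative is kept.  Coverage is accounted per BAC at a nominal
unit length of 120 kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from bacpool.model import ReadPair, SeqRecord, revcomp

DEFAULT_UNIT_LENGTH = 120_000


class ExactMatchIndex:
    """Membership index over all length-w substrings of references, both strands.

    Realizes a zero-mismatch full-read screen: a read of length w matches
    iff it occurs exactly in a reference on either strand.  w-mers
    containing N are excluded, so N never counts as a match.
    """

    def __init__(self, references: Sequence[SeqRecord], w: int):
        if w < 1:
            raise ValueError("w must be >= 1")
        short = [r.id for r in references if len(r) < w]
        if short:
            raise ValueError(f"references shorter than w={w}: {short}")
        self.w = w
        self.reference_ids = [r.id for r in references]
        self._kmers: set[str] = set()
        for rec in references:
            for s in (rec.sequence, revcomp(rec.sequence)):
                for i in range(len(s) - w + 1):
                    km = s[i : i + w]
                    if "N" not in km:
                        self._kmers.add(km)

    def __contains__(self, read: str) -> bool:
        if len(read) < self.w:
            raise ValueError(f"read length {len(read)} below index word size {self.w}")
        if len(read) != self.w:
            return False
        return read in self._kmers

    def __len__(self) -> int:
        return len(self._kmers)


def build_exact_index(references: Sequence[SeqRecord], w: int) -> ExactMatchIndex:
    """Index every w-mer of ``references`` and their reverse complements."""
    return ExactMatchIndex(references, w)


@dataclass
class QcReport:
    """Pre-processing statistics for one sequencing unit (pool or BAC)."""

    input_pairs: int
    removed_vector_pairs: int = 0
    removed_ecoli_pairs: int = 0
    removed_clonal_pairs: int = 0
    kept_pairs: int = 0
    raw_coverage: float = 0.0
    filtered_coverage: float = 0.0

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.input_pairs if self.input_pairs else 0.0

    @property
    def vector_percent(self) -> float:
        return self._pct(self.removed_vector_pairs)

    @property
    def ecoli_percent(self) -> float:
        return self._pct(self.removed_ecoli_pairs)

    @property
    def clonal_percent(self) -> float:
        return self._pct(self.removed_clonal_pairs)

    def validate(self) -> None:
        removed = (
            self.removed_vector_pairs + self.removed_ecoli_pairs + self.removed_clonal_pairs
        )
        if self.kept_pairs + removed != self.input_pairs:
            raise ValueError("QcReport accounting broken: kept + removed != input")

    def to_row(self) -> dict:
        return {
            "input_pairs": self.input_pairs,
            "kept_pairs": self.kept_pairs,
            "vector_pct": round(self.vector_percent, 2),
            "ecoli_pct": round(self.ecoli_percent, 2),
            "clonal_pct": round(self.clonal_percent, 2),
            "raw_coverage_x": round(self.raw_coverage),
            "filtered_coverage_x": round(self.filtered_coverage),
        }


def filter_contaminant_pairs(
    pairs: Iterable[ReadPair],
    ecoli_index: ExactMatchIndex,
    vector_index: ExactMatchIndex,
) -> tuple[list[ReadPair], QcReport]:
    """Remove pairs where either read exact-matches a contaminant reference.

    Removal is pair-atomic.  When a pair matches both references the
    class is vector (checked first) for deterministic accounting.
    """
    kept: list[ReadPair] = []
    n_vec = n_eco = n_in = 0
    for p in pairs:
        n_in += 1
        if p.read1 in vector_index or p.read2 in vector_index:
            n_vec += 1
        elif p.read1 in ecoli_index or p.read2 in ecoli_index:
            n_eco += 1
        else:
            kept.append(p)
    report = QcReport(
        input_pairs=n_in,
        removed_vector_pairs=n_vec,
        removed_ecoli_pairs=n_eco,
        kept_pairs=len(kept),
    )
    report.validate()
    return kept, report


def _canonical_pair_key(p: ReadPair) -> tuple[str, str]:
    """Key identical for a pair and its mate-swapped reverse complement."""
    a = (p.read1, p.read2)
    b = (revcomp(p.read2), revcomp(p.read1))
    return min(a, b)


def remove_clonal_pairs(pairs: Iterable[ReadPair]) -> tuple[list[ReadPair], int]:
    """Keep the first representative of each duplicate read-pair group.

    Two pairs are clonal duplicates when their (read1, read2) byte
    sequences are identical, or identical after swapping mates and
    reverse-complementing both.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[ReadPair] = []
    removed = 0
    for p in pairs:
        key = _canonical_pair_key(p)
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(p)
    return kept, removed


def estimate_coverage(
    total_bases: float, n_bacs: int, unit_length: int = DEFAULT_UNIT_LENGTH
) -> float:
    """Fold coverage of ``total_bases`` over ``n_bacs`` nominal-length BACs."""
    if n_bacs <= 0 or unit_length <= 0:
        raise ValueError("n_bacs and unit_length must be positive")
    if total_bases < 0:
        raise ValueError("total_bases must be >= 0")
    return total_bases / (n_bacs * unit_length)


def qc_pipeline(
    pairs: Sequence[ReadPair],
    ecoli_refs: Sequence[SeqRecord],
    vector_refs: Sequence[SeqRecord],
    read_length: int,
    n_bacs: int,
    unit_length: int = DEFAULT_UNIT_LENGTH,
) -> tuple[list[ReadPair], QcReport]:
    """Run the full pre-processing chain: contaminant screen, then clonal removal.

    Returns kept pairs and a QcReport with raw and filtered fold coverage
    estimated at ``unit_length`` per BAC.
    """
    ecoli_idx = build_exact_index(ecoli_refs, read_length)
    vector_idx = build_exact_index(vector_refs, read_length)
    kept, report = filter_contaminant_pairs(pairs, ecoli_idx, vector_idx)
    kept, n_clonal = remove_clonal_pairs(kept)
    report.removed_clonal_pairs = n_clonal
    report.kept_pairs = len(kept)
    report.raw_coverage = estimate_coverage(
        sum(len(p.read1) + len(p.read2) for p in pairs), n_bacs, unit_length
    )
    report.filtered_coverage = estimate_coverage(
        sum(len(p.read1) + len(p.read2) for p in kept), n_bacs, unit_length
    )
    report.validate()
    return kept, report
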
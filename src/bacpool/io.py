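"""Readers and writers for FASTA, paired FASTQ and BLAST tabular (outfmt 6).

FASTA/FASTQ go through Biopython's SeqIO; this module adds the contracts
the pipeline relies on (uppercasing, U→T, duplicate-id detection, pair
matching, coordinate normalization) on top.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from bacpool.model import AlignmentHit, FormatError, ReadPair, SeqRecord

_MATE_SUFFIX = re.compile(r"/[12]$")

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, in file order.

    Sequences are uppercased and U mapped to T.  Raises FormatError on an
    empty file or duplicate ids.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, _normalize(str(rec.seq))))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def strip_mate_suffix(read_id: str) -> str:
    """Drop a trailing /1 or /2 mate tag from a read id.

    Space-separated mate tags (Casava 1.8 style) never reach this point:
    ids are cut at the first whitespace during FASTQ parsing.
    """
    return _MATE_SUFFIX.sub("", read_id)


def read_paired_fastq(path1, path2) -> Iterator[ReadPair]:
    """Stream ReadPairs from two mate FASTQ files matched by record order.

    Raises FormatError on a record-count mismatch (reporting both counts)
    or when the ids disagree after stripping mate suffixes.
    """
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    n1 = n2 = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            break
        if r1 is None or r2 is None:
            # drain to report accurate counts
            n1 += sum(1 for _ in it1) + (r1 is not None)
            n2 += sum(1 for _ in it2) + (r2 is not None)
            raise FormatError(
                f"paired FASTQ record count mismatch: {path1} has {n1}, {path2} has {n2}"
            )
        n1 += 1
        n2 += 1
        id1, id2 = strip_mate_suffix(r1.id), strip_mate_suffix(r2.id)
        if id1 != id2:
            raise FormatError(
                f"read id mismatch at record {n1}: {r1.id!r} vs {r2.id!r}"
            )
        q1 = r1.letter_annotations.get("phred_quality")
        q2 = r2.letter_annotations.get("phred_quality")
        yield ReadPair(
            pair_id=id1,
            read1=_normalize(str(r1.seq)),
            read2=_normalize(str(r2.seq)),
            quality1="".join(chr(q + 33) for q in q1) if q1 else None,
            quality2="".join(chr(q + 33) for q in q2) if q2 else None,
        )


def write_paired_fastq(pairs: Iterable[ReadPair], path1, path2) -> None:
    """Write pairs as two mate FASTQ files (phred+33; 'I' when no qualities)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = p.quality1 or "I" * len(p.read1)
            q2 = p.quality2 or "I" * len(p.read2)
            f1.write(f"@{p.pair_id}/1\n{p.read1}\n+\n{q1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.read2}\n+\n{q2}\n")


def read_blast_tabular(path) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular (-outfmt 6) into AlignmentHits.

    File coordinates are 1-based inclusive; they are converted to 0-based
    half-open.  A subject interval given descending (sstart > send) marks a
    minus-strand hit and is stored ascending with strand '-'.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            (qseqid, sseqid, pident, length, _mism, _gapo,
             qstart, qend, sstart, send, evalue, bitscore) = fields
            ss, se = int(sstart), int(send)
            if ss <= se:
                strand, s0, s1 = "+", ss - 1, se
            else:
                strand, s0, s1 = "-", se - 1, ss
            hits.append(
                AlignmentHit(
                    query_id=qseqid,
                    subject_id=sseqid,
                    query_start=int(qstart) - 1,
                    query_end=int(qend),
                    subject_start=s0,
                    subject_end=s1,
                    strand=strand,
                    percent_identity=float(pident),
                    aligned_length=int(length),
                    bit_score=float(bitscore),
                    evalue=float(evalue),
                )
            )
    return hits


def write_blast_tabular(hits: Sequence[AlignmentHit], path) -> None:
    """Write hits back to the 12-column dialect (inverse of read_blast_tabular)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                ss, se = h.subject_start + 1, h.subject_end
            else:
                ss, se = h.subject_end, h.subject_start + 1
            mismatches = round(h.aligned_length * (100.0 - h.percent_identity) / 100.0)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                        h.aligned_length, mismatches, 0,
                        h.query_start + 1, h.query_end, ss, se,
                        f"{h.evalue:.2g}", f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )
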
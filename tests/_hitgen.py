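"""Minimal exact-seed, ungapped-extension hit generator — a test fixture.

Stands in for an external aligner when tests need hits between short
queries (BES, reads) and contigs.  Seeds exact k-mers at a fixed stride,
extends ungapped along the diagonal over the full query, and scores hits
with a simple match/mismatch bit-score proxy (+2/−3).  One hit per
(strand, diagonal).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from bacpool.model import AlignmentHit, SeqRecord, revcomp


def _subject_index(subject: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(subject) - k + 1):
        idx[subject[i : i + k]].append(i)
    return idx


def find_hits(
    query: SeqRecord,
    subject: SeqRecord,
    k: int = 21,
    stride: int = 50,
    min_identity: float = 90.0,
    index: dict | None = None,
) -> list[AlignmentHit]:
    subj = subject.sequence
    if index is None:
        index = _subject_index(subj, k)
    hits: dict[tuple, AlignmentHit] = {}
    for strand, q in (("+", query.sequence), ("-", revcomp(query.sequence))):
        if len(q) < k:
            continue
        offsets = list(range(0, len(q) - k + 1, stride))
        if offsets[-1] != len(q) - k:
            offsets.append(len(q) - k)
        for qi in offsets:
            for sj in index.get(q[qi : qi + k], ()):
                diag = sj - qi
                key = (strand, diag)
                if key in hits:
                    continue
                qs = max(0, -diag)
                qe = min(len(q), len(subj) - diag)
                alen = qe - qs
                if alen < k:
                    continue
                matches = sum(
                    1 for t in range(qs, qe) if q[t] == subj[diag + t]
                )
                identity = 100.0 * matches / alen
                if identity < min_identity:
                    continue
                bit = 2.0 * matches - 3.0 * (alen - matches)
                if bit <= 0:
                    continue
                if strand == "+":
                    q0, q1 = qs, qe
                else:  # report coordinates on the original (unreversed) query
                    q0, q1 = len(q) - qe, len(q) - qs
                hits[key] = AlignmentHit(
                    query_id=query.id,
                    subject_id=subject.id,
                    query_start=q0,
                    query_end=q1,
                    subject_start=diag + qs,
                    subject_end=diag + qe,
                    strand=strand,
                    percent_identity=identity,
                    aligned_length=alen,
                    bit_score=bit,
                )
    return list(hits.values())


def all_hits(
    queries: Sequence[SeqRecord],
    subjects: Sequence[SeqRecord],
    k: int = 21,
    stride: int = 50,
    min_identity: float = 90.0,
) -> list[AlignmentHit]:
    out: list[AlignmentHit] = []
    for subject in subjects:
        index = _subject_index(subject.sequence, k)
        for query in queries:
            out.extend(find_hits(query, subject, k, stride, min_identity, index))
    return out
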
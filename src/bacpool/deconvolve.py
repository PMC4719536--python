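"""Pool deconvolution via BAC-end-sequence (BES) hit scoring.

A pooled assembly mixes contigs of several clones.  Each clone's Sanger
BES pair anchors it: a BES belongs at a contig *end*, so among multiple
(repeat-driven) hits of a BES the right one is found by the score

    S = b − d_s

where ``b`` is the hit's bit score and ``d_s`` the hit's shortest
distance to either edge of its contig.  BES are length-filtered
(> 120 bp and < X, default X = 1000 bp, a Sanger-read bound) before
scoring.  Clones lacking BES can be anchored by 120 bp proxies cut from
the cloning-vector ends, which flank the insert in every read-through;
proxies bypass the length filter and are flagged in the report.

Pooled assemblies are additionally validated by pairing each pool contig
to its best-matching singleton (individually assembled) clone by summed
bit score.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from bacpool.model import AlignmentHit, SeqRecord

BES_MIN_LENGTH = 120
BES_MAX_LENGTH_DEFAULT = 1000
VECTOR_END_LENGTH = 120


@dataclass
class BesQuery:
    """One BAC-end sequence (or vector-end proxy) to be placed on the assembly."""

    bes_id: str
    clone_id: str
    end: str  # "forward" or "reverse"
    sequence: str
    source: str = "sanger_bes"  # or "vector_end_proxy"

    def __post_init__(self) -> None:
        if self.end not in ("forward", "reverse"):
            raise ValueError("end must be 'forward' or 'reverse'")
        if self.source not in ("sanger_bes", "vector_end_proxy"):
            raise ValueError("source must be 'sanger_bes' or 'vector_end_proxy'")
        if not self.sequence:
            raise ValueError(f"BES {self.bes_id!r} has an empty sequence")
        if self.source == "vector_end_proxy" and len(self.sequence) != VECTOR_END_LENGTH:
            raise ValueError("vector_end_proxy sequences must be exactly 120 bp")


@dataclass
class BesAssignment:
    """The chosen placement of one BES: contig, position and score S = b − d_s."""

    bes_id: str
    contig_id: str
    subject_start: int
    subject_end: int
    strand: str
    d_s: int
    score: float
    competing_hits: int


def edge_distance(hit: AlignmentHit, contig_length: int) -> int:
    """Shortest distance from the hit to either edge of its contig."""
    if hit.subject_start < 0 or hit.subject_end > contig_length:
        raise ValueError(
            f"hit [{hit.subject_start},{hit.subject_end}) outside contig of {contig_length} bp"
        )
    return min(hit.subject_start, contig_length - hit.subject_end)


def score_bes_hits(
    query: BesQuery,
    hits: Sequence[AlignmentHit],
    contig_lengths: Mapping[str, int],
    min_len: int = BES_MIN_LENGTH,
    max_len: int = BES_MAX_LENGTH_DEFAULT,
) -> Optional[BesAssignment]:
    """Pick the best placement for one BES by maximum S = bit score − d_s.

    Sanger BES must satisfy min_len < length < max_len or no assignment
    is made; vector-end proxies (exactly 120 bp by construction) bypass
    the filter.  Ties break by higher bit score, then smaller d_s, then
    lexicographic contig id.
    """
    if query.source == "sanger_bes":
        if not (min_len < len(query.sequence) < max_len):
            return None
    if not hits:
        return None
    scored = []
    for h in hits:
        if h.query_id != query.bes_id:
            raise ValueError(f"hit query {h.query_id!r} does not match BES {query.bes_id!r}")
        if h.subject_id not in contig_lengths:
            raise ValueError(f"hit references unknown contig {h.subject_id!r}")
        d = edge_distance(h, contig_lengths[h.subject_id])
        s = h.bit_score - d
        scored.append((s, h.bit_score, -d, h))
    scored.sort(key=lambda t: (-t[0], -t[1], -t[2], t[3].subject_id))
    s, _, negd, best = scored[0]
    return BesAssignment(
        bes_id=query.bes_id,
        contig_id=best.subject_id,
        subject_start=best.subject_start,
        subject_end=best.subject_end,
        strand=best.strand,
        d_s=-negd,
        score=s,
        competing_hits=len(hits),
    )


@dataclass
class DeconvolutionReport:
    """Contig-to-clone mapping for one pool.

    ``anchored`` lists clones with both ends assigned; ``conflicts`` lists
    contigs claimed by BES of more than one clone — these are reported,
    never auto-resolved, since they flag overlapping clones or
    misassembly.  ``proxy_anchored`` marks clones placed via vector-end
    proxies rather than real BES.
    """

    assignments: dict[str, BesAssignment]  # bes_id -> assignment
    clone_contigs: dict[str, dict[str, str]]  # clone -> {end: contig}
    anchored: list[str]
    proxy_anchored: list[str]
    conflicts: list[tuple[str, tuple[str, ...]]]  # (contig, claiming clones)
    unassigned_contigs: list[str]


def deconvolute_pool(
    queries: Sequence[BesQuery],
    assignments: Mapping[str, Optional[BesAssignment]],
    pool_clone_ids: Sequence[str],
    contig_ids: Sequence[str] = (),
) -> DeconvolutionReport:
    """Aggregate per-BES assignments into a contig→clone deconvolution.

    A clone is anchored when both its forward and reverse end queries
    assigned.  Each BES contributes at most one assignment.
    """
    by_id = {q.bes_id: q for q in queries}
    clone_contigs: dict[str, dict[str, str]] = defaultdict(dict)
    contig_claims: dict[str, set[str]] = defaultdict(set)
    proxy_clones: set[str] = set()
    clean: dict[str, BesAssignment] = {}
    for bes_id, asn in assignments.items():
        if asn is None:
            continue
        q = by_id[bes_id]
        clean[bes_id] = asn
        clone_contigs[q.clone_id][q.end] = asn.contig_id
        contig_claims[asn.contig_id].add(q.clone_id)
        if q.source == "vector_end_proxy":
            proxy_clones.add(q.clone_id)
    anchored = [
        c for c in pool_clone_ids
        if {"forward", "reverse"} <= set(clone_contigs.get(c, {}))
    ]
    conflicts = [
        (contig, tuple(sorted(clones)))
        for contig, clones in sorted(contig_claims.items())
        if len(clones) > 1
    ]
    claimed = set(contig_claims)
    unassigned = [c for c in contig_ids if c not in claimed]
    return DeconvolutionReport(
        assignments=clean,
        clone_contigs=dict(clone_contigs),
        anchored=anchored,
        proxy_anchored=sorted(proxy_clones & set(anchored)),
        conflicts=conflicts,
        unassigned_contigs=unassigned,
    )


def bes_queries_from_fasta(records: Sequence[SeqRecord]) -> list[BesQuery]:
    """Interpret BES FASTA ids of the form ``<clone>_..._For`` / ``_Rev``.

    The end label is the last underscore-separated token (case-insensitive
    prefix match on for/rev/f/r); the clone id is everything before the
    primer/end suffix up to the first token that is not part of the clone
    name — in practice, everything before the final one or two tokens,
    e.g. ``A01_M13_For`` → clone ``A01``, end forward.
    """
    primers = {"m13", "sp6", "t7", "m13f", "m13r"}
    queries = []
    for rec in records:
        tokens = rec.id.split("_")
        last = tokens[-1].lower()
        if len(tokens) < 2:
            end = None
        elif last.startswith("for") or last == "f":
            end = "forward"
        elif last.startswith("rev") or last == "r":
            end = "reverse"
        else:
            end = None
        if end is None:
            raise ValueError(
                f"cannot infer end (For/Rev) from BES id {rec.id!r}; "
                "expected ids like CLONE_PRIMER_For"
            )
        clone_tokens = tokens[:-1]
        if len(clone_tokens) > 1 and clone_tokens[-1].lower() in primers:
            clone_tokens = clone_tokens[:-1]
        queries.append(BesQuery(rec.id, "_".join(clone_tokens), end, rec.sequence))
    return queries


def vector_end_proxies(
    vector: SeqRecord, clone_id: str, length: int = VECTOR_END_LENGTH
) -> tuple[BesQuery, BesQuery]:
    """Cut 120 bp proxies from the two ends of the cloning-vector backbone.

    In a BAC read-through the vector ends flank the insert, so they land
    at the insert's contig ends just as real BES would.
    """
    fwd = BesQuery(f"{clone_id}_vecFOR", clone_id, "forward",
                   vector.sequence[-length:], "vector_end_proxy")
    rev = BesQuery(f"{clone_id}_vecREV", clone_id, "reverse",
                   vector.sequence[:length], "vector_end_proxy")
    return fwd, rev


def assign_bes(
    queries: Sequence[BesQuery],
    hits: Sequence[AlignmentHit],
    contig_lengths: Mapping[str, int],
    min_len: int = BES_MIN_LENGTH,
    max_len: int = BES_MAX_LENGTH_DEFAULT,
) -> dict[str, Optional[BesAssignment]]:
    """score_bes_hits for every query, hits grouped by query id."""
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    return {
        q.bes_id: score_bes_hits(q, by_query.get(q.bes_id, []), contig_lengths, min_len, max_len)
        for q in queries
    }


@dataclass
class ContigPairing:
    """Best singleton assembly for one pool contig, by summed bit score."""

    pool_contig: str
    singleton: Optional[str]
    summed_bit_score: float
    aligned_fraction: float
    shared: bool
    paired: bool


def pair_pool_to_singletons(
    pool_contig_lengths: Mapping[str, int],
    singleton_of_contig: Mapping[str, str],
    hits: Sequence[AlignmentHit],
    min_aligned_fraction: float = 0.5,
    shared_ratio: float = 0.2,
) -> list[ContigPairing]:
    """Pair each pool contig to the singleton assembly it best matches.

    ``singleton_of_contig`` maps singleton contig ids to their assembly
    (clone) id.  The winner is the singleton with maximum summed bit
    score over the pool contig's hits; the aligned fraction is the union
    of hit query intervals over the contig length.  Contigs aligning
    below ``min_aligned_fraction`` are unpaired; a runner-up with
    ≥ ``shared_ratio`` × the winning score flags the contig as shared.
    """
    by_contig: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        if h.query_id in pool_contig_lengths:
            by_contig[h.query_id].append(h)
    out = []
    for contig, length in sorted(pool_contig_lengths.items()):
        contig_hits = by_contig.get(contig, [])
        scores: dict[str, float] = defaultdict(float)
        for h in contig_hits:
            singleton = singleton_of_contig.get(h.subject_id)
            if singleton is None:
                raise ValueError(f"hit subject {h.subject_id!r} not in any singleton assembly")
            scores[singleton] += h.bit_score
        if not scores:
            out.append(ContigPairing(contig, None, 0.0, 0.0, False, False))
            continue
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        best, best_score = ranked[0]
        shared = len(ranked) > 1 and ranked[1][1] >= shared_ratio * best_score
        ivals = sorted(
            (h.query_start, h.query_end)
            for h in contig_hits
            if singleton_of_contig[h.subject_id] == best
        )
        covered = 0
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
        frac = covered / length
        out.append(
            ContigPairing(contig, best, best_score, frac, shared, frac >= min_aligned_fraction)
        )
    return out
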
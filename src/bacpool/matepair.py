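"""Mate-pair orientation QC and scaffolding-link construction.

A Nextera-style long-insert mate-pair (MP) library reads outward from a
circularized fragment, so a correctly mapped pair shows RF orientation
(leftmost mate on '-', rightmost on '+').  Two artifact classes
contaminate such libraries: the shadow library — short-insert inward
(FR) pairs that escaped circularization — and chimeric junction pairs
mapping same-direction (FF or RR, reported jointly).  Classifying mapped
pairs into these three classes, with outer-distance insert sizes,
validates assembly contiguity; pairs passing strict mapping filters are
then turned into SSPACE tab-file links and bundled per contig pair with a
minimum-link threshold (K) and a gap estimate.
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

ORIENTATION_CLASSES = ("RF", "FR", "FF_RR")


@dataclass
class MappedPair:
    """A read pair with both mates aligned, plus mapping quality metadata.

    ``contig1``/``contig2`` may differ (inter-contig pairs feed link
    building; orientation classification requires one contig).
    ``hit_count*`` counts all places the mate maps (1 = unique).
    """

    pair_id: str
    contig1: str
    contig2: str
    mate1: tuple[int, int, str]  # (start, end, strand)
    mate2: tuple[int, int, str]
    identity1: float = 100.0
    identity2: float = 100.0
    aligned1: int = 0
    aligned2: int = 0
    hit_count1: int = 1
    hit_count2: int = 1
    read_len1: Optional[int] = None
    read_len2: Optional[int] = None

    def __post_init__(self) -> None:
        for (s, e, strand), name in ((self.mate1, "mate1"), (self.mate2, "mate2")):
            if s >= e:
                raise ValueError(f"{self.pair_id}: {name} interval invalid")
            if strand not in ("+", "-"):
                raise ValueError(f"{self.pair_id}: {name} strand invalid")
        for ident in (self.identity1, self.identity2):
            if not 0.0 <= ident <= 100.0:
                raise ValueError(f"{self.pair_id}: identity outside [0, 100]")
        if self.read_len1 is None:
            self.read_len1 = self.aligned1 or (self.mate1[1] - self.mate1[0])
        if self.read_len2 is None:
            self.read_len2 = self.aligned2 or (self.mate2[1] - self.mate2[0])
        self.aligned1 = self.aligned1 or (self.mate1[1] - self.mate1[0])
        self.aligned2 = self.aligned2 or (self.mate2[1] - self.mate2[0])


@dataclass
class OrientationCall:
    """RF / FR / FF_RR class with the pair's outer-distance insert size."""

    orientation: str
    insert_size: int

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATION_CLASSES:
            raise ValueError(f"unknown orientation class {self.orientation!r}")


def classify_orientation(
    mate1: tuple[int, int, str],
    mate2: tuple[int, int, str],
    same_contig: bool = True,
) -> OrientationCall:
    """Classify a same-contig pair by positional strand pattern.

    Mates are ordered by leftmost start (ties by mate number): RF when the
    leftmost mate is '-' and the rightmost '+' (outward, the expected MP
    class), FR when '+' then '-' (inward, shadow library), FF_RR when the
    strands are equal (chimeric).  Insert size is the outer distance
    (rightmost end − leftmost start).
    """
    if not same_contig:
        raise ValueError("mates on different contigs: classify via the link path")
    left, right = (mate1, mate2) if mate1[0] <= mate2[0] else (mate2, mate1)
    if left[2] == right[2]:
        cls = "FF_RR"
    elif left[2] == "-":
        cls = "RF"
    else:
        cls = "FR"
    return OrientationCall(cls, right[1] - left[0])


def classify_pair(pair: MappedPair) -> OrientationCall:
    """classify_orientation on a MappedPair (mates must share a contig)."""
    return classify_orientation(pair.mate1, pair.mate2, pair.contig1 == pair.contig2)


def select_validation_pairs(
    pairs: Iterable[MappedPair], min_read_len: int = 100
) -> list[MappedPair]:
    """Pairs usable for orientation QC: both mates mapped once to the same
    contig, at 100 % identity, with read lengths above ``min_read_len``."""
    return [
        p
        for p in pairs
        if p.contig1 == p.contig2
        and p.hit_count1 == 1
        and p.hit_count2 == 1
        and p.identity1 == 100.0
        and p.identity2 == 100.0
        and p.read_len1 > min_read_len
        and p.read_len2 > min_read_len
    ]


def orientation_summary(
    calls: Sequence[OrientationCall],
) -> dict[str, dict[str, float]]:
    """Per-class percentage of pairs and median insert size.

    Returns ``{class: {"percent": ..., "median_insert": ...}}`` with every
    class present (median None when a class is empty); percentages sum
    to 100 up to rounding.
    """
    if not calls:
        raise ValueError("no orientation calls to summarize")
    n = len(calls)
    out: dict[str, dict[str, float]] = {}
    for cls in ORIENTATION_CLASSES:
        inserts = [c.insert_size for c in calls if c.orientation == cls]
        out[cls] = {
            "percent": 100.0 * len(inserts) / n,
            "median_insert": statistics.median(inserts) if inserts else None,
        }
    return out


def select_scaffold_pairs(
    pairs: Iterable[MappedPair],
    read_length: int,
    pool_of_contig: Optional[Mapping[str, str]] = None,
) -> list[MappedPair]:
    """Pairs eligible to scaffold: both mates at 100 % identity over the
    full read length, and both within one pool.

    With ``pool_of_contig`` unset, all contigs are treated as one pool.
    """
    kept = []
    for p in pairs:
        if p.identity1 != 100.0 or p.identity2 != 100.0:
            continue
        if p.aligned1 != read_length or p.aligned2 != read_length:
            continue
        if pool_of_contig is not None:
            pool1 = pool_of_contig.get(p.contig1)
            pool2 = pool_of_contig.get(p.contig2)
            if pool1 is None or pool1 != pool2:
                continue
        kept.append(p)
    return kept


MAPPED_PAIR_COLUMNS = [
    "pair_id",
    "contig1", "start1", "end1", "strand1", "identity1", "aligned1", "hit_count1",
    "contig2", "start2", "end2", "strand2", "identity2", "aligned2", "hit_count2",
]


def read_mapped_pairs_tsv(path) -> list[MappedPair]:
    """Read mapped pairs from the minimal 15-column TSV (header required)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MAPPED_PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        MappedPair(
            pair_id=str(r.pair_id),
            contig1=str(r.contig1),
            contig2=str(r.contig2),
            mate1=(int(r.start1), int(r.end1), str(r.strand1)),
            mate2=(int(r.start2), int(r.end2), str(r.strand2)),
            identity1=float(r.identity1),
            identity2=float(r.identity2),
            aligned1=int(r.aligned1),
            aligned2=int(r.aligned2),
            hit_count1=int(r.hit_count1),
            hit_count2=int(r.hit_count2),
        )
        for r in df.itertuples()
    ]


def write_mapped_pairs_tsv(pairs: Sequence[MappedPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MAPPED_PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        p.pair_id,
                        p.contig1, p.mate1[0], p.mate1[1], p.mate1[2],
                        p.identity1, p.aligned1, p.hit_count1,
                        p.contig2, p.mate2[0], p.mate2[1], p.mate2[2],
                        p.identity2, p.aligned2, p.hit_count2,
                    )
                )
                + "\n"
            )


@dataclass
class ScaffoldLink:
    """One selected inter-contig pair: positions and strands of both mates."""

    contig_a: str
    contig_b: str
    mate_a: tuple[int, int, str]
    mate_b: tuple[int, int, str]

    def __post_init__(self) -> None:
        if self.contig_a == self.contig_b:
            raise ValueError("inter-contig link requires distinct contigs")


def links_from_pairs(pairs: Iterable[MappedPair]) -> list[ScaffoldLink]:
    """Turn inter-contig mapped pairs into ScaffoldLinks (same-contig pairs skipped)."""
    return [
        ScaffoldLink(p.contig1, p.contig2, p.mate1, p.mate2)
        for p in pairs
        if p.contig1 != p.contig2
    ]


def write_sspace_tab(
    links: Sequence[ScaffoldLink], path, known_contigs: Optional[set] = None
) -> None:
    """Write links as a 6-column SSPACE tab file (1-based inclusive coordinates).

    One line per link: contig_a start_a end_a contig_b start_b end_b, in
    deterministic (contig pair, position) order.
    """
    for link in links:
        if known_contigs is not None:
            for c in (link.contig_a, link.contig_b):
                if c not in known_contigs:
                    raise ValueError(f"link references unknown contig {c!r}")
    rows = sorted(
        links,
        key=lambda l: (l.contig_a, l.contig_b, l.mate_a[0], l.mate_b[0]),
    )
    with open(path, "w") as fh:
        for l in rows:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        l.contig_a, l.mate_a[0] + 1, l.mate_a[1],
                        l.contig_b, l.mate_b[0] + 1, l.mate_b[1],
                    )
                )
                + "\n"
            )


@dataclass
class LinkBundle:
    """All links agreeing on one (contig pair, relative orientation)."""

    contig_a: str
    contig_b: str
    orientation: tuple[str, str]
    n_links: int
    gap_estimate: float


def _outward_coverage(mate: tuple[int, int, str], contig_length: int) -> int:
    """Bases of the MP insert lying on this contig, for an RF-geometry mate.

    A '-' mate has its insert extending rightward from its start; a '+'
    mate leftward from its end.
    """
    start, end, strand = mate
    return contig_length - start if strand == "-" else end


def bundle_links(
    links: Sequence[ScaffoldLink],
    contig_lengths: Mapping[str, int],
    min_links: int = 10,
    insert_range: tuple[int, int] = (4000, 9000),
) -> list[LinkBundle]:
    """Group links per (unordered contig pair, relative orientation), keep
    bundles of at least ``min_links`` (the SSPACE K threshold), and
    estimate the gap per bundle.

    Gap = median over links of (insert midpoint − span of mate A on its
    contig − span of mate B on its contig), with the insert midpoint
    taken from ``insert_range``.
    """
    mean_insert = (insert_range[0] + insert_range[1]) / 2.0
    groups: dict[tuple, list[float]] = defaultdict(list)
    for l in links:
        a, b = (l.contig_a, l.mate_a), (l.contig_b, l.mate_b)
        if l.contig_a > l.contig_b:
            a, b = b, a
        key = (a[0], b[0], a[1][2], b[1][2])
        da = _outward_coverage(a[1], contig_lengths[a[0]])
        db = _outward_coverage(b[1], contig_lengths[b[0]])
        groups[key].append(mean_insert - da - db)
    bundles = []
    for (ca, cb, sa, sb), gaps in sorted(groups.items()):
        if len(gaps) < min_links:
            continue
        bundles.append(LinkBundle(ca, cb, (sa, sb), len(gaps), statistics.median(gaps)))
    return bundles
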
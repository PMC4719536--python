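"""Synthetic BAC pools with full ground truth.

Emulates the data regime of a pooled BAC-by-BAC sequencing experiment on a
repeat-rich genome: 100–130 kb BAC inserts built as mosaics of unique
sequence and slightly diverged repeat-unit copies (grass BACs run ~80 %
repeat), paired-end pools contaminated with E. coli host reads, cloning
vector reads and clonal (PCR-duplicate) pairs at the proportions seen in
real pre-processing tables, long-insert mate pairs dominated by the
outward-facing RF class with a small shadow-library (FR) and chimeric
(FF/RR) admixture, and Sanger-length BAC-end sequences (BES).

Every emitted read pair carries a truth label, so filter recall, clonal
detection, orientation classification and pool deconvolution are exactly
measurable downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from bacpool.model import ReadPair, SeqRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n:
        # draw replacement from the 3 other bases via offset 1..3 in base order
        idx = np.flatnonzero(hit)
        cur = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(cur + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode()


@dataclass
class SimClone:
    """A simulated BAC clone: insert plus its two end sequences (BES)."""

    clone_id: str
    insert: str
    repeat_fraction: float
    bes_forward: str
    bes_reverse: str
    repeat_mask: Optional[np.ndarray] = None  # bool per base, True = repeat copy

    def __post_init__(self) -> None:
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction must lie in [0, 1]")


@dataclass
class SimPool:
    """A pool of (by default four) non-overlapping clones sequenced together."""

    pool_id: str
    clones: list[SimClone]


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults mirror the pooled-sequencing protocol this package supports:
    150 bp paired-end reads at ~500 bp inserts, mate pairs at 6–10 kb,
    host/vector/clonal contamination at the rates typical of BAC preps
    (E. coli ~12 %, vector ~4 %, clonal ~0.6 % of pairs) and a mate-pair
    library that is 99 % RF with 0.3 % shadow (FR) and 0.7 % chimeric
    (FF/RR) pairs.
    """

    seed: int = 0
    read_length: int = 150
    pe_insert_mean: float = 500.0
    pe_insert_sd: float = 50.0
    mp_insert_min: int = 6000
    mp_insert_max: int = 10000
    ecoli_fraction: float = 0.12
    vector_fraction: float = 0.04
    clonal_fraction: float = 0.006
    mp_orientation_mix: tuple[float, float, float] = (0.99, 0.003, 0.007)

    def __post_init__(self) -> None:
        fracs = (self.ecoli_fraction, self.vector_fraction, self.clonal_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("contamination fractions must each lie in [0, 1]")
        if sum(fracs) >= 1.0:
            raise ValueError("contamination fractions must jointly sum below 1")
        if abs(sum(self.mp_orientation_mix) - 1.0) > 1e-9:
            raise ValueError("mp_orientation_mix must sum to 1")


BES_LENGTH_DEFAULT = 600  # Sanger-scale end read
BES_ERROR_RATE = 0.001


def simulate_clone(
    length: int,
    repeat_fraction: float,
    repeat_unit_length: int = 3000,
    seed: int = 0,
    clone_id: str = "clone",
    n_repeat_units: int = 5,
    bes_length: int = BES_LENGTH_DEFAULT,
    rng: Optional[np.random.Generator] = None,
) -> SimClone:
    """Build one BAC insert as a unique/repeat mosaic.

    Repeat copies are drawn from a small per-clone library of
    ``n_repeat_units`` units and diverged by 1 % substitutions per copy;
    they occupy ``repeat_fraction`` of the insert to within ±2 %.  The BES
    are the terminal ``bes_length`` bases of each end (reverse end
    reverse-complemented) with 0.1 % Sanger-like substitution error.
    Deterministic for a given seed.
    """
    if not 0.0 <= repeat_fraction <= 0.95:
        raise ValueError("repeat_fraction must lie in [0, 0.95]")
    if length < 10 * repeat_unit_length and repeat_fraction > 0:
        raise ValueError(
            f"insert length {length} too short for repeat units of {repeat_unit_length} bp"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    mask = np.zeros(length, dtype=bool)
    if repeat_fraction == 0:
        insert = _random_dna(rng, length)
    else:
        units = [_random_dna(rng, repeat_unit_length) for _ in range(n_repeat_units)]
        repeat_total = int(round(repeat_fraction * length))
        if repeat_total > 0.97 * length:
            raise ValueError("repeat_fraction infeasible for this length/unit combination")
        # full-length copies plus one truncated copy to hit the target exactly
        copy_lens = [repeat_unit_length] * (repeat_total // repeat_unit_length)
        if repeat_total % repeat_unit_length >= 50:
            copy_lens.append(repeat_total % repeat_unit_length)
        n_copies = len(copy_lens)
        unique_total = length - sum(copy_lens)
        # split unique sequence into n_copies+1 chunks around the repeat copies
        cuts = np.sort(rng.integers(0, unique_total + 1, size=n_copies))
        chunk_lens = np.diff(np.concatenate(([0], cuts, [unique_total])))
        parts: list[str] = []
        pos = 0
        for i in range(n_copies):
            u = int(chunk_lens[i])
            parts.append(_random_dna(rng, u))
            pos += u
            unit = units[int(rng.integers(0, n_repeat_units))][: copy_lens[i]]
            parts.append(_mutate(rng, unit, 0.01))
            mask[pos : pos + copy_lens[i]] = True
            pos += copy_lens[i]
        parts.append(_random_dna(rng, int(chunk_lens[-1])))
        insert = "".join(parts)
        achieved = mask.mean()
        if abs(achieved - repeat_fraction) > 0.02:
            raise ValueError(
                f"achieved repeat fraction {achieved:.3f} misses target {repeat_fraction}"
            )

    bes_f = _mutate(rng, insert[:bes_length], BES_ERROR_RATE)
    bes_r = _mutate(rng, revcomp(insert[-bes_length:]), BES_ERROR_RATE)
    return SimClone(clone_id, insert, repeat_fraction, bes_f, bes_r, mask)


def simulate_pool(
    pool_id: str,
    n_clones: int = 4,
    insert_length: int = 113000,
    repeat_fraction: float = 0.8,
    seed: int = 0,
    **clone_kwargs,
) -> SimPool:
    """Assemble a pool of ``n_clones`` independently simulated clones.

    Each clone draws its own repeat-unit library, so clones share no
    read-length substring (the pooling protocol selects non-overlapping
    clones) except by negligible chance.
    """
    rng = np.random.default_rng(seed)
    clones = [
        simulate_clone(
            insert_length,
            repeat_fraction,
            clone_id=f"{pool_id}_c{i + 1}",
            rng=rng,
            **clone_kwargs,
        )
        for i in range(n_clones)
    ]
    return SimPool(pool_id, clones)


def make_contaminant_refs(
    cfg: SimConfig,
    inserts: Sequence[str],
    seed: int = 1,
    ecoli_length: int = 50000,
    vector_length: int = 7500,
    check_k: int = 32,
) -> dict[str, SeqRecord]:
    """Generate mock host-genome and vector references.

    Verified by exact k-mer census (k = ``check_k`` on both strands) to
    share no k-mer — hence no read-length substring — with the inserts, so
    filter recall and precision are exactly measurable.
    """
    rng = np.random.default_rng(seed)
    insert_kmers: set[str] = set()
    for ins in inserts:
        for s in (ins, revcomp(ins)):
            insert_kmers.update(s[i : i + check_k] for i in range(len(s) - check_k + 1))
    refs = {}
    for name, length in (("ecoli", ecoli_length), ("vector", vector_length)):
        for _attempt in range(10):
            seq = _random_dna(rng, length)
            kmers = {seq[i : i + check_k] for i in range(len(seq) - check_k + 1)}
            if not (kmers & insert_kmers):
                refs[name] = SeqRecord(name, seq)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not generate disjoint {name} reference")
    return refs


def _pe_pair_from(
    rng: np.random.Generator, ref: str, cfg: SimConfig
) -> tuple[str, str]:
    """Draw one inward-facing (FR) paired-end read pair from ``ref``."""
    L = cfg.read_length
    lo = max(L, int(cfg.pe_insert_mean - 4 * cfg.pe_insert_sd))
    hi = min(len(ref), int(cfg.pe_insert_mean + 4 * cfg.pe_insert_sd))
    insert = int(np.clip(round(rng.normal(cfg.pe_insert_mean, cfg.pe_insert_sd)), lo, hi))
    start = int(rng.integers(0, len(ref) - insert + 1))
    frag = ref[start : start + insert]
    return frag[:L], revcomp(frag[-L:])


def simulate_pool_reads(
    pool: SimPool,
    target_coverage: float,
    cfg: SimConfig,
) -> tuple[list[ReadPair], dict[str, SeqRecord]]:
    """Emit labelled PE pairs for a pool at ``target_coverage`` per pool.

    ``n = ceil(coverage × Σ insert length / (2 × read length))`` insert
    pairs are drawn first; E. coli, vector and clonal pairs are then
    injected so the configured fractions hold on the final total.  Clonal
    pairs are byte-identical duplicates of already-emitted insert pairs.
    Returns the pairs (shuffled deterministically) and the mock
    contaminant references used.
    """
    if not pool.clones:
        raise ValueError("pool has no clones")
    if target_coverage <= 0:
        raise ValueError("target_coverage must be > 0")
    rng = np.random.default_rng(cfg.seed)
    L = cfg.read_length
    lengths = np.array([len(c.insert) for c in pool.clones], dtype=float)
    n_insert = math.ceil(target_coverage * lengths.sum() / (2 * L))

    frac_contam = cfg.ecoli_fraction + cfg.vector_fraction + cfg.clonal_fraction
    n_total = int(round(n_insert / (1.0 - frac_contam)))
    n_ecoli = int(round(cfg.ecoli_fraction * n_total))
    n_vector = int(round(cfg.vector_fraction * n_total))
    n_clonal = int(round(cfg.clonal_fraction * n_total)) if n_insert else 0

    refs = make_contaminant_refs(cfg, [c.insert for c in pool.clones], seed=cfg.seed + 1)

    pairs: list[ReadPair] = []
    weights = lengths / lengths.sum()
    clone_idx = rng.choice(len(pool.clones), size=n_insert, p=weights)
    for i, ci in enumerate(clone_idx):
        clone = pool.clones[int(ci)]
        r1, r2 = _pe_pair_from(rng, clone.insert, cfg)
        pairs.append(ReadPair(f"{pool.pool_id}_p{i}", r1, r2, truth=f"insert:{clone.clone_id}"))

    for name, count in (("ecoli", n_ecoli), ("vector", n_vector)):
        ref = refs[name].sequence
        for j in range(count):
            r1, r2 = _pe_pair_from(rng, ref, cfg)
            pairs.append(ReadPair(f"{pool.pool_id}_{name}{j}", r1, r2, truth=name))

    # duplicate only insert pairs so contaminant filtering cannot eat duplicates
    for j in range(n_clonal):
        src = pairs[int(rng.integers(0, n_insert))]
        pairs.append(ReadPair(f"{src.pair_id}_dup{j}", src.read1, src.read2, truth="clonal"))

    order = rng.permutation(len(pairs))
    return [pairs[int(i)] for i in order], refs


@dataclass
class SimMatePair:
    """A simulated mate pair plus its construction ground truth."""

    pair: ReadPair
    truth_class: str  # RF, FR or FF_RR
    insert_size: int
    mate1: tuple[int, int, str]  # (start, end, strand) on the reference
    mate2: tuple[int, int, str]


def simulate_mate_pairs(
    reference: SeqRecord,
    n_pairs: int,
    cfg: SimConfig,
    seed: Optional[int] = None,
) -> list[SimMatePair]:
    """Draw long-insert mate pairs from one reference sequence.

    Insert sizes are uniform on [mp_insert_min, mp_insert_max].  The
    orientation class is sampled from ``cfg.mp_orientation_mix``: RF pairs
    are emitted outward-facing (leftmost mate on '-', rightmost on '+'),
    FR inward-facing, FF/RR with both mates on the same strand.  Which
    physical mate is written as read 1 is randomized.
    """
    ref = reference.sequence
    L = cfg.read_length
    if len(ref) <= cfg.mp_insert_max + 2 * L:
        raise ValueError(
            f"reference {reference.id!r} ({len(ref)} bp) shorter than "
            f"mp_insert_max + 2 reads ({cfg.mp_insert_max + 2 * L} bp)"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    classes = ("RF", "FR", "FF_RR")
    out: list[SimMatePair] = []
    for i in range(n_pairs):
        insert = int(rng.integers(cfg.mp_insert_min, cfg.mp_insert_max + 1))
        start = int(rng.integers(0, len(ref) - insert + 1))
        left = (start, start + L)
        right = (start + insert - L, start + insert)
        cls = classes[int(rng.choice(3, p=cfg.mp_orientation_mix))]
        if cls == "RF":
            strands = ("-", "+")
        elif cls == "FR":
            strands = ("+", "-")
        else:
            s = "+" if rng.random() < 0.5 else "-"
            strands = (s, s)
        mates = []
        for (s0, s1), strand in zip((left, right), strands):
            seq = ref[s0:s1]
            mates.append(((s0, s1, strand), seq if strand == "+" else revcomp(seq)))
        if rng.random() < 0.5:
            mates.reverse()
        (m1, seq1), (m2, seq2) = mates
        out.append(
            SimMatePair(
                pair=ReadPair(f"{reference.id}_mp{i}", seq1, seq2, truth=cls),
                truth_class=cls,
                insert_size=insert,
                mate1=m1,
                mate2=m2,
            )
        )
    return out


def truth_table(pairs: Sequence[ReadPair]) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate truth labels (pair_id, label, clone_id) for emitted pairs."""
    import pandas as pd

    rows = []
    for p in pairs:
        label = p.truth or "unknown"
        clone = label.split(":", 1)[1] if label.startswith("insert:") else ""
        rows.append((p.pair_id, label.split(":")[0], clone))
    return pd.DataFrame(rows, columns=["pair_id", "label", "clone_id"])
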
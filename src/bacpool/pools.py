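"""Pool design from physical-map metadata and assembly-size validation.

Clones for pooled sequencing must not overlap, or their pooled assembly
collapses the overlap.  Overlap is derived from the physical (FPC) map:
consecutive minimal-tiling-path clones within one FPC contig overlap by
construction, giving a sparse clone graph whose edges must not fall
inside a pool.  Pools are built by greedy randomized partition with
restarts.

Pooled assembly sizes are validated against the FPC size estimates
(approximations from counted restriction fragments) with a classical
paired t test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_POOL_SIZE = 4


@dataclass
class CloneGraph:
    """Clone ids plus symmetric overlap edges (no self-edges)."""

    clones: list[str]
    edges: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        clone_set = set(self.clones)
        if len(clone_set) != len(self.clones):
            raise ValueError("duplicate clone ids")
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"bad edge {set(e)}: self-edges not allowed")
            if not e <= clone_set:
                raise ValueError(f"edge {set(e)} references unknown clones")

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError("self-edges not allowed")
        self.edges.add(frozenset((a, b)))

    def overlaps(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def neighbors(self, clone: str) -> set[str]:
        return {next(iter(e - {clone})) for e in self.edges if clone in e}


def clone_graph_from_table(table: pd.DataFrame) -> CloneGraph:
    """Build overlap edges from a clone table.

    Expects columns ``clone_id``, ``fpc_contig``, ``position``; consecutive
    clones (by position) within one FPC contig are marked overlapping —
    the natural proxy when no base-pair coordinates exist.
    """
    graph = CloneGraph(list(table["clone_id"]))
    for _, grp in table.groupby("fpc_contig"):
        ordered = grp.sort_values("position")["clone_id"].tolist()
        for a, b in zip(ordered, ordered[1:]):
            graph.add_edge(a, b)
    return graph


class PoolDesignError(RuntimeError):
    """No edge-free partition found; carries the obstructing clique."""

    def __init__(self, clone: str, clique: Sequence[str]):
        self.clone = clone
        self.clique = list(clique)
        super().__init__(
            f"could not place clone {clone!r} in any pool; "
            f"mutually overlapping clones: {self.clique}"
        )


def _greedy_clique(graph: CloneGraph, seed_clone: str) -> list[str]:
    """A maximal clique containing seed_clone, grown greedily (for diagnostics)."""
    clique = [seed_clone]
    candidates = graph.neighbors(seed_clone)
    while candidates:
        c = sorted(candidates)[0]
        clique.append(c)
        candidates &= graph.neighbors(c)
    return sorted(clique)


def design_pools(
    graph: CloneGraph,
    pool_size: int = DEFAULT_POOL_SIZE,
    seed: int = 0,
    max_restarts: int = 1000,
) -> dict[str, str]:
    """Partition clones into edge-free pools of ``pool_size``.

    Greedy randomized assignment: clones in shuffled order go into the
    first pool with room and no overlap edge to its members; on failure
    the whole attempt restarts with a new shuffle.  Deterministic under
    ``seed``.  Returns a clone → pool-id map (pools named p001, p002, …).
    A clone count not divisible by pool_size leaves a smaller remainder
    pool, with a warning.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    clones = list(graph.clones)
    if not clones:
        return {}
    n_pools = math.ceil(len(clones) / pool_size)
    if len(clones) % pool_size:
        warnings.warn(
            f"{len(clones)} clones not divisible by pool size {pool_size}; "
            "allowing one smaller remainder pool",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    last_failure: Optional[str] = None
    for _attempt in range(max_restarts):
        order = [clones[int(i)] for i in rng.permutation(len(clones))]
        pools: list[list[str]] = [[] for _ in range(n_pools)]
        ok = True
        for clone in order:
            placed = False
            for pool in pools:
                if len(pool) < pool_size and not any(
                    graph.overlaps(clone, member) for member in pool
                ):
                    pool.append(clone)
                    placed = True
                    break
            if not placed:
                ok = False
                last_failure = clone
                break
        if ok:
            width = max(3, len(str(n_pools)))
            return {
                clone: f"p{idx + 1:0{width}d}"
                for idx, pool in enumerate(pools)
                for clone in pool
            }
    assert last_failure is not None
    raise PoolDesignError(last_failure, _greedy_clique(graph, last_failure))


def verify_pools(graph: CloneGraph, assignment: dict[str, str]) -> None:
    """Assert no overlap edge lies inside any pool and pools cover all clones."""
    if set(assignment) != set(graph.clones):
        raise ValueError("assignment does not partition the clone set")
    by_pool: dict[str, list[str]] = {}
    for clone, pool in assignment.items():
        by_pool.setdefault(pool, []).append(clone)
    for pool, members in by_pool.items():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if graph.overlaps(a, b):
                    raise ValueError(f"pool {pool} contains overlapping clones {a}, {b}")


def expected_lane_coverage(
    lane_bases: float = 40e9,
    n_bacs: int = 384,
    mean_bac_length: int = 120_000,
) -> float:
    """Fold coverage per BAC when one lane is split over ``n_bacs`` clones.

    Defaults model a 40 Gbp lane over 384 pooled BACs of ~120 kb: ~868x,
    inside the 450x–900x band where assembly length saturates.
    """
    if lane_bases <= 0 or n_bacs <= 0 or mean_bac_length <= 0:
        raise ValueError("all arguments must be positive")
    return lane_bases / (n_bacs * mean_bac_length)


@dataclass
class SizeComparison:
    """Paired t test of pooled assembly sizes against FPC size estimates."""

    n: int
    mean_assembly: float
    mean_fpc: float
    mean_difference: float
    t: float
    df: int
    p_value: float


def compare_sizes_paired_t(
    assembly_sizes: Sequence[float], fpc_sizes: Sequence[float]
) -> SizeComparison:
    """Classical paired t: d = assembly − fpc, t = mean(d)/(sd(d)/√n), df = n−1.

    Zero variance with a nonzero mean difference reports t = ±inf, p = 0;
    identical vectors report t = 0, p = 1.
    """
    a = np.asarray(assembly_sizes, dtype=float)
    f = np.asarray(fpc_sizes, dtype=float)
    if a.shape != f.shape:
        raise ValueError("size vectors must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - f
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if md == 0.0 else math.copysign(math.inf, md)
        p = 1.0 if md == 0.0 else 0.0
    else:
        t = md / (sd / math.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return SizeComparison(
        n=n,
        mean_assembly=float(a.mean()),
        mean_fpc=float(f.mean()),
        mean_difference=float(md),
        t=float(t),
        df=n - 1,
        p_value=float(p),
    )
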
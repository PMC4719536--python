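"""Coverage-saturation analysis: how much sequence is enough to assemble a BAC?

Deeply sequenced clones are subsampled with replacement across a coverage
grid (default 200x–3000x in 100x steps), each subset is assembled, and the
assembly-length-vs-coverage curve is smoothed with a local quadratic LOESS
(span 0.75, tricube weights) over an analysis window (default 200x–1000x).
The optimal coverage is the smallest grid point whose smoothed assembly
length reaches within epsilon (default 1 %) of the window maximum — the
point where added data stops buying assembly length.

The assembler itself is pluggable: pass any callable mapping a list of
read pairs to assembled contig sequences (or drive an external command via
the CLI).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from bacpool.model import ReadPair


@dataclass
class CoverageGrid:
    """Fold-coverage levels to subsample, ``start..stop`` inclusive by ``step``."""

    start: int = 200
    stop: int = 3000
    step: int = 100

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.start > self.stop:
            raise ValueError("start must be <= stop")

    def levels(self) -> list[int]:
        return list(range(self.start, self.stop + 1, self.step))

    def __len__(self) -> int:
        return (self.stop - self.start) // self.step + 1


@dataclass
class LoessSpec:
    """Local-regression settings: span (fraction of points per window) and degree."""

    span: float = 0.75
    degree: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must lie in (0, 1]")
        if self.degree not in (0, 1, 2):
            raise ValueError("degree must be 0, 1 or 2")


@dataclass
class CoverageCurve:
    """Assembly length as a function of subsampled coverage, for one clone."""

    clone_id: str
    points: list[tuple[float, float]]  # (coverage, assembly_length)
    fitted: Optional[list[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        covs = [c for c, _ in self.points]
        if any(b <= a for a, b in zip(covs, covs[1:])):
            raise ValueError("coverages must be strictly increasing")
        if any(length < 0 for _, length in self.points):
            raise ValueError("assembly lengths must be >= 0")


def plan_subsamples(
    n_clones: int, grid: CoverageGrid = CoverageGrid()
) -> list[tuple[int, int]]:
    """All (clone index, coverage) assembly jobs, clone-major, coverage ascending.

    The default design — 11 clones over 200x–3000x in 100x steps — yields
    319 jobs.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    levels = grid.levels()
    if not levels:
        raise ValueError("empty coverage grid")
    return [(c, cov) for c in range(n_clones) for cov in levels]


def subsample_size(target_coverage: float, unit_length: int, effective_read_length: int) -> int:
    """Closed-form pair count: ceil(coverage × unit / (2 × read length))."""
    return math.ceil(target_coverage * unit_length / (2 * effective_read_length))


def subsample_pairs(
    pairs: Sequence[ReadPair],
    target_coverage: float,
    unit_length: int,
    read_length: int,
    trim_to: Optional[int] = None,
    seed: int = 0,
) -> list[ReadPair]:
    """Draw pairs uniformly with replacement to hit a target coverage.

    If ``trim_to`` is given, reads are truncated to that many bases first
    and the draw count uses the trimmed length.
    """
    if not pairs:
        raise ValueError("no pairs to subsample")
    if target_coverage <= 0:
        raise ValueError("target_coverage must be > 0")
    eff = read_length
    if trim_to is not None:
        if trim_to > read_length:
            raise ValueError(f"trim_to={trim_to} exceeds read length {read_length}")
        eff = trim_to
    n = subsample_size(target_coverage, unit_length, eff)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pairs), size=n)
    out = []
    for i in idx:
        p = pairs[int(i)]
        if trim_to is not None:
            p = ReadPair(
                p.pair_id,
                p.read1[:trim_to],
                p.read2[:trim_to],
                p.quality1[:trim_to] if p.quality1 else None,
                p.quality2[:trim_to] if p.quality2 else None,
                p.truth,
            )
        out.append(p)
    return out


def _wls_poly_at(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, x0: float, degree: int
) -> float:
    """Weighted polynomial fit centered at x0; returns fitted value at x0."""
    xc = x - x0
    X = np.vander(xc, degree + 1, increasing=True)
    sw = np.sqrt(w)
    beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    if rank < degree + 1:
        raise np.linalg.LinAlgError("rank-deficient local system")
    return float(beta[0])


def loess_fit(
    points: Sequence[tuple[float, float]], spec: LoessSpec = LoessSpec()
) -> list[float]:
    """LOESS-smooth y over x with tricube weights and nearest-neighbour windows.

    At each x0 the ``ceil(span × n)`` nearest points are fit with a
    weighted degree-``spec.degree`` polynomial, weights
    ``(1 − (d/dmax)³)³``, and the local fit is evaluated at x0.  A
    singular local system falls back to degree 1 at that point (with a
    warning).  x must be strictly increasing.
    """
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    n = len(x)
    k = max(math.ceil(spec.span * n), spec.degree + 1)
    if k > n or n < spec.degree + 1:
        raise ValueError(
            f"window of {k} points exceeds {n} available (need >= degree+1 = {spec.degree + 1})"
        )
    fitted: list[float] = []
    for x0 in x:
        d = np.abs(x - x0)
        window = np.argsort(d, kind="stable")[:k]
        dw = d[window]
        dmax = dw.max()
        if dmax == 0:
            w = np.ones_like(dw)
        else:
            w = np.clip(1.0 - (dw / dmax) ** 3, 0.0, None) ** 3
            # the farthest point gets weight 0; keep it from zeroing the fit
            if np.count_nonzero(w) < spec.degree + 1:
                w = np.ones_like(dw)
        try:
            val = _wls_poly_at(x[window], y[window], w, x0, spec.degree)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular local system at x0={x0}; falling back to degree 1",
                RuntimeWarning,
                stacklevel=2,
            )
            val = _wls_poly_at(x[window], y[window], w, x0, min(1, spec.degree))
        fitted.append(val)
    return fitted


def find_plateau(
    curve: CoverageCurve,
    epsilon: float = 0.01,
    window: tuple[float, float] = (200.0, 1000.0),
) -> float:
    """Smallest coverage whose fitted length is within epsilon of the window max.

    The analysis window defaults to 200x–1000x; points outside it are
    ignored (curves can wobble at extreme depth as error accumulates).
    """
    if not curve.fitted:
        raise ValueError("curve has no fitted values; run loess_fit first")
    in_win = [(c, v) for c, v in curve.fitted if window[0] <= c <= window[1]]
    if len(in_win) < 3:
        raise ValueError("need fitted values on >= 3 grid points inside the window")
    vmax = max(v for _, v in in_win)
    threshold = (1.0 - epsilon) * vmax
    for c, v in in_win:
        if v >= threshold:
            return c
    raise AssertionError("unreachable: max must meet its own threshold")


def run_saturation_curve(
    clone_id: str,
    pairs: Sequence[ReadPair],
    assemble: Callable[[list[ReadPair]], Sequence[str]],
    grid: CoverageGrid = CoverageGrid(),
    unit_length: int = 120_000,
    read_length: int = 150,
    trim_to: Optional[int] = None,
    spec: LoessSpec = LoessSpec(),
    seed: int = 0,
) -> CoverageCurve:
    """Subsample → assemble → measure over a grid, returning a fitted curve.

    ``assemble`` maps read pairs to contig sequences; assembly length is
    the summed contig length.  Each grid level gets a seed derived from
    ``seed`` and the level, so levels are independent but reproducible.
    """
    points = []
    for i, cov in enumerate(grid.levels()):
        sub = subsample_pairs(pairs, cov, unit_length, read_length, trim_to, seed=seed * 100003 + i)
        contigs = assemble(sub)
        points.append((float(cov), float(sum(len(c) for c in contigs))))
    curve = CoverageCurve(clone_id, points)
    if len(points) >= spec.degree + 1:
        fitted = loess_fit(points, spec)
        curve.fitted = [(c, v) for (c, _), v in zip(points, fitted)]
    return curve
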
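"""Data partitioning for the four computation types.

Two schemes cover all cases:

* **Linear partitioning** (per-SNP and per-individual statistics): M items
  are cut into P contiguous subsets of ``floor(M/P)`` items, with the
  integer-division remainder attached to the last subset — 801 items over
  4 processors give subsets of 200/200/200/201.

* **Pairwise partitioning** (individual-pair and SNP-pair statistics):
  the n x n pair grid is split recursively into ``4^depth`` equal-area
  blocks. The first stage halves the index range (remainder to the second
  half), producing two diagonal quadrants and two off-diagonal quadrants.
  At each further stage every diagonal block splits into its own four
  quadrants while every off-diagonal block splits into four contiguous
  strips of near-equal size, so a depth-2 plan has 16 blocks: 8 descended
  from the diagonal quadrants and 8 strips from the off-diagonal ones.

The recursion depth is chosen automatically: deep enough that the number
of blocks reaches the processor count, and deep enough that half-splitting
has brought ``ceil(n / 2^depth)`` under ``side_max`` items (default 7000),
which caps every block at about ``side_max**2`` pairs and so bounds a
worker's memory footprint. With the default, chromosomes of up to
14,000 / 28,000 / 56,000 items map to 4 / 16 / 64 subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .errors import ParameterError

#: Largest allowed block side in the pairwise plan (items per axis).
DEFAULT_SIDE_MAX = 7000


@dataclass(frozen=True)
class IndexRange:
    """Half-open 0-based index range [start, stop)."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ParameterError(f"invalid range [{self.start}, {self.stop})")

    @property
    def size(self) -> int:
        return self.stop - self.start

    def indices(self) -> range:
        return range(self.start, self.stop)


@dataclass(frozen=True)
class LinearPartition:
    """Contiguous equal-size split of [0, M) into P ranges (remainder last)."""

    M: int
    P: int
    ranges: tuple[IndexRange, ...]

    def sizes(self) -> list[int]:
        return [r.size for r in self.ranges]


@dataclass(frozen=True)
class PairBlock:
    """One rows x cols block of the pair grid.

    ``lineage`` records the quadrant/strip label (1-4) chosen at each
    recursion level, root first; its first element tells whether the block
    descends from a diagonal (1 or 4) or off-diagonal (2 or 3) quadrant.
    """

    rows: IndexRange
    cols: IndexRange
    kind: str  # "diagonal" | "offdiag"
    lineage: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("diagonal", "offdiag"):
            raise ParameterError(f"invalid block kind {self.kind!r}")
        if self.kind == "diagonal" and self.rows != self.cols:
            raise ParameterError("diagonal blocks must have rows == cols")

    @property
    def area(self) -> int:
        return self.rows.size * self.cols.size

    def cells(self) -> Iterator[tuple[int, int]]:
        for i in self.rows.indices():
            for k in self.cols.indices():
                yield i, k


@dataclass(frozen=True)
class PairwisePlan:
    """4^depth-block decomposition of the n x n pair grid."""

    n: int
    depth: int
    blocks: tuple[PairBlock, ...]


def partition_linear(M: int, P: int) -> LinearPartition:
    """Split M items into P contiguous subsets; remainder goes to the last.

    Every subset holds ``floor(M/P)`` items except the last, which holds
    ``M - (P-1)*floor(M/P)``. Requires ``1 <= P <= M`` so that every
    processor receives work.
    """
    if M < 1:
        raise ParameterError(f"M must be >= 1, got {M}")
    if P < 1:
        raise ParameterError(f"P must be >= 1, got {P}")
    if P > M:
        raise ParameterError(f"cannot partition {M} items over {P} processors")
    base = M // P
    starts = [i * base for i in range(P)]
    stops = starts[1:] + [M]
    ranges = tuple(IndexRange(a, b) for a, b in zip(starts, stops))
    return LinearPartition(M=M, P=P, ranges=ranges)


def _halves(r: IndexRange) -> tuple[IndexRange, IndexRange]:
    mid = r.start + r.size // 2
    return IndexRange(r.start, mid), IndexRange(mid, r.stop)


def _strips(r: IndexRange, k: int) -> list[IndexRange]:
    """k contiguous strips of floor(size/k) items, remainder to the last."""
    base = r.size // k
    bounds = [r.start + i * base for i in range(k)] + [r.stop]
    return [IndexRange(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def _split_block(b: PairBlock) -> list[PairBlock]:
    if b.kind == "diagonal":
        r1, r2 = _halves(b.rows)
        return [
            PairBlock(r1, r1, "diagonal", b.lineage + (1,)),
            PairBlock(r1, r2, "offdiag", b.lineage + (2,)),
            PairBlock(r2, r1, "offdiag", b.lineage + (3,)),
            PairBlock(r2, r2, "diagonal", b.lineage + (4,)),
        ]
    # off-diagonal: four near-equal strips, by row when possible (the
    # documented scheme), by column for short-wide blocks, and as 2x2
    # quadrants in the degenerate 2-or-3-by-2-or-3 corner
    if b.rows.size >= 4:
        return [
            PairBlock(s, b.cols, "offdiag", b.lineage + (i + 1,))
            for i, s in enumerate(_strips(b.rows, 4))
        ]
    if b.cols.size >= 4:
        return [
            PairBlock(b.rows, s, "offdiag", b.lineage + (i + 1,))
            for i, s in enumerate(_strips(b.cols, 4))
        ]
    if b.rows.size >= 2 and b.cols.size >= 2:
        r1, r2 = _halves(b.rows)
        c1, c2 = _halves(b.cols)
        return [
            PairBlock(r1, c1, "offdiag", b.lineage + (1,)),
            PairBlock(r1, c2, "offdiag", b.lineage + (2,)),
            PairBlock(r2, c1, "offdiag", b.lineage + (3,)),
            PairBlock(r2, c2, "offdiag", b.lineage + (4,)),
        ]
    raise ParameterError(
        f"block {b.rows} x {b.cols} is too small to split into 4 subsets"
    )


def partition_pairwise(n: int, depth: int) -> PairwisePlan:
    """Recursive 4^depth-block decomposition of the n x n pair grid.

    Requires ``n >= 2^depth`` so every block side stays non-empty. Blocks
    tile the grid exactly (no gap, no overlap) with near-equal areas.
    """
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    if depth < 1:
        raise ParameterError(f"depth must be >= 1, got {depth}")
    if n < 2**depth:
        raise ParameterError(f"n={n} is too small for depth {depth} (need n >= {2**depth})")
    root = PairBlock(IndexRange(0, n), IndexRange(0, n), "diagonal", ())
    blocks = [root]
    for _ in range(depth):
        blocks = [child for b in blocks for child in _split_block(b)]
    return PairwisePlan(n=n, depth=depth, blocks=tuple(blocks))


def pairwise_depth(n: int, P: int, side_max: int = DEFAULT_SIDE_MAX) -> int:
    """Recursion depth for a pairwise plan over n items and P processors.

    ``depth = max(d_mem, d_proc, 1)`` where d_mem is the smallest depth
    with ``ceil(n / 2^depth) <= side_max`` (capping block areas at about
    ``side_max**2`` pairs) and d_proc the smallest with ``4^depth >= P``.
    The floor of 1 guarantees at least 4 subsets even for one processor.
    """
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    if P < 1:
        raise ParameterError(f"P must be >= 1, got {P}")
    if side_max < 2:
        raise ParameterError(f"side_max must be >= 2, got {side_max}")
    d_mem = 0
    while -(-n // (2**d_mem)) > side_max:  # ceil division
        d_mem += 1
    d_proc = 0
    while 4**d_proc < P:
        d_proc += 1
    return max(d_mem, d_proc, 1)


def plan_pairwise(n: int, P: int, side_max: int = DEFAULT_SIDE_MAX) -> PairwisePlan:
    """Convenience: depth selection + decomposition in one call."""
    return partition_pairwise(n, pairwise_depth(n, P, side_max=side_max))
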
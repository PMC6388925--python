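"""Pareto ranking of households in residual space.

Positive deviants are households whose five relative-performance residuals
are Pareto-optimal: no other household is at least as good in every
dimension and strictly better in one. The rank-1 front is the set of
non-dominated households; removing it and recomputing yields the rank-2
front (households dominated only by rank-1 members). Both fronts pooled
form the positive-deviant set by default.

All comparisons are on raw floating-point residuals with no epsilon: exact
ties are structural (duplicated records) and such rows co-rank.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["ParetoResult", "dominates", "nondominated_front", "pareto_ranks", "positive_deviants"]

UNRANKED = 0  # sentinel front_rank for households beyond max_front_rank


@dataclasses.dataclass
class ParetoResult:
    """Front ranks (1..max_front_rank, 0 = unranked) and the deviant flag."""

    front_rank: np.ndarray  # (n,) int
    max_front_rank: int
    index: pd.Index | None = None

    @property
    def positive_deviant(self) -> np.ndarray:
        return (self.front_rank >= 1) & (self.front_rank <= self.max_front_rank)

    def rank_counts(self) -> dict[int, int]:
        return {
            r: int((self.front_rank == r).sum())
            for r in range(1, self.max_front_rank + 1)
        }

    def to_frame(self) -> pd.DataFrame:
        idx = self.index if self.index is not None else pd.RangeIndex(len(self.front_rank))
        return pd.DataFrame(
            {
                "front_rank": [r if r else pd.NA for r in self.front_rank],
                "positive_deviant": self.positive_deviant,
            },
            index=idx,
        )


def dominates(a, b) -> bool:
    """True iff a is at least as good as b everywhere and strictly better once.

    All dimensions are maximisation-oriented.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape} vs {bv.shape}")
    return bool(np.all(av >= bv) and np.any(av > bv))


def _dominated_mask(x: np.ndarray) -> np.ndarray:
    """Boolean mask of rows dominated by some other row (pairwise, vectorized)."""
    n = len(x)
    dominated = np.zeros(n, dtype=bool)
    for j in range(n):
        ge = np.all(x[j] >= x, axis=1)
        gt = np.any(x[j] > x, axis=1)
        dom_by_j = ge & gt
        dom_by_j[j] = False
        dominated |= dom_by_j
    return dominated


def nondominated_front(matrix) -> np.ndarray:
    """Indices of the non-dominated rows (duplicates co-front)."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    return np.flatnonzero(~_dominated_mask(x))


def pareto_ranks(matrix, max_front_rank: int = 2, index: pd.Index | None = None) -> ParetoResult:
    """Iteratively peel non-dominated fronts up to max_front_rank.

    Rank 1 is the front of all rows; rank r the front of rows with no rank
    below r. Rows beyond max_front_rank stay unranked (0).
    """
    if max_front_rank < 1:
        raise ValueError("max_front_rank must be >= 1")
    x = np.asarray(matrix, dtype=float)
    n = len(x)
    ranks = np.zeros(n, dtype=int)
    remaining = np.arange(n)
    for r in range(1, max_front_rank + 1):
        if len(remaining) == 0:
            break
        front_local = nondominated_front(x[remaining])
        ranks[remaining[front_local]] = r
        remaining = np.delete(remaining, front_local)
    return ParetoResult(front_rank=ranks, max_front_rank=max_front_rank, index=index)


def positive_deviants(result: ParetoResult) -> list:
    """Ids (or positions when no index was attached) of ranked households."""
    mask = result.positive_deviant
    if result.index is not None:
        return list(result.index[mask])
    return list(np.flatnonzero(mask))
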
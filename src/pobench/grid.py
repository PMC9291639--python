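"""Dose-combination grids and their feasible complete orderings.

A dual-agent trial studies combinations :math:`d_{kl}` of dose :math:`a_k`
of agent A (``k = 1..K``) and dose :math:`b_l` of agent B (``l = 1..L``).
Monotonicity within each agent induces a partial order on the grid:
``d_kl <= d_k'l'`` iff ``k <= k'`` and ``l <= l'``.  A *feasible complete
ordering* is a total order of all ``K*L`` combinations consistent with that
partial order, i.e. a linear extension of the grid poset — equivalently a
standard Young tableau of rectangular shape ``K x L``, which gives an exact
counting oracle via the hook-length formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseGrid",
    "OrderingSet",
    "ExtensionLimitError",
    "count_linear_extensions",
    "enumerate_linear_extensions",
    "incomparability_counts",
    "compute_weights",
]

#: refuse to enumerate grids with more linear extensions than this
DEFAULT_EXTENSION_LIMIT = 10**6


class ExtensionLimitError(ValueError):
    """Raised when a grid has too many linear extensions to enumerate."""


@dataclass(frozen=True)
class DoseGrid:
    """Rectangular dual-agent dose grid with K doses of A and L doses of B."""

    K: int
    L: int

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def n_combos(self) -> int:
        return self.K * self.L

    def positions(self) -> list[tuple[int, int]]:
        """All (k, l) pairs, 1-based, in row-major order."""
        return [(k, l) for k in range(1, self.K + 1) for l in range(1, self.L + 1)]


def count_linear_extensions(grid: DoseGrid) -> int:
    """Exact number of feasible complete orderings of the grid.

    Uses the hook-length formula for the rectangular shape ``K x L``:
    ``(KL)! / prod(hooks)`` with hook ``(K - k) + (L - l) + 1`` at (k, l).
    """
    K, L = grid.K, grid.L
    prod = 1
    for k in range(K):
        for l in range(L):
            prod *= (K - k) + (L - l) - 1
    return math.factorial(K * L) // prod


@dataclass
class OrderingSet:
    """All feasible complete orderings of a grid.

    Attributes
    ----------
    grid : DoseGrid
    ranks : ndarray of shape (S, K*L), int
        ``ranks[s, j]`` is the rank (1..K*L) of the j-th position (row-major)
        under ordering ``s``.  Orderings are sorted lexicographically by rank
        vector, so indices are stable across runs.
    """

    grid: DoseGrid
    ranks: np.ndarray
    _pos_of_rank: np.ndarray | None = field(default=None, repr=False)

    @property
    def S(self) -> int:
        return self.ranks.shape[0]

    @property
    def pos_of_rank(self) -> np.ndarray:
        """(S, K*L) array: flat position index holding rank r+1 under each ordering."""
        if self._pos_of_rank is None:
            self._pos_of_rank = np.argsort(self.ranks, axis=1)
        return self._pos_of_rank

    def incomparability_counts(self) -> np.ndarray:
        return incomparability_counts(self.grid)

    def weights(self) -> np.ndarray:
        return compute_weights(self.grid)


def enumerate_linear_extensions(
    grid: DoseGrid, limit: int = DEFAULT_EXTENSION_LIMIT
) -> OrderingSet:
    """Enumerate every feasible complete ordering of the grid.

    Works by repeatedly assigning the next rank to a currently-minimal
    unfilled cell: cell (k, l) may receive a rank once (k-1, l) and
    (k, l-1) have theirs.  The state is the filled-prefix length of each
    row (a staircase), so the recursion enumerates standard Young tableaux
    of shape K x L.

    Raises
    ------
    ExtensionLimitError
        If the hook-length count exceeds ``limit``.
    """
    count = count_linear_extensions(grid)
    if count > limit:
        raise ExtensionLimitError(
            f"{grid.K}x{grid.L} grid has {count} feasible orderings, "
            f"above the enumeration limit of {limit}"
        )
    K, L = grid.K, grid.L
    n = K * L
    out = np.empty((count, n), dtype=np.int64)
    ranks = np.zeros(n, dtype=np.int64)
    filled = [0] * K  # cells assigned so far in each row
    idx = 0

    def recurse(step: int) -> None:
        nonlocal idx
        if step > n:
            out[idx] = ranks
            idx += 1
            return
        for k in range(K):
            if filled[k] < L and (k == 0 or filled[k - 1] > filled[k]):
                j = k * L + filled[k]
                ranks[j] = step
                filled[k] += 1
                recurse(step + 1)
                filled[k] -= 1

    recurse(1)
    assert idx == count
    # canonical order: lexicographic on rank vectors
    order = np.lexsort(out.T[::-1])
    return OrderingSet(grid=grid, ranks=out[order])


def incomparability_counts(grid: DoseGrid) -> np.ndarray:
    """Number of combinations incomparable to each (k, l), as a K x L matrix.

    Under the product order, (k', l') is incomparable to (k, l) iff one
    index is strictly larger and the other strictly smaller, so the count
    is ``(k-1)(L-l) + (K-k)(l-1)`` (1-based indices).
    """
    K, L = grid.K, grid.L
    k = np.arange(1, K + 1)[:, None]
    l = np.arange(1, L + 1)[None, :]
    return (k - 1) * (L - l) + (K - k) * (l - 1)


def compute_weights(grid: DoseGrid) -> np.ndarray:
    """Power-likelihood weights ``w_kl = 1 / (1 + #incomparable)`` as K x L.

    Combinations comparable to every other combination (the grid corners
    (1,1) and (K,L)) get weight 1; combinations with many incomparable
    peers carry less information about the complete ordering and are
    down-weighted accordingly.
    """
    return 1.0 / (1.0 + incomparability_counts(grid))
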
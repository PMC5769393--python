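"""Published baseline schedules for the Nussinov fill.

Two multi-core reformulations of the fill are provided as baselines next
to the reference order and the ISS-tiled executor:

* Chang's schedule computes the matrix diagonal by diagonal (offset
  d = j - i ascending).  Cells on one diagonal are mutually independent,
  so they may be computed concurrently with a barrier between diagonals.

* Li's schedule keeps Chang's diagonal order but stores the transpose of
  every finalized cell in the lower triangle and reads the column operand
  of the split term through that mirror, S[j][k+1] instead of S[k+1][j],
  so both operands of the inner reduction are row-contiguous (the point of
  the optimization: rows are cache lines, columns are strided).

Both reproduce the reference matrix bit-exactly on the upper triangle.
``workers`` expresses the concurrency contract only; an optional seeded
``rng`` shuffles the within-diagonal cell order to let tests exercise the
claim that any interleaving yields the same matrix.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .fold import fill_reference, sigma
from .sequences import DEFAULT_RULE, PairingRule, RnaSequence

__all__ = ["chang_fill", "li_fill", "SCHEDULES", "get_schedule"]


def _check_workers(workers: int) -> None:
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")


def _diagonal_cells(n: int, d: int, rng: Optional[np.random.Generator]):
    cells = list(range(n - d))
    if rng is not None:
        rng.shuffle(cells)
    return cells


def chang_fill(
    seq: RnaSequence,
    rule: PairingRule = DEFAULT_RULE,
    workers: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Diagonal-synchronized fill: d = 0, 1 initialized to zero, then each
    diagonal computed from the previous ones; a barrier separates
    diagonals.  Result is independent of ``workers`` and of the order of
    cells within a diagonal."""
    if isinstance(seq, str):
        seq = RnaSequence.from_string(seq)
    _check_workers(workers)
    n = len(seq)
    S = np.zeros((n, n), dtype=np.int64)
    for d in range(2, n):
        for i in _diagonal_cells(n, d, rng):
            j = i + d
            best = int(np.max(S[i, i:j] + S[i + 1 : j + 1, j]))
            pair = int(S[i + 1, j - 1]) + sigma(seq, i, j, rule)
            S[i, j] = best if best >= pair else pair
    return S


def li_fill(
    seq: RnaSequence,
    rule: PairingRule = DEFAULT_RULE,
    workers: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Cache-efficient diagonal fill with a transposed lower triangle.

    The split term reads S[row][k] + S[col][k+1]: the second operand is the
    mirror of S[k+1][col], kept in row ``col`` of the lower triangle, so
    both reductions stream along rows.  After a cell is finalized its value
    is also stored at the transposed position.
    """
    if isinstance(seq, str):
        seq = RnaSequence.from_string(seq)
    _check_workers(workers)
    n = len(seq)
    S = np.zeros((n, n), dtype=np.int64)
    for d in range(2, n):
        for i in _diagonal_cells(n, d, rng):
            j = i + d
            # both slices are row reads: S[i, i:j] and mirror row S[j, i+1:j+1]
            best = int(np.max(S[i, i:j] + S[j, i + 1 : j + 1]))
            pair = int(S[j - 1, i + 1]) + sigma(seq, i, j, rule)
            val = best if best >= pair else pair
            S[i, j] = val
            S[j, i] = val
    return S


def _reference(seq, rule=DEFAULT_RULE, workers: int = 1, rng=None) -> np.ndarray:
    return fill_reference(seq, rule)


def _tiled(seq, rule=DEFAULT_RULE, workers: int = 1, rng=None, B=None) -> np.ndarray:
    from .tiling import TileSize, tiled_fill

    return tiled_fill(seq, rule, B if B is not None else TileSize(1, 96, 8), workers, rng)


#: registry used by the command-line interface (--schedule NAME)
SCHEDULES: dict[str, Callable] = {
    "reference": _reference,
    "chang": chang_fill,
    "li": li_fill,
    "tiled": _tiled,
}


def get_schedule(name: str) -> Callable:
    try:
        return SCHEDULES[name]
    except KeyError:
        raise KeyError(
            f"unknown schedule {name!r}; choose from {sorted(SCHEDULES)}"
        ) from None
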
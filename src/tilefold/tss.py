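"""Tile-size selection: enumerate, validate, time, rank.

Empirical tile-size selection runs the tiled code once per candidate size
and keeps the fastest.  The default per-dimension candidate list holds 20
values (1, 2, 4, ..., 512), giving a search space of 20^3 = 8000 sizes.

Each candidate is validated before being timed: sizes in the b1 = 1 family
are pre-verified (no instance is ever corrected there), anything else is
checked with the full dependence oracle on a proxy problem size (default
N = 24), since instance-level closure at production N is out of reach.
Timing uses one warm-up run followed by the median of ``repeats``
measurements; the timer is injectable, so the search logic itself is a
pure, deterministically testable function of its inputs.  Absolute times
are hardware-bound and are never treated as correctness criteria.
"""

from __future__ import annotations

import statistics
import time
from dataclasses import dataclass
from itertools import product
from typing import Callable, Optional, Sequence

import numpy as np

from .sequences import DEFAULT_RULE, PairingRule, RnaSequence
from .tiling import (
    ScheduleError,
    TileSize,
    _graph_cached,
    _tilemap_cached,
    check_wavefronts,
    lexicographic_order,
    tiled_fill,
    validate_schedule,
)

__all__ = [
    "DEFAULT_CANDIDATES",
    "CandidateGrid",
    "TssRecord",
    "tss_enumerate",
    "is_valid_tile_size",
    "default_timer",
    "tss_search",
]

#: the 20 default per-dimension candidates
DEFAULT_CANDIDATES: tuple[int, ...] = (
    1, 2, 4, 6, 8, 12, 16, 24, 32, 40, 48, 64, 96, 128, 150, 200, 256, 300, 400, 512,
)


@dataclass(frozen=True)
class CandidateGrid:
    """Per-dimension candidate lists for (b1, b2, b3)."""

    b1: tuple[int, ...] = DEFAULT_CANDIDATES
    b2: tuple[int, ...] = DEFAULT_CANDIDATES
    b3: tuple[int, ...] = DEFAULT_CANDIDATES

    def __post_init__(self) -> None:
        for dim in ("b1", "b2", "b3"):
            vals = getattr(self, dim)
            if not vals:
                raise ValueError(f"empty candidate list for {dim}")
            if min(vals) < 1:
                raise ValueError(f"candidates for {dim} must be >= 1")


def tss_enumerate(grid: CandidateGrid = CandidateGrid()) -> list[TileSize]:
    """Cartesian product of the candidate lists in lexicographic order."""
    return [TileSize(*t) for t in product(grid.b1, grid.b2, grid.b3)]


def is_valid_tile_size(B: TileSize, proxy_n: int = 24) -> bool:
    """Validity of a tile size: family membership or desk-scale oracle.

    b1 = 1 candidates belong to the pre-verified family.  Other candidates
    are checked by constructing the corrected tiling at the proxy problem
    size and running both the lexicographic and the wavefront validity
    oracles.
    """
    B = TileSize(*B).validated()
    if B.b1 == 1:
        return True
    tilemap = _tilemap_cached(proxy_n, B)
    graph = _graph_cached(proxy_n)
    if validate_schedule(tilemap, graph, lexicographic_order(tilemap)):
        return False
    try:
        check_wavefronts(tilemap, graph)
    except ScheduleError:
        return False
    return True


def default_timer(B: TileSize, thunk: Callable[[], None]) -> float:
    """Wall-clock seconds of one execution of ``thunk``."""
    t0 = time.perf_counter()
    thunk()
    return time.perf_counter() - t0


@dataclass(frozen=True)
class TssRecord:
    """One search-table row: tile size, validity, median runtime, rank."""

    B: TileSize
    valid: bool
    runtime: Optional[float]  # None for invalid or failed candidates
    repeats: int
    rank: Optional[int]  # 1-based over valid timed records; None otherwise
    error: Optional[str] = None


def tss_search(
    seq: RnaSequence,
    grid: CandidateGrid = CandidateGrid(),
    repeats: int = 3,
    timer: Callable[[TileSize, Callable[[], None]], float] = default_timer,
    seed: int = 0,
    proxy_n: int = 24,
    rule: PairingRule = DEFAULT_RULE,
) -> list[TssRecord]:
    """Search a candidate grid: validate, time, rank.

    For each candidate: check validity (see :func:`is_valid_tile_size`),
    then time ``tiled_fill`` with one warm-up plus ``repeats`` measured
    runs, taking the median.  Records are ranked by ascending runtime over
    the valid, successfully timed candidates, with the tile size as a
    deterministic tie-break; ties in runtime therefore never reorder
    between runs.  A failing timer marks its record and the search goes
    on.  Raises if no candidate is valid.
    """
    if isinstance(seq, str):
        seq = RnaSequence.from_string(seq)
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    rows: list[tuple[TileSize, bool, Optional[float], Optional[str]]] = []
    any_valid = False
    for B in tss_enumerate(grid):
        try:
            valid = is_valid_tile_size(B, proxy_n=proxy_n)
        except Exception as exc:  # validity check itself failed
            rows.append((B, False, None, str(exc)))
            continue
        if not valid:
            rows.append((B, False, None, None))
            continue
        any_valid = True
        rng = np.random.default_rng(seed)

        def thunk(B=B, rng=rng):
            tiled_fill(seq, rule, B, rng=rng if B.b1 != 1 else None)

        try:
            samples = [timer(B, thunk) for _ in range(repeats + 1)]
            runtime = statistics.median(samples[1:])  # drop the warm-up
            rows.append((B, True, runtime, None))
        except Exception as exc:
            rows.append((B, True, None, f"timing failed: {exc}"))
    if not any_valid:
        raise ValueError("no valid candidate in the grid")
    ranked = sorted(
        (r for r in rows if r[1] and r[2] is not None), key=lambda r: (r[2], r[0])
    )
    rank_of = {r[0]: idx + 1 for idx, r in enumerate(ranked)}
    return [
        TssRecord(B, valid, runtime, repeats, rank_of.get(B), err)
        for B, valid, runtime, err in rows
    ]
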
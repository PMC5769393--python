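"""Sparse integer model lifting two fixed-tile-size codes to a parametric one.

A tiled code generated for a fixed tile size B = (b1, b2, b3) contains
integer factors (loop-bound constants, strides, offsets).  Generating the
same code twice, for two different prime tile-size vectors B1 and B2,
yields identical structure with different factors; each factor position
gives a pair (y1, y2).  Every factor is assumed to follow the affine model

    y = a0*(b1*b2) + a1*b1 + a2*b2 + a3*b3 + a4

with unknown integer coefficients a0..a4 of which at most two are nonzero.
Fitting a pair means finding the unique exact integer solution over
candidate supports of size <= 2; substituting the symbolic b's back into
the fitted expression turns the fixed code parametric.

Prime tile sizes (defaults B1 = [23, 47, 113], B2 = [37, 79, 167]) keep
products and sums from colliding, which is what makes small supports
identifiable.  The support search order is fixed so that fitting is
deterministic: the constant first, then single linear terms, then a linear
term plus constant, then linear pairs, then supports involving the b1*b2
product.  If several supports inside one rank solve exactly (with distinct
coefficient vectors) the fit refuses rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .tiling import TileSize

__all__ = [
    "DEFAULT_B1",
    "DEFAULT_B2",
    "ModelCoefficients",
    "FactorPair",
    "UnmodellableFactor",
    "AmbiguousFactor",
    "fit_factor_model",
    "predict_factor",
    "fit_code_model",
    "FitResult",
    "SUPPORT_RANKS",
]

DEFAULT_B1 = TileSize(23, 47, 113)
DEFAULT_B2 = TileSize(37, 79, 167)

#: coefficient names in basis order (a0 multiplies b0 = b1*b2, a4 is the constant)
_COEFFS = ("a0", "a1", "a2", "a3", "a4")

#: support priority: rank lists searched in order; within a rank every
#: support is tried and distinct exact solutions are an error
SUPPORT_RANKS: tuple[tuple[tuple[str, ...], ...], ...] = (
    (("a4",),),
    (("a1",), ("a2",), ("a3",)),
    (("a0",),),
    (("a1", "a4"), ("a2", "a4"), ("a3", "a4")),
    (("a1", "a2"), ("a1", "a3"), ("a2", "a3")),
    (("a0", "a4"), ("a0", "a1"), ("a0", "a2"), ("a0", "a3")),
)


class UnmodellableFactor(ValueError):
    """No sparse support solves the factor pair exactly."""


class AmbiguousFactor(ValueError):
    """Several supports of the same rank solve the pair; refusing to choose."""

    def __init__(self, pair, candidates):
        self.candidates = candidates
        super().__init__(
            f"factor pair ({pair.y1}, {pair.y2}) admits {len(candidates)} exact "
            f"solutions at the same priority rank: {candidates}"
        )


@dataclass(frozen=True)
class ModelCoefficients:
    """Integer coefficients of y = a0*b1*b2 + a1*b1 + a2*b2 + a3*b3 + a4."""

    a0: int = 0
    a1: int = 0
    a2: int = 0
    a3: int = 0
    a4: int = 0

    def __post_init__(self) -> None:
        nz = sum(1 for a in self.as_tuple() if a != 0)
        if nz > 2:
            raise ValueError(f"at most two nonzero coefficients allowed, got {nz}")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.a0, self.a1, self.a2, self.a3, self.a4)

    def formula(self) -> str:
        """Human-readable expression, e.g. '2*b1+b2', 'b1-1', 'b1*b2', '7'."""
        terms = []
        for coef, sym in zip(self.as_tuple(), ("b1*b2", "b1", "b2", "b3", "")):
            if coef == 0:
                continue
            if sym == "":
                terms.append(f"{coef:+d}")
            elif abs(coef) == 1:
                terms.append(("+" if coef > 0 else "-") + sym)
            else:
                terms.append(f"{coef:+d}*{sym}")
        if not terms:
            return "0"
        out = "".join(terms)
        return out[1:] if out.startswith("+") else out


@dataclass(frozen=True)
class FactorPair:
    """A factor observed at the same position of the two fixed-size codes."""

    y1: int
    y2: int
    B1: TileSize = DEFAULT_B1
    B2: TileSize = DEFAULT_B2

    def __post_init__(self) -> None:
        if tuple(self.B1) == tuple(self.B2):
            raise ValueError("B1 and B2 must differ in at least one coordinate")


def _basis_value(name: str, B: TileSize) -> int:
    b1, b2, b3 = B
    return {"a0": b1 * b2, "a1": b1, "a2": b2, "a3": b3, "a4": 1}[name]


def _solve_support(pair: FactorPair, support: tuple[str, ...]) -> Optional[ModelCoefficients]:
    """Exact integer solution of the 2-equation system on one support.

    Integer-only arithmetic: a 1-unknown support needs one consistent exact
    division; a 2-unknown support is solved by Cramer's rule with
    divisibility checks.  Singular 2x2 systems are skipped (they cannot
    pin a unique solution).
    """
    y1, y2 = pair.y1, pair.y2
    if len(support) == 1:
        (u,) = support
        v1, v2 = _basis_value(u, pair.B1), _basis_value(u, pair.B2)
        if v1 and y1 % v1 == 0 and y1 // v1 * v2 == y2:
            return ModelCoefficients(**{u: y1 // v1})
        return None
    u, w = support
    u1, u2 = _basis_value(u, pair.B1), _basis_value(u, pair.B2)
    w1, w2 = _basis_value(w, pair.B1), _basis_value(w, pair.B2)
    det = u1 * w2 - u2 * w1
    if det == 0:
        return None
    num_u = y1 * w2 - y2 * w1
    num_w = u1 * y2 - u2 * y1
    if num_u % det or num_w % det:
        return None
    return ModelCoefficients(**{u: num_u // det, w: num_w // det})


def fit_factor_model(pair: FactorPair) -> ModelCoefficients:
    """Fit the sparse integer factor model to one (y1, y2) pair.

    Ranks of candidate supports are searched in the fixed priority order;
    the first rank with an exact solution wins.  Distinct coefficient
    vectors within one rank raise :class:`AmbiguousFactor` (never silently
    chosen); no solution at any rank raises :class:`UnmodellableFactor`.
    """
    if pair.y1 == 0 and pair.y2 == 0:
        return ModelCoefficients()
    for rank in SUPPORT_RANKS:
        found: list[ModelCoefficients] = []
        for support in rank:
            sol = _solve_support(pair, support)
            if sol is not None and sol not in found:
                found.append(sol)
        if len(found) == 1:
            return found[0]
        if len(found) > 1:
            raise AmbiguousFactor(pair, found)
    raise UnmodellableFactor(
        f"unmodellable factor pair ({pair.y1}, {pair.y2}) under "
        f"B1={tuple(pair.B1)}, B2={tuple(pair.B2)}"
    )


def predict_factor(coeffs: ModelCoefficients, B: TileSize) -> int:
    """Evaluate a0*b1*b2 + a1*b1 + a2*b2 + a3*b3 + a4 at a tile size."""
    b1, b2, b3 = B
    return coeffs.a0 * b1 * b2 + coeffs.a1 * b1 + coeffs.a2 * b2 + coeffs.a3 * b3 + coeffs.a4


@dataclass(frozen=True)
class FitResult:
    """One row of the code-model table."""

    position: str
    y1: int
    y2: int
    coeffs: Optional[ModelCoefficients]
    error: Optional[str] = None

    @property
    def formula(self) -> str:
        return self.coeffs.formula() if self.coeffs else f"<{self.error}>"


def fit_code_model(
    pairs: Sequence[FactorPair], positions: Optional[Sequence[str]] = None
) -> list[FitResult]:
    """Fit every factor position of a code pair independently.

    Returns one :class:`FitResult` per pair, mirroring the usual reporting
    table (y1, y2, a0..a4, formula); per-pair failures are recorded with
    the position attached instead of aborting the whole table.
    """
    if positions is None:
        positions = [str(idx) for idx in range(len(pairs))]
    if len(positions) != len(pairs):
        raise ValueError("positions and pairs must have equal length")
    out: list[FitResult] = []
    for label, pair in zip(positions, pairs):
        try:
            coeffs = fit_factor_model(pair)
            out.append(FitResult(label, pair.y1, pair.y2, coeffs))
        except (UnmodellableFactor, AmbiguousFactor) as exc:
            out.append(FitResult(label, pair.y1, pair.y2, None, error=f"{label}: {exc}"))
    return out
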
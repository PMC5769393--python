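"""Nussinov maximum-base-pair folding: reference fill, oracle, traceback.

Nussinov's dynamic program scores an RNA strand x_1..x_N by the maximum
number of complementary base pairs a non-crossing secondary structure can
contain.  With sigma(i, j) = 1 iff (x_i, x_j) is an allowed pair separated
by at least one base, the table S satisfies, over 0 <= i < j <= N-1,

    S[i][j] = max( S[i+1][j-1] + sigma(i, j),
                   max_{i <= k < j} ( S[i][k] + S[k+1][j] ) )

and S is zero on and below the main diagonal.  S[0][N-1] is the optimal
pair count.

:func:`fill_reference` evaluates the recurrence in the canonical serial
order (rows bottom-up, columns left-to-right, all split terms before the
pairing term), which is the order every alternative schedule in this
package must reproduce bit-exactly.  :func:`brute_force_max_pairs` is an
independent enumeration oracle for small N, and :func:`traceback` recovers
one optimal structure deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import DEFAULT_RULE, PairingRule, RnaSequence, SequenceError

__all__ = [
    "sigma",
    "fill_reference",
    "brute_force_max_pairs",
    "Structure",
    "traceback",
    "check_matrix",
    "BRUTE_FORCE_CAP",
]

#: default refusal threshold for the exponential enumeration oracle
BRUTE_FORCE_CAP = 16


def sigma(seq: RnaSequence, i: int, j: int, rule: PairingRule = DEFAULT_RULE) -> int:
    """Pairing indicator: 1 iff (seq[i], seq[j]) is allowed and j - i >= 2."""
    n = len(seq)
    if not (0 <= i < j <= n - 1):
        raise ValueError(f"sigma requires 0 <= i < j <= N-1, got i={i}, j={j}, N={n}")
    if j - i < rule.min_separation:
        return 0
    return 1 if rule.allows(seq[i], seq[j]) else 0


def fill_reference(seq: RnaSequence, rule: PairingRule = DEFAULT_RULE) -> np.ndarray:
    """Fill the Nussinov matrix in the canonical serial order.

    Rows are processed with i descending from N-1, columns with j ascending
    from i+1; for each cell all split-term updates (reading S[i][i+k] and
    S[i+k+1][j] for k = 0..j-i-1) precede the pairing-term update reading
    S[i+1][j-1].  The split maximum over k is evaluated as one vectorized
    reduction, which is arithmetically identical to the serial sequence of
    max-updates.

    Returns an N x N int64 array; the diagonal and lower triangle are 0.
    """
    if isinstance(seq, str):  # convenience for interactive use
        seq = RnaSequence.from_string(seq)
    n = len(seq)
    if n == 0:
        raise SequenceError("empty sequence")
    S = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            # split terms: k = 0..j-i-1 reads S[i][i+k] and S[i+k+1][j]
            best = int(np.max(S[i, i:j] + S[i + 1 : j + 1, j]))
            # pairing term
            pair = int(S[i + 1, j - 1]) + sigma(seq, i, j, rule)
            S[i, j] = best if best >= pair else pair
    return S


def brute_force_max_pairs(
    seq: RnaSequence, rule: PairingRule = DEFAULT_RULE, cap: int = BRUTE_FORCE_CAP
) -> int:
    """Maximum pair count by exhaustive enumeration of non-crossing pairings.

    Backtracks over the leftmost free index: leave it unpaired, or pair it
    with every admissible partner; pairing index i with h splits the
    remaining indices into the enclosed interval (i+1, h-1) and the outer
    interval (h+1, j), which is exactly the non-crossing condition.  No
    memoization is used, so this is independent of the dynamic program it
    checks.  Exponential: refuses sequences longer than ``cap``.
    """
    if isinstance(seq, str):
        seq = RnaSequence.from_string(seq)
    n = len(seq)
    if n > cap:
        raise ValueError(
            f"brute_force_max_pairs is exponential; N={n} exceeds cap={cap}"
        )

    def enum(i: int, j: int) -> int:
        if j - i < rule.min_separation:
            return 0
        best = enum(i + 1, j)  # i unpaired
        for h in range(i + rule.min_separation, j + 1):
            if rule.allows(seq[i], seq[h]):
                best = max(best, 1 + enum(i + 1, h - 1) + enum(h + 1, j))
        return best

    return enum(0, n - 1)


@dataclass(frozen=True)
class Structure:
    """A non-crossing secondary structure: paired indices plus dot-bracket.

    ``pairs`` holds 0-based (i, j) with i < j; ``dot_bracket`` is the usual
    serialization with '(' at i, ')' at j and '.' elsewhere.  The
    constructor enforces the structural invariants (disjoint indices,
    non-crossing, bracket string consistent with the pair set).
    """

    pairs: frozenset
    dot_bracket: str

    def __post_init__(self) -> None:
        n = len(self.dot_bracket)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j <= n - 1):
                raise ValueError(f"pair {(i, j)} out of range for length {n}")
            if i in seen or j in seen:
                raise ValueError(f"index reused by pair {(i, j)}")
            seen.update((i, j))
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            i, j = plist[a]
            for p, q in plist[a + 1 :]:
                if i < p < j < q:
                    raise ValueError(f"crossing pairs {(i, j)} and {(p, q)}")
        expected = ["."] * n
        for i, j in self.pairs:
            expected[i] = "("
            expected[j] = ")"
        if "".join(expected) != self.dot_bracket:
            raise ValueError("dot_bracket inconsistent with pair set")

    @classmethod
    def from_pairs(cls, pairs, n: int) -> "Structure":
        db = ["."] * n
        for i, j in pairs:
            db[i] = "("
            db[j] = ")"
        return cls(pairs=frozenset(tuple(p) for p in pairs), dot_bracket="".join(db))

    def __len__(self) -> int:
        return len(self.dot_bracket)


def check_matrix(S: np.ndarray, *, allow_mirror: bool = True) -> None:
    """Validate DP-matrix invariants; raise ValueError if they fail.

    Checks non-negativity, the pair-count ceiling floor((j-i+1)/2), and the
    two monotonicity relations implied by the k = i and k = j-1 split terms
    (S[i][j] >= S[i+1][j] and S[i][j] >= S[i][j-1]).  The lower triangle
    must be either all zero or the exact transpose of the upper triangle
    (``allow_mirror`` covers schedules that mirror for cache efficiency).
    """
    S = np.asarray(S)
    n = S.shape[0]
    if S.ndim != 2 or S.shape[1] != n:
        raise ValueError("S must be square")
    if (S < 0).any():
        raise ValueError("negative entry in S")
    iu, ju = np.triu_indices(n, k=1)
    if (S[iu, ju] > (ju - iu + 1) // 2).any():
        raise ValueError("entry exceeds floor((j-i+1)/2) pair ceiling")
    # monotonicity: S[i][j] >= S[i+1][j] and S[i][j] >= S[i][j-1] on i<j,
    # checked on the zero-padded upper triangle (sub-diagonal terms are 0)
    up = np.triu(S, k=1)
    if n > 1:
        if (up[:-1, 1:] < up[1:, 1:]).any():
            raise ValueError("monotonicity violated: S[i][j] < S[i+1][j]")
        if (up[:-1, 1:] < up[:-1, :-1]).any():
            raise ValueError("monotonicity violated: S[i][j] < S[i][j-1]")
    low = np.tril(S, k=-1)
    if low.any():
        if not allow_mirror or not np.array_equal(low, np.triu(S, k=1).T):
            raise ValueError("lower triangle neither zero nor a mirror of the upper")
    if np.diag(S).any():
        raise ValueError("main diagonal must be zero")


def traceback(
    S: np.ndarray, seq: RnaSequence, rule: PairingRule = DEFAULT_RULE
) -> Structure:
    """Recover one optimal structure from a filled matrix.

    Deterministic tie-break: at each cell prefer the pairing branch when it
    attains the optimum with sigma = 1, otherwise take the smallest split
    point k and recurse into the left part first.  The returned structure
    always carries exactly S[0][N-1] pairs.
    """
    if isinstance(seq, str):
        seq = RnaSequence.from_string(seq)
    n = len(seq)
    check_matrix(S)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n > 1 else []
    while stack:
        i, j = stack.pop()
        if j - i < rule.min_separation or S[i, j] == 0:
            continue
        if sigma(seq, i, j, rule) == 1 and S[i, j] == S[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            left = S[i, k] if k > i else 0
            right = S[k + 1, j] if k + 1 < j else 0
            if S[i, j] == left + right:
                # push right first so the left part is processed first
                stack.append((k + 1, j))
                stack.append((i, k))
                break
        else:  # pragma: no cover - guarded by check_matrix
            raise ValueError(f"no recurrence branch matches S[{i}][{j}]; S inconsistent")
    st = Structure.from_pairs(pairs, n)
    if len(st.pairs) != int(S[0, n - 1]) and n > 1:
        raise ValueError("traceback pair count disagrees with S[0][N-1]")
    return st
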
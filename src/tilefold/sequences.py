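"""RNA sequences and base-pairing rules.

The folding code works on plain RNA strings over {A, C, G, U}.  Input is
normalized aggressively (lowercase accepted, DNA ``T`` mapped to ``U``)
because DNA-alphabet FASTA files are common carriers of transcript
sequences; anything outside the alphabet after normalization is a hard
error that names the offending position.

A :class:`PairingRule` decides which residue pairs may stack.  The default
is Watson-Crick (A-U, G-C) plus the G-U wobble pair, which is the standard
choice for maximum-base-pair folding; a Watson-Crick-only rule and an empty
rule are available for sensitivity checks.  Two paired residues must be
separated by at least one unpaired base (``j - i >= 2``), which forbids
sterically impossible hairpins of zero length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "SequenceError",
    "RnaSequence",
    "PairingRule",
    "DEFAULT_RULE",
    "normalize_residues",
]

RNA_ALPHABET = frozenset("ACGU")

#: minimum index separation for a base pair: j - i >= 2, i.e. i < j - 1
MIN_SEPARATION = 2


class SequenceError(ValueError):
    """Raised for malformed or non-RNA input sequences."""


def normalize_residues(raw: str, *, name: str = "") -> str:
    """Uppercase ``raw``, map T to U, and validate the alphabet.

    Raises :class:`SequenceError` naming the record and 1-based position of
    the first illegal residue.
    """
    up = raw.upper().replace("T", "U")
    for pos, ch in enumerate(up, start=1):
        if ch not in RNA_ALPHABET:
            where = f" in record {name!r}" if name else ""
            raise SequenceError(
                f"illegal residue {ch!r} at position {pos}{where}; "
                "expected one of A, C, G, U (T is accepted and mapped to U)"
            )
    return up


@dataclass(frozen=True)
class RnaSequence:
    """An RNA strand x_1..x_N over {A, C, G, U}.

    ``residues`` must already be normalized; use :meth:`from_string` for
    arbitrary user input.
    """

    residues: str
    id: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("empty sequence")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise SequenceError(
                f"non-normalized residues {sorted(bad)}; use RnaSequence.from_string"
            )

    @classmethod
    def from_string(cls, raw: str, id: str = "") -> "RnaSequence":
        return cls(normalize_residues(raw, name=id), id=id)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, idx):
        return self.residues[idx]

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __str__(self) -> str:
        return self.residues


def _sym(pairs) -> frozenset:
    """Freeze a collection of 2-tuples into a symmetric set of pairs."""
    out = set()
    for x, y in pairs:
        out.add(frozenset((x, y)))
    return frozenset(out)


@dataclass(frozen=True)
class PairingRule:
    """Which unordered residue pairs may form, plus the loop constraint.

    ``allowed_pairs`` is a set of ``frozenset`` pairs so that (x, y) is
    allowed iff (y, x) is.  ``min_separation`` is the smallest admissible
    ``j - i`` for a pair (fixed to 2: paired bases must enclose at least
    one residue).
    """

    allowed_pairs: frozenset = field(
        default_factory=lambda: _sym([("A", "U"), ("G", "C"), ("G", "U")])
    )
    min_separation: int = MIN_SEPARATION

    @classmethod
    def watson_crick(cls, wobble: bool = True) -> "PairingRule":
        pairs = [("A", "U"), ("G", "C")]
        if wobble:
            pairs.append(("G", "U"))
        return cls(allowed_pairs=_sym(pairs))

    @classmethod
    def none(cls) -> "PairingRule":
        """A rule under which no pair forms (folds everything to zero)."""
        return cls(allowed_pairs=frozenset())

    def allows(self, x: str, y: str) -> bool:
        key = frozenset((x, y))
        return key in self.allowed_pairs


DEFAULT_RULE = PairingRule.watson_crick()
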
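"""File formats, synthetic strand generation, and report writers.

FASTA is the input carrier (parsed with Biopython, then normalized to the
RNA alphabet); outputs are plain text: dot-bracket structure files, TSV
pair lists, CSV tile-size-selection tables, TSV violation reports.  All
randomness flows through explicit seeds, so identical configurations give
byte-identical output files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO

from .fold import Structure
from .sequences import RnaSequence, SequenceError
from .tss import TssRecord
from .tiling import Violation

__all__ = [
    "read_fasta",
    "SynthSpec",
    "synth_rna",
    "write_structure",
    "write_pairs_tsv",
    "write_tss_csv",
    "write_violations_tsv",
    "load_config",
]

_BASES = ("A", "C", "G", "U")


def read_fasta(path) -> list[RnaSequence]:
    """Parse a (multi-record) FASTA file into normalized RNA sequences.

    T is mapped to U and case is folded; an illegal residue raises
    :class:`SequenceError` naming the record and its 1-based position.
    """
    path = Path(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(RnaSequence.from_string(str(rec.seq), id=rec.id))
    return out


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a seeded random RNA strand with i.i.d. residues."""

    length: int
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        f = self.base_frequencies
        if len(f) != 4 or min(f) < 0 or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(
                f"base_frequencies must be 4 non-negative values summing to 1, got {f}"
            )


def synth_rna(spec: SynthSpec) -> RnaSequence:
    """Random strand emulating randomly generated RNA inputs; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    draws = rng.choice(4, size=spec.length, p=list(spec.base_frequencies))
    return RnaSequence(
        "".join(_BASES[d] for d in draws), id=f"synth-n{spec.length}-s{spec.seed}"
    )


def write_structure(path, seq: RnaSequence, structure: Structure) -> None:
    """Dot-bracket file: sequence line + bracket line per record."""
    with open(path, "w") as fh:
        fh.write(f"{seq.residues}\n{structure.dot_bracket}\n")


def write_pairs_tsv(path, seq: RnaSequence, structure: Structure) -> None:
    """Pair list as TSV with 1-based indices and the paired residues."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["i", "j", "residues"])
        for i, j in sorted(structure.pairs):
            w.writerow([i + 1, j + 1, f"{seq[i]}-{seq[j]}"])


def write_tss_csv(path, records: Sequence[TssRecord]) -> None:
    """Search table: one row per candidate, valid timed rows ranked first."""
    ordered = sorted(
        records, key=lambda r: (r.rank is None, r.rank if r.rank is not None else 0, r.B)
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["b1", "b2", "b3", "valid", "runtime_s", "rank"])
        for r in ordered:
            w.writerow(
                [
                    r.B.b1,
                    r.B.b2,
                    r.B.b3,
                    int(r.valid),
                    "" if r.runtime is None else f"{r.runtime:.6f}",
                    "" if r.rank is None else r.rank,
                ]
            )


def write_violations_tsv(path, violations: Iterable[Violation]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["src_stmt", "src_i", "src_j", "src_k", "dst_stmt", "dst_i", "dst_j",
             "dst_k", "src_tile", "dst_tile"]
        )
        for v in violations:
            w.writerow(
                [
                    f"s{v.source.stmt}", v.source.i, v.source.j, v.source.k,
                    f"s{v.target.stmt}", v.target.i, v.target.j, v.target.k,
                    "/".join(map(str, v.source_tile)), "/".join(map(str, v.target_tile)),
                ]
            )


def load_config(path) -> dict:
    """YAML experiment manifest (pairing rule, grids, seeds); CLI flags override."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
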
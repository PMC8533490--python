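"""Shared primitives: intervals, sequence helpers, error types.

All genomic coordinates inside the package are 0-based half-open on the
forward strand of the named sequence; GFF3 output converts to 1-based
inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn",
                            "TGCAYRMKVHDBNtgcayrmkvhdbn")

# Highest-usage sense codon per amino acid (one fixed codon each, so that
# reverse translation is deterministic and never introduces an in-frame stop).
MOST_FREQUENT_CODON = {
    "A": "GCC", "R": "CGC", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCC",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}
STOP_CODON = "TAA"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class SailorError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(SailorError):
    """An element/degradation/scenario specification is internally inconsistent."""


class CapacityError(SailorError):
    """A genome is too short to host the requested insertions."""


class CoordinateError(SailorError):
    """An interval falls outside its sequence."""


class ParameterError(SailorError):
    """An operation parameter is out of its valid range."""


class ParseError(SailorError):
    """A text input could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FlankError(SailorError):
    """Not enough flanking sequence for the requested operation."""


class InsufficientDataError(SailorError):
    """Too few usable alignment columns to estimate a distance."""


class ConfigurationError(SailorError):
    """A rule table or configuration file is invalid."""


@dataclass(frozen=True)
class GenomicInterval:
    """A located region on a named sequence (0-based, half-open)."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise CoordinateError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}")
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.seq_id == other.seq_id
                and self.start < other.end and other.start < self.end)

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.seq_id, self.start + offset,
                               self.end + offset, self.strand)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform A/C/G/T background sequence."""
    return "".join(np.array(list(DNA_ALPHABET))[rng.integers(0, 4, size=length)])


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)])


def reverse_translate(protein: str) -> str:
    """Deterministic reverse translation via the fixed codon table, plus stop."""
    try:
        return "".join(MOST_FREQUENT_CODON[aa] for aa in protein) + STOP_CODON
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise InvalidSpecError(f"cannot reverse-translate residue {exc}") from exc


def translate(nt: str) -> str:
    """Standard-table translation of an in-frame nucleotide string."""
    from Bio.Seq import Seq

    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())


def derive_seed(seed: int, *salt: int) -> int:
    """Deterministically fold extra integers into a sub-stream seed (< 2**31)."""
    mask = (1 << 64) - 1
    h = seed & mask
    for s in salt:
        h = (h * 6364136223846793005 + s + 1442695040888963407) & mask
    return h % (2**31 - 1)
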
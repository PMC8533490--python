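"""FASTA / GFF3 / TSV input-output helpers.

GFF3 files are written 1-based inclusive. Elements are emitted as
``terminal_inverted_repeat_element`` features with ``terminal_inverted_repeat``
and ``target_site_duplication`` children, matching the truth tables produced by
the synthetic-genome generator so that annotation round-trips can be compared
record for record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ParseError

GFF_ELEMENT = "terminal_inverted_repeat_element"
GFF_TIR = "terminal_inverted_repeat"
GFF_TSD = "target_site_duplication"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


@dataclass
class Gff3Record:
    """One GFF3 feature line (start/end already 1-based inclusive)."""

    seq_id: str
    type: str
    start: int
    end: int
    strand: str
    source: str = "sailorte"
    score: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items()) or "."
        return "\t".join([self.seq_id, self.source, self.type, str(self.start),
                          str(self.end), self.score, self.strand, ".", attrs])

    @property
    def key(self) -> tuple:
        """Coordinate identity used when comparing truth vs annotation."""
        return (self.seq_id, self.type, self.start, self.end, self.strand)


def write_gff3(path: str | Path, records: Iterable[Gff3Record]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(rec.line() + "\n")


def read_gff3(path: str | Path) -> list[Gff3Record]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"expected 9 GFF3 columns, got {len(fields)}", lineno)
            attrs = {}
            if fields[8] != ".":
                for chunk in fields[8].split(";"):
                    if chunk:
                        k, _, v = chunk.partition("=")
                        attrs[k] = v
            records.append(Gff3Record(
                seq_id=fields[0], source=fields[1], type=fields[2],
                start=int(fields[3]), end=int(fields[4]), score=fields[5],
                strand=fields[6], attributes=attrs))
    return records
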
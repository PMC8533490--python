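"""Candidate transposase discovery.

Two entry paths produce :class:`CandidateLocus` lists: an internal six-frame
stop-to-stop ORF scan followed by catalytic-motif screening, and a reader for
externally produced homology hits in 12-column BLAST tabular format (the
classic ``-outfmt 6`` dialect).  Candidate loci are extracted with flanking
sequence (2 kb by default, enough to cover the TIRs and UTRs of known
IS630-Tc1-mariner families) for downstream TIR/TSD annotation.

The ORF scan substitutes for spliced gene prediction: transposase ORFs are
intronless in practice and the intactness criterion used downstream is
ORF-based anyway.  Length thresholds are strict: the default 300 means an ORF
must exceed 300 aa to be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import CoordinateError, GenomicInterval, ParseError, revcomp, translate
from .dde_signature import get_motif_set, motif_matches, scan_triads


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    position: int
    mismatches: int


@dataclass
class CandidateLocus:
    """A candidate transposase locus with its translated product."""

    interval: GenomicInterval
    frame: int                    # 1..3 forward, -1..-3 reverse, 0 for external hits
    protein: str
    motif_hits: list[MotifHit] = field(default_factory=list)
    source: str = "internal-scan"


def six_frame_orfs(genome: str, min_protein_len: int = 300,
                   seq_id: str = "seq") -> list[tuple[GenomicInterval, int, str]]:
    """Maximal stop-to-stop ORFs longer than ``min_protein_len`` on both strands.

    Intervals give the genome coordinates of the codon span (stop codon
    excluded).  Frames are 1-based and negative on the reverse strand.
    """
    results = []
    L = len(genome)
    for strand_seq, sign in ((genome, 1), (revcomp(genome), -1)):
        for offset in range(3):
            protein = translate(strand_seq[offset:])
            pos = 0
            for segment in protein.split("*"):
                if len(segment) > min_protein_len:
                    nt_start = offset + pos * 3
                    nt_end = nt_start + len(segment) * 3
                    if sign == 1:
                        interval = GenomicInterval(seq_id, nt_start, nt_end, "+")
                    else:
                        interval = GenomicInterval(seq_id, L - nt_end,
                                                   L - nt_start, "-")
                    results.append((interval, sign * (offset + 1), segment))
                pos += len(segment) + 1
    results.sort(key=lambda r: (r[0].start, r[0].end, r[1]))
    return results


def motif_scan(protein: str, motif_set: str = "sailor",
               max_mismatch_per_motif: int = 1) -> list:
    """Triad candidates (all three motifs in order, each within tolerance).

    Candidates are ranked by total mismatches then leftmost anchored D
    position; overlapping candidates are allowed.  See
    :func:`sailorte.dde_signature.locate_triad` for the anchored version used
    in classification.
    """
    return scan_triads(protein, motif_set, max_mismatch_per_motif)


def motif_hit_list(protein: str, motif_set: str,
                   max_mismatch_per_motif: int = 1) -> list[MotifHit]:
    """Flat per-motif hit list (ordered by position) for locus bookkeeping."""
    ms = get_motif_set(motif_set)
    hits = []
    for motif in ms.motifs:
        for start, mm in motif_matches(protein, motif, max_mismatch_per_motif):
            hits.append(MotifHit(motif.name, start, mm))
    hits.sort(key=lambda h: h.position)
    return hits


def find_candidate_loci(genome: str, motif_set: str = "sailor",
                        min_protein_len: int = 300,
                        max_mismatch_per_motif: int = 1,
                        seq_id: str = "seq") -> list[CandidateLocus]:
    """Internal mining path: ORF scan + triad-motif screen."""
    loci = []
    for interval, frame, protein in six_frame_orfs(genome, min_protein_len,
                                                   seq_id=seq_id):
        if scan_triads(protein, motif_set, max_mismatch_per_motif):
            loci.append(CandidateLocus(
                interval=interval, frame=frame, protein=protein,
                motif_hits=motif_hit_list(protein, motif_set,
                                          max_mismatch_per_motif),
                source="internal-scan"))
    return loci


@dataclass(frozen=True)
class LocusMap:
    """Coordinate map from an extracted locus back to its genome."""

    genome_start: int

    def to_genome(self, locus_pos: int) -> int:
        return self.genome_start + locus_pos

    def to_locus(self, genome_pos: int) -> int:
        return genome_pos - self.genome_start


def extract_locus(genome: str, interval: GenomicInterval,
                  flank: int = 2000) -> tuple[str, LocusMap]:
    """Interval plus ``flank`` bp on each side, clipped at genome ends."""
    if interval.start > len(genome) or interval.end > len(genome):
        raise CoordinateError(
            f"interval [{interval.start}, {interval.end}) outside genome of "
            f"length {len(genome)}")
    start = max(0, interval.start - flank)
    end = min(len(genome), interval.end + flank)
    return genome[start:end], LocusMap(genome_start=start)


BLAST_TAB_COLUMNS = ["query", "subject", "pident", "length", "mismatch",
                     "gapopen", "qstart", "qend", "sstart", "send",
                     "evalue", "bitscore"]


def read_blast_tab(path, max_evalue: float = 1e-100) -> list[CandidateLocus]:
    """Ingest 12-column BLAST tabular hits (TBLASTN-style external search).

    Hits with an E-value above ``max_evalue`` are dropped.  Subject
    coordinates arrive 1-based inclusive with ``sstart > send`` on the minus
    strand; they are normalized to 0-based half-open plus a strand flag.
    """
    loci = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"expected 12 BLAST tabular columns, got {len(fields)}",
                    lineno)
            try:
                subject = fields[1]
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
            except ValueError as exc:
                raise ParseError(f"unparseable field ({exc})", lineno) from None
            if evalue > max_evalue:
                continue
            if sstart <= send:
                interval = GenomicInterval(subject, sstart - 1, send, "+")
            else:
                interval = GenomicInterval(subject, send - 1, sstart, "-")
            loci.append(CandidateLocus(interval=interval, frame=0, protein="",
                                       source="blast-tab"))
    return loci


def merge_candidate_intervals(loci: list[CandidateLocus]) -> list[GenomicInterval]:
    """Merge intervals overlapping by >= 1 bp (per sequence, strand-agnostic).

    How overlapping homology hits should be merged before flank extraction is
    underdetermined; this greedy union is the package's documented choice.
    """
    by_seq: dict[str, list[GenomicInterval]] = {}
    for locus in loci:
        by_seq.setdefault(locus.interval.seq_id, []).append(locus.interval)
    merged = []
    for seq_id, intervals in sorted(by_seq.items()):
        intervals.sort(key=lambda iv: (iv.start, iv.end))
        current = intervals[0]
        for iv in intervals[1:]:
            if iv.start < current.end:
                if iv.end > current.end:
                    current = GenomicInterval(seq_id, current.start, iv.end,
                                              current.strand)
            else:
                merged.append(current)
                current = iv
        merged.append(current)
    return merged


def loci_table(loci: list[CandidateLocus]) -> pd.DataFrame:
    """Candidate loci as a tidy table (for TSV export)."""
    return pd.DataFrame([{
        "seq_id": lc.interval.seq_id,
        "start": lc.interval.start,
        "end": lc.interval.end,
        "strand": lc.interval.strand,
        "frame": lc.frame,
        "protein_length": len(lc.protein),
        "n_motif_hits": len(lc.motif_hits),
        "source": lc.source,
    } for lc in loci])
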
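"""TIR/TSD annotation, element delimitation and classification.

Given a candidate locus (a transposase ORF plus flanking sequence), this
module finds the terminal-inverted-repeat pair by locally aligning the 5'
window against the reverse complement of the 3' window, calls the target-site
duplication from the genomic flanks, delimits the element at the outer TIR
edges, and classifies it:

* full-length — both TIRs present;
* intact      — full-length, transposase ORF > 300 aa and a catalytic triad
                located;
* fragment    — anything else.

Palindromic TSDs (TA, TATA) are perfect inverted repeats themselves, so the
raw TIR alignment necessarily absorbs them; boundaries are therefore refined
by trimming the largest ``t`` for which the trimmed boundaries exhibit an
exact ``t``-bp duplication.  Consensus building follows common practice:
majority rule over a multiple alignment when enough copies exist, otherwise
the longest copy is the representative.
"""

from __future__ import annotations

import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from itertools import islice
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

from .core import (FlankError, GenomicInterval, InvalidSpecError,
                   ParameterError, SailorError, revcomp)
from .dde_signature import CatalyticTriad, locate_triad, signature
from .io import GFF_ELEMENT, GFF_TIR, GFF_TSD, Gff3Record
from .mining import extract_locus, find_candidate_loci

# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class TirPair:
    """A detected terminal-inverted-repeat pair within one locus."""

    left: GenomicInterval
    right: GenomicInterval
    length: int
    identity: float
    alignment: tuple[str, str]


@dataclass(frozen=True)
class TsdCall:
    """A target-site duplication flanking an element."""

    sequence: str
    length: int
    upstream: GenomicInterval
    downstream: GenomicInterval


@dataclass
class TransposonElement:
    """An annotated element in genome coordinates."""

    interval: GenomicInterval
    tir: TirPair | None = None
    tsd: TsdCall | None = None
    orf: GenomicInterval | None = None
    protein: str | None = None
    triad: CatalyticTriad | None = None
    status: str = "fragment"
    element_id: str = ""

    @property
    def tir_length(self) -> int:
        return self.tir.length if self.tir else 0


# ---------------------------------------------------------------------------
# TIR detection


def _tir_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _alignment_columns(alignment) -> list[tuple[int | None, int | None, bool]]:
    """Per-column view of a pairwise alignment: (a_pos, b_pos, is_match);
    gap columns carry ``None`` on the gapped side."""
    a_blocks, b_blocks = alignment.aligned
    seq_a, seq_b = alignment.sequences
    columns: list[tuple[int | None, int | None, bool]] = []
    prev_a = prev_b = None
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        if prev_a is not None:
            for pos in range(prev_a, a0):
                columns.append((pos, None, False))
            for pos in range(prev_b, b0):
                columns.append((None, pos, False))
        for i in range(a1 - a0):
            columns.append((a0 + i, b0 + i, seq_a[a0 + i] == seq_b[b0 + i]))
        prev_a, prev_b = a1, b1
    return columns


def _best_core(columns, min_len: int, max_len: int, min_identity: float):
    """Highest-scoring contiguous sub-segment meeting the TIR bounds.

    The raw local alignment may carry noisy low-identity extensions (or be a
    purely spurious repeat); the reported TIR is the best internal core whose
    gap-excluded identity and span satisfy the thresholds.  Segments are
    scored with the alignment scoring (+1/-1/-2) and ties broken by longer
    span then smaller start offset.  Returns ``None`` when no segment
    qualifies.
    """
    match_idx = [i for i, col in enumerate(columns) if col[2]]
    n = len(columns)
    match_pref = np.cumsum([0] + [col[2] for col in columns])
    paired_pref = np.cumsum([0] + [col[0] is not None and col[1] is not None
                                   for col in columns])
    best = None
    for ai, a in enumerate(match_idx):
        for b in match_idx[ai:]:
            a_span = columns[b][0] - columns[a][0] + 1
            b_span = columns[b][1] - columns[a][1] + 1
            span = max(a_span, b_span)
            if span > max_len:
                break
            if span < min_len:
                continue
            matches = int(match_pref[b + 1] - match_pref[a])
            paired = int(paired_pref[b + 1] - paired_pref[a])
            gaps = (b - a + 1) - paired
            identity = matches / paired if paired else 0.0
            if identity < min_identity:
                continue
            score = matches - (paired - matches) - 2 * gaps
            key = (score, span, -a)
            if best is None or key > best[0]:
                best = (key, a, b, identity)
    return best


def find_tirs(locus: str, min_tir_len: int = 18, max_tir_len: int = 1500,
              search_window: int | None = None, min_identity: float = 0.8,
              seq_id: str = "locus", max_alternatives: int = 64) -> TirPair | None:
    """Highest-scoring inverted-repeat pair between the locus ends.

    The first ``search_window`` bp are locally aligned (match +1, mismatch
    -1, gap -2) against the reverse complement of the last ``search_window``
    bp.  The best-scoring pair satisfying the length and identity bounds is
    returned; among co-optimal alignments ties are broken by longer repeat,
    then smaller start offset.  Identity is computed over aligned columns
    excluding gaps.
    """
    if len(locus) < 2 * min_tir_len:
        raise ParameterError("locus shorter than twice min_tir_len")
    if search_window is None:
        window = min(len(locus) // 2, 2600)
    else:
        if search_window > len(locus):
            raise ParameterError("search_window larger than locus")
        window = min(search_window, len(locus) // 2)

    left_window = locus[:window]
    right_window_rc = revcomp(locus[-window:])
    alignments = _tir_aligner().align(left_window, right_window_rc)
    try:
        first = next(iter(alignments))
    except (StopIteration, ValueError):
        return None

    best = None
    for alignment in islice(alignments, max_alternatives):
        if alignment.score < first.score:
            break
        columns = _alignment_columns(alignment)
        core = _best_core(columns, min_tir_len, max_tir_len, min_identity)
        if core is None:
            continue
        key, a, b, identity = core
        if best is None or key > best[0]:
            best = (key, columns, a, b, identity, alignment)
    if best is None:
        return None
    _, columns, a, b, identity, alignment = best

    l0, l1 = columns[a][0], columns[b][0] + 1   # left window, half-open
    r0, r1 = columns[a][1], columns[b][1] + 1   # revcomp(right window)
    L = len(locus)
    left = GenomicInterval(seq_id, l0, l1, "+")
    right = GenomicInterval(seq_id, L - r1, L - r0, "+")
    return TirPair(left=left, right=right, length=l1 - l0, identity=identity,
                   alignment=(str(alignment[0]), str(alignment[1])))


# ---------------------------------------------------------------------------
# TSD detection and boundary refinement


def find_tsd(genome: str, element_interval: tuple[int, int] | GenomicInterval,
             k_range: range = range(2, 11),
             seq_id: str = "seq") -> TsdCall | None:
    """Longest exact duplication immediately flanking the element."""
    if isinstance(element_interval, GenomicInterval):
        start, end = element_interval.start, element_interval.end
        seq_id = element_interval.seq_id
    else:
        start, end = element_interval
    k_max = max(k_range)
    if start < k_max or end + k_max > len(genome):
        raise FlankError(
            f"need {k_max} bp of flank on both sides of [{start}, {end})")
    for k in sorted(k_range, reverse=True):
        upstream = genome[start - k:start]
        downstream = genome[end:end + k]
        if upstream == downstream:
            return TsdCall(sequence=upstream, length=k,
                           upstream=GenomicInterval(seq_id, start - k, start),
                           downstream=GenomicInterval(seq_id, end, end + k))
    return None


def _terminal_ir_run(genome: str, start: int, end: int, cap: int = 12) -> int:
    """Length of the exact inverted-repeat run anchored at both termini."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    run = 0
    for i in range(min(cap, (end - start) // 2)):
        if genome[start + i] != comp.get(genome[end - 1 - i], "?"):
            break
        run += 1
    return run


def refine_element_boundaries(genome: str, start: int, end: int,
                              k_range: range = range(2, 11),
                              seq_id: str = "seq", delta: int = 80,
                              min_ir_anchor: int = 8
                              ) -> tuple[int, int, TsdCall | None]:
    """Snap raw inverted-repeat boundaries onto the insertion-site signature.

    Local alignment of the locus ends overshoots the true element: palindromic
    TSDs (TA, TATA) are inverted repeats themselves and short gapped
    excursions into the flanks can score positively.  The overshoot is
    one-sided — the optimal alignment always contains the exact TSD+TIR run —
    so the true boundaries lie inside the raw ones.  Inward boundary pairs
    within ``delta`` bp are scored by (TSD length, element span, terminal-IR
    run); pairs without at least ``min_ir_anchor`` exact IR bases and a TSD
    are ignored.  If no pair qualifies (e.g. degraded flanks)
    the raw boundaries stand.
    """
    k_max = max(k_range)
    best = None
    for left in range(max(k_max, start), start + delta + 1):
        for right in range(end - delta, min(len(genome) - k_max, end) + 1):
            if right - left < 4 * k_max:
                continue
            ir_run = _terminal_ir_run(genome, left, right)
            if ir_run < min_ir_anchor:
                continue
            try:
                tsd = find_tsd(genome, (left, right), k_range, seq_id)
            except FlankError:
                continue
            if tsd is None:
                continue
            # strongest duplication evidence wins; among equals prefer the
            # outermost (longest) element, then the stronger IR anchor
            key = (tsd.length, right - left, ir_run)
            if best is None or key > best[0]:
                best = (key, left, right, tsd)
    if best is not None:
        _, left, right, tsd = best
        return left, right, tsd
    try:
        tsd = find_tsd(genome, (start, end), k_range, seq_id)
    except FlankError:
        tsd = None
    return start, end, tsd


# ---------------------------------------------------------------------------
# Classification


def classify_element(element: TransposonElement,
                     intact_min_aa: int = 300) -> str:
    """Status per the intactness rules (strict > on the ORF length)."""
    full_length = element.tir is not None
    intact = (full_length
              and element.protein is not None
              and len(element.protein) > intact_min_aa
              and element.triad is not None)
    element.status = ("intact" if intact
                      else "full-length" if full_length
                      else "fragment")
    return element.status


# ---------------------------------------------------------------------------
# Consensus / representative


def _run_mafft(copies: list[str]) -> list[str]:
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "copies.fasta"
        with open(fasta, "w") as fh:
            for i, seq in enumerate(copies):
                fh.write(f">copy_{i}\n{seq}\n")
        proc = subprocess.run(["mafft", "--auto", "--quiet", str(fasta)],
                              capture_output=True, text=True, check=True)
    aligned: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            aligned[name] = ""
        elif name is not None:
            aligned[name] += line.strip()
    return [aligned[f"copy_{i}"].upper() for i in range(len(copies))]


def build_consensus(copies: list[str],
                    min_copies_for_consensus: int = 3) -> tuple[str, str]:
    """Majority-rule consensus, or the longest copy as representative.

    With at least ``min_copies_for_consensus`` copies, the copies are
    multiple-aligned (mafft when lengths differ) and a strict majority call
    is made per column: ties go to the first alphabetical base and
    gap-majority columns are dropped.  With fewer copies the longest copy is
    returned, labelled ``"representative"``.
    """
    if not copies:
        raise InvalidSpecError("build_consensus requires at least one copy")
    copies = [c.upper() for c in copies]
    if len(copies) < min_copies_for_consensus:
        return max(copies, key=len), "representative"
    if len(set(map(len, copies))) == 1:
        aligned = copies
    else:
        aligned = _run_mafft(copies)
    n = len(aligned)
    out = []
    for column in zip(*aligned):
        counts = Counter(column)
        if counts.get("-", 0) > n / 2:
            continue
        counts.pop("-", None)
        best = max(sorted(counts), key=lambda b: counts[b])
        out.append(best)
    return "".join(out), "consensus"


# ---------------------------------------------------------------------------
# Genome-level annotation pipeline


def annotate_genome(genome: str, seq_id: str = "seq",
                    motif_set: str = "sailor", min_protein_len: int = 300,
                    flank: int = 2000, min_tir_len: int = 18,
                    max_tir_len: int = 1500, min_identity: float = 0.8,
                    k_range: range = range(2, 11), intact_min_aa: int = 300,
                    max_mismatch: int = 1) -> list[TransposonElement]:
    """Mine, delimit and classify every transposon element in ``genome``."""
    elements: list[TransposonElement] = []
    seen: set[tuple[int, int]] = set()
    for locus in find_candidate_loci(genome, motif_set=motif_set,
                                     min_protein_len=min_protein_len,
                                     max_mismatch_per_motif=max_mismatch,
                                     seq_id=seq_id):
        locus_seq, locus_map = extract_locus(genome, locus.interval, flank)
        tir = find_tirs(locus_seq, min_tir_len=min_tir_len,
                        max_tir_len=max_tir_len, min_identity=min_identity,
                        seq_id=seq_id)

        # transposase protein: trim the stop-to-stop ORF to its first Met
        protein = locus.protein
        met = protein.find("M")
        if met > 0:
            protein = protein[met:]
            if locus.interval.strand == "+":
                orf = GenomicInterval(seq_id, locus.interval.start + 3 * met,
                                      locus.interval.end, "+")
            else:
                orf = GenomicInterval(seq_id, locus.interval.start,
                                      locus.interval.end - 3 * met, "-")
        else:
            orf = locus.interval
        triad = locate_triad(protein, motif_set, max_mismatch)

        if tir is not None:
            raw_start = locus_map.to_genome(tir.left.start)
            raw_end = locus_map.to_genome(tir.right.end)
            start, end, tsd = refine_element_boundaries(genome, raw_start,
                                                        raw_end, k_range,
                                                        seq_id)
            left_end = max(start + 1, locus_map.to_genome(tir.left.end))
            right_start = min(end - 1, locus_map.to_genome(tir.right.start))
            tir = TirPair(
                left=GenomicInterval(seq_id, start, left_end, "+"),
                right=GenomicInterval(seq_id, right_start, end, "+"),
                length=left_end - start,
                identity=tir.identity,
                alignment=tir.alignment)
            interval = GenomicInterval(seq_id, start, end,
                                       locus.interval.strand)
        else:
            tsd = None
            interval = GenomicInterval(seq_id, orf.start, orf.end,
                                       locus.interval.strand)

        if (interval.start, interval.end) in seen:
            continue
        seen.add((interval.start, interval.end))
        element = TransposonElement(interval=interval, tir=tir, tsd=tsd,
                                    orf=orf, protein=protein, triad=triad,
                                    element_id=f"element_{len(elements):04d}")
        classify_element(element, intact_min_aa)
        elements.append(element)
    elements.sort(key=lambda e: (e.interval.start, e.interval.end))
    for i, element in enumerate(elements):
        element.element_id = f"element_{i:04d}"
    return elements


def elements_to_gff3(elements: list[TransposonElement]) -> list[Gff3Record]:
    """Annotated elements as GFF3, mirroring the synthetic truth layout."""
    records = []
    for el in elements:
        iv = el.interval
        attrs = {"ID": el.element_id, "status": el.status,
                 "tir_length": str(el.tir_length)}
        if el.tsd:
            attrs["tsd"] = el.tsd.sequence
        records.append(Gff3Record(iv.seq_id, GFF_ELEMENT, iv.start + 1,
                                  iv.end, iv.strand, attributes=attrs))
        if el.tir:
            for part in (el.tir.left, el.tir.right):
                records.append(Gff3Record(iv.seq_id, GFF_TIR, part.start + 1,
                                          part.end, iv.strand,
                                          attributes={"Parent": el.element_id}))
        if el.tsd:
            for part in (el.tsd.upstream, el.tsd.downstream):
                records.append(Gff3Record(iv.seq_id, GFF_TSD, part.start + 1,
                                          part.end, "+",
                                          attributes={"Parent": el.element_id}))
    records.sort(key=lambda r: (r.start, r.type, r.end))
    return records


def elements_table(elements: list[TransposonElement]) -> pd.DataFrame:
    """One row per element: lengths, TIR length, TSD, signature, status."""
    rows = []
    for el in elements:
        rows.append({
            "element_id": el.element_id,
            "seq_id": el.interval.seq_id,
            "start": el.interval.start,
            "end": el.interval.end,
            "strand": el.interval.strand,
            "element_length": el.interval.length,
            "tir_length": el.tir_length,
            "tsd": el.tsd.sequence if el.tsd else "",
            "tpase_length": len(el.protein) if el.protein else 0,
            "signature": signature(el.triad) if el.triad else "",
            "status": el.status,
        })
    return pd.DataFrame(rows)
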
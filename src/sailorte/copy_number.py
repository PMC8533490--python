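"""Element copy counting under coverage/identity filters.

Copies of a consensus or representative element are located by exact k-mer
seeding on both strands followed by banded local alignment of the query
against each seeded genomic window, mirroring what a BLASTN search returns at
the scale this package operates on.  Counting applies the classic screen for
element copies: a hit counts when it covers more than 40% of the query length
at more than 80% identity (both strict).

Coverage is query coverage — the fraction of the representative copy's length
that aligns — and identity is computed over aligned columns excluding gap
columns, matching tabular BLAST semantics so externally produced hits are
interchangeable with internal ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .core import GenomicInterval, ParameterError, revcomp


@dataclass(frozen=True)
class CopyHit:
    """One genomic copy of the query element."""

    interval: GenomicInterval
    strand: str
    identity: float
    query_coverage: float
    score: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.query_coverage <= 1.0):
            raise ParameterError("identity and coverage must lie in [0, 1]")


def _search_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _seed_clusters(genome_index: dict[str, list[int]], query: str, seed_k: int,
                   max_span: int) -> list[tuple[int, int]]:
    """Cluster exact seed matches into candidate genomic windows."""
    matches = []  # (genome_pos, query_pos)
    for qpos in range(len(query) - seed_k + 1):
        for gpos in genome_index.get(query[qpos:qpos + seed_k], ()):
            matches.append((gpos, qpos))
    if not matches:
        return []
    # anchor each match at its implied copy start and cluster nearby anchors
    anchors = sorted(g - q for g, q in matches)
    clusters = []
    current = [anchors[0]]
    for a in anchors[1:]:
        if a - current[-1] <= max_span:
            current.append(a)
        else:
            clusters.append(current)
            current = [a]
    clusters.append(current)
    return [(min(c), max(c)) for c in clusters]


def _index_genome(genome: str, seed_k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for pos in range(len(genome) - seed_k + 1):
        index.setdefault(genome[pos:pos + seed_k], []).append(pos)
    return index


def search_copies(genome: str, query: str, seed_k: int = 12,
                  seq_id: str = "seq", pad: int = 100,
                  min_hit_span: int = 50) -> list[CopyHit]:
    """All copies of ``query`` in ``genome`` (both strands).

    Exact ``seed_k``-mers seed candidate windows which are then locally
    aligned; alignments spanning fewer than ``min_hit_span`` query bases
    (chance seed matches in background sequence) are discarded, overlapping
    hits keep the higher-scoring one, and hits on the same strand separated
    by < 50 bp are merged (fragmented copies of a single insertion).
    """
    if len(query) < seed_k:
        raise ParameterError("query shorter than seed_k")
    query = query.upper()
    genome = genome.upper()
    index = _index_genome(genome, seed_k)
    aligner = _search_aligner()

    raw_hits: list[CopyHit] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        for anchor_lo, anchor_hi in _seed_clusters(index, q, seed_k,
                                                   max_span=len(query) // 2):
            win_start = max(0, anchor_lo - pad)
            win_end = min(len(genome), anchor_hi + len(query) + pad)
            window = genome[win_start:win_end]
            alignments = aligner.align(window, q)
            try:
                best = next(iter(alignments))
            except (StopIteration, ValueError):
                continue
            g_blocks, q_blocks = best.aligned
            if len(g_blocks) == 0:
                continue
            matches = paired = 0
            for (g0, g1), (q0, q1) in zip(g_blocks, q_blocks):
                paired += g1 - g0
                matches += sum(1 for x, y in zip(window[g0:g1], q[q0:q1])
                               if x == y)
            if paired == 0:
                continue
            g_start = win_start + int(g_blocks[0][0])
            g_end = win_start + int(g_blocks[-1][1])
            q_aligned = int(q_blocks[-1][1]) - int(q_blocks[0][0])
            if q_aligned < min(min_hit_span, len(query)):
                continue
            raw_hits.append(CopyHit(
                interval=GenomicInterval(seq_id, g_start, g_end, strand),
                strand=strand,
                identity=matches / paired,
                query_coverage=min(1.0, q_aligned / len(query)),
                score=float(best.score)))

    # de-overlap: keep the higher-scoring hit for any overlapping region
    raw_hits.sort(key=lambda h: -h.score)
    kept: list[CopyHit] = []
    for hit in raw_hits:
        if any(hit.interval.overlaps(k.interval) for k in kept):
            continue
        kept.append(hit)

    # merge fragmented hits of one copy: same strand, < 50 bp apart
    kept.sort(key=lambda h: h.interval.start)
    merged: list[CopyHit] = []
    for hit in kept:
        if (merged and merged[-1].strand == hit.strand
                and hit.interval.start - merged[-1].interval.end < 50):
            prev = merged[-1]
            w_prev = prev.interval.length
            w_hit = hit.interval.length
            merged[-1] = CopyHit(
                interval=GenomicInterval(seq_id, prev.interval.start,
                                         hit.interval.end, hit.strand),
                strand=hit.strand,
                identity=(prev.identity * w_prev + hit.identity * w_hit)
                / (w_prev + w_hit),
                query_coverage=min(1.0, prev.query_coverage
                                   + hit.query_coverage),
                score=prev.score + hit.score)
        else:
            merged.append(hit)
    return merged


def count_copies(hits: list[CopyHit], min_coverage: float = 0.40,
                 min_identity: float = 0.80) -> int:
    """Copies passing the coverage/identity screen (strict inequalities)."""
    return sum(1 for h in hits
               if h.query_coverage > min_coverage and h.identity > min_identity)


def hits_table(hits: list[CopyHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "seq_id": h.interval.seq_id,
        "start": h.interval.start,
        "end": h.interval.end,
        "strand": h.strand,
        "identity": h.identity,
        "query_coverage": h.query_coverage,
        "score": h.score,
    } for h in hits])


def hits_bed(hits: list[CopyHit]) -> str:
    """Hits as BED (0-based half-open) text."""
    lines = [f"{h.interval.seq_id}\t{h.interval.start}\t{h.interval.end}"
             f"\tcopy_{i:04d}\t{h.score:.0f}\t{h.strand}"
             for i, h in enumerate(hits)]
    return "\n".join(lines) + ("\n" if lines else "")
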
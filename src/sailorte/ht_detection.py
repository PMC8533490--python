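"""Horizontal-transfer detection by pairwise genetic distance comparison.

The decision rule: for a species pair, horizontal transfer of the transposon
is supported when the transposase coding-sequence distance is strictly lower
than the distances of *both* L3 and L4 ribosomal-protein host genes, the
vertical-descent yardstick.  Distances are Tamura-Nei (TN93) estimates with
pairwise deletion (columns with a gap or ambiguity in either sequence are
excluded).  The composite-likelihood flavour of distance estimation is
approximated per the package's design: per-pair TN93 by default, plus an
optional pooled-parameter mode in which base frequencies are estimated
jointly over all pairs.

Host-gene choice follows the domain of the pair: prokaryote-involving pairs
use the organelle/prokaryotic L3/L4 set (prokaryotic ribosomal proteins are
homologous to eukaryote organelle ones); eukaryote-eukaryote pairs use the
cytoplasmic set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import log
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align

from .core import (ConfigurationError, InsufficientDataError, ParameterError,
                   SailorError)

logger = logging.getLogger(__name__)

MARKERS = ("TE", "L3", "L4")
GENE_CLASSES = ("organelle", "cytoplasmic", "prokaryotic", "na")


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class MarkerAlignmentSet:
    """Per-species coding sequences for one marker.

    ``aligned=True`` asserts the sequences are columns of one multiple
    alignment (all equal length); otherwise pairs are aligned on demand.
    """

    marker: str
    gene_class: str
    sequences: dict[str, str]
    aligned: bool = False

    def __post_init__(self):
        if self.marker not in MARKERS:
            raise ConfigurationError(f"unknown marker {self.marker!r}")
        if self.gene_class not in GENE_CLASSES:
            raise ConfigurationError(f"unknown gene class {self.gene_class!r}")
        if self.aligned and len({len(s) for s in self.sequences.values()}) > 1:
            raise ConfigurationError(
                f"{self.marker}/{self.gene_class}: aligned set has unequal "
                f"sequence lengths")


@dataclass(frozen=True)
class DistanceRecord:
    """A pairwise distance for one marker."""

    species_a: str
    species_b: str
    marker: str
    distance: float
    sites_used: int
    saturated: bool = False


@dataclass
class HTCall:
    """The three distances and the HT decision for one species pair."""

    species_a: str
    species_b: str
    d_te: float | None
    d_l3: float | None
    d_l4: float | None
    gene_class: str
    is_ht: bool | None            # None = untestable
    reason: str = ""


# ---------------------------------------------------------------------------
# Pairwise alignment


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    # affine convention: first gap residue costs 5, each further residue 1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def pairwise_align(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global alignment (match +1, mismatch -1, gap open -5, extend -1)."""
    if not seq_a or not seq_b:
        raise ParameterError("cannot align empty sequences")
    alignments = _global_aligner().align(seq_a.upper(), seq_b.upper())
    best = alignments[0]
    return str(best[0]), str(best[1])


# ---------------------------------------------------------------------------
# TN93 distance

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _pair_counts(aligned_a: str, aligned_b: str):
    """Usable-site counts after pairwise deletion.

    Returns (n, transitions_AG, transitions_CT, transversions, base_counts)
    where base_counts sums both sequences over used columns.
    """
    a = np.array([_CODE.get(c, -1) for c in aligned_a.upper()], dtype=np.int8)
    b = np.array([_CODE.get(c, -1) for c in aligned_b.upper()], dtype=np.int8)
    if a.shape != b.shape:
        raise ParameterError("aligned sequences must have equal length")
    used = (a >= 0) & (b >= 0)
    a, b = a[used], b[used]
    n = int(used.sum())
    purine_a, purine_b = (a == 0) | (a == 2), (b == 0) | (b == 2)
    diff = a != b
    p1 = int((diff & purine_a & purine_b).sum())            # A<->G
    p2 = int((diff & ~purine_a & ~purine_b).sum())          # C<->T
    q = int((diff & (purine_a != purine_b)).sum())          # transversions
    base_counts = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    return n, p1, p2, q, base_counts.astype(float)


def tn93_from_counts(n: int, p1_count: int, p2_count: int, q_count: int,
                     freqs: np.ndarray) -> float:
    """TN93 distance from site counts and base frequencies.

    Raises :class:`InsufficientDataError` when a log argument is
    non-positive (saturation) or a frequency class is empty.
    """
    g_a, g_c, g_g, g_t = freqs
    g_r, g_y = g_a + g_g, g_c + g_t
    if n <= 0:
        raise InsufficientDataError("no usable sites")
    if min(g_r, g_y) <= 0 or g_a * g_g <= 0 or g_c * g_t <= 0:
        raise InsufficientDataError("degenerate base composition")
    p1, p2, q = p1_count / n, p2_count / n, q_count / n
    k1 = 2 * g_a * g_g / g_r
    k2 = 2 * g_t * g_c / g_y
    k3 = 2 * (g_r * g_y - g_a * g_g * g_y / g_r - g_t * g_c * g_r / g_y)
    w1 = 1 - p1 / k1 - q / (2 * g_r)
    w2 = 1 - p2 / k2 - q / (2 * g_y)
    w3 = 1 - q / (2 * g_r * g_y)
    if min(w1, w2, w3) <= 0:
        raise SaturationError("TN93 log argument non-positive")
    return -k1 * log(w1) - k2 * log(w2) - k3 * log(w3)


class SaturationError(SailorError):
    """Distances saturated beyond the TN93 log domain."""


def tn93_distance(aligned_a: str, aligned_b: str, *,
                  species_a: str = "a", species_b: str = "b",
                  marker: str = "TE", min_sites: int = 100,
                  saturation_cap: float = 5.0,
                  freqs: np.ndarray | None = None) -> DistanceRecord:
    """Tamura-Nei (1993) distance with pairwise deletion.

    Base frequencies default to the pair's own empirical composition over the
    used columns; passing ``freqs`` enables the pooled-parameter mode.
    Saturated pairs are flagged and capped at ``saturation_cap`` rather than
    silently dropped.
    """
    n, p1, p2, q, base_counts = _pair_counts(aligned_a, aligned_b)
    if n < min_sites:
        raise InsufficientDataError(
            f"{species_a}/{species_b} ({marker}): only {n} usable sites "
            f"(< {min_sites})")
    if p1 + p2 + q == 0:
        return DistanceRecord(species_a, species_b, marker, 0.0, n)
    if freqs is None:
        freqs = base_counts / base_counts.sum()
    try:
        d = tn93_from_counts(n, p1, p2, q, np.asarray(freqs, dtype=float))
        saturated = False
    except SaturationError:
        d, saturated = saturation_cap, True
    return DistanceRecord(species_a, species_b, marker, d, n,
                          saturated=saturated)


def jc69_distance(aligned_a: str, aligned_b: str) -> float:
    """Jukes-Cantor distance (used as the uniform-limit cross-check)."""
    n, p1, p2, q, _ = _pair_counts(aligned_a, aligned_b)
    if n == 0:
        raise InsufficientDataError("no usable sites")
    p = (p1 + p2 + q) / n
    if p >= 0.75:
        raise SaturationError("JC69 saturated")
    return -0.75 * log(1 - 4 * p / 3)


# ---------------------------------------------------------------------------
# HT decision rule


def select_gene_class(domain_a: str, domain_b: str) -> str:
    """Host-gene set for a species pair, by domain of life.

    Prokaryote-eukaryote pairs use the organelle set (prokaryotic ribosomal
    proteins hit eukaryote organelle homologs); prokaryote-prokaryote pairs
    use the prokaryotic set (treated as organelle-homologous); pure
    eukaryote pairs use the cytoplasmic set.
    """
    domains = {domain_a, domain_b}
    if not domains <= {"prokaryote", "eukaryote"}:
        raise ConfigurationError(f"unknown domain label in {domains}")
    if domains == {"prokaryote"}:
        return "prokaryotic"
    if domains == {"eukaryote"}:
        return "cytoplasmic"
    return "organelle"


def ht_test(d_te: float | None, d_l3: float | None,
            d_l4: float | None) -> bool | None:
    """True iff the transposon distance is strictly lower than both host
    distances; ``None`` (untestable) when any distance is missing."""
    if d_te is None or d_l3 is None or d_l4 is None:
        return None
    return d_te < d_l3 and d_te < d_l4


# ---------------------------------------------------------------------------
# Pair scanning and aggregation


def _marker_lookup(sets: Iterable[MarkerAlignmentSet]):
    lookup: dict[tuple[str, str], MarkerAlignmentSet] = {}
    for ms in sets:
        key = (ms.marker, ms.gene_class)
        if key in lookup:
            raise ConfigurationError(f"duplicate marker set {key}")
        lookup[key] = ms
    return lookup


def _host_set(lookup, marker: str, gene_class: str) -> MarkerAlignmentSet | None:
    # prokaryote-prokaryote pairs fall back to the organelle-homologous set
    for cls in ((gene_class, "organelle") if gene_class == "prokaryotic"
                else (gene_class,)):
        if (marker, cls) in lookup:
            return lookup[(marker, cls)]
    return None


def _pair_distance(ms: MarkerAlignmentSet, a: str, b: str,
                   min_sites: int, freqs=None) -> DistanceRecord:
    seq_a, seq_b = ms.sequences[a], ms.sequences[b]
    if not ms.aligned and len(seq_a) != len(seq_b):
        seq_a, seq_b = pairwise_align(seq_a, seq_b)
    return tn93_distance(seq_a, seq_b, species_a=a, species_b=b,
                         marker=ms.marker, min_sites=min_sites, freqs=freqs)


def pooled_base_freqs(sets: Iterable[MarkerAlignmentSet]) -> np.ndarray:
    """Base frequencies pooled over every sequence of every set (the
    shared-parameter ingredient of composite-likelihood estimation)."""
    counts = np.zeros(4)
    for ms in sets:
        for seq in ms.sequences.values():
            codes = np.array([_CODE.get(c, -1) for c in seq.upper()])
            counts += np.bincount(codes[codes >= 0], minlength=4)
    if counts.sum() == 0:
        raise InsufficientDataError("no unambiguous bases in any set")
    return counts / counts.sum()


def scan_pairs(marker_sets: Iterable[MarkerAlignmentSet],
               species_meta: Mapping[str, tuple[str, str]] | pd.DataFrame,
               min_sites: int = 100,
               shared_params: bool = False
               ) -> tuple[list[HTCall], pd.DataFrame]:
    """Evaluate the HT rule over all unordered species pairs.

    ``species_meta`` maps species -> (domain, lineage) (or a DataFrame with
    ``species``, ``domain``, ``lineage`` columns).  Species missing any
    required marker are dropped with a logged reason; pairs whose distances
    cannot be computed (too few sites, saturation) are reported untestable.
    Returns the per-pair calls plus a lineage-by-lineage table counting
    HT-supporting pairs.
    """
    if isinstance(species_meta, pd.DataFrame):
        species_meta = {row["species"]: (row["domain"], row["lineage"])
                        for _, row in species_meta.iterrows()}
    lookup = _marker_lookup(marker_sets)
    te_sets = [ms for (m, _), ms in lookup.items() if m == "TE"]
    if not te_sets:
        raise ConfigurationError("no TE marker set provided")
    te_set = te_sets[0]
    freqs = pooled_base_freqs(lookup.values()) if shared_params else None

    species = []
    for sp in sorted(species_meta):
        if sp in te_set.sequences:
            species.append(sp)
        else:
            logger.info("dropping %s: no transposon sequence", sp)

    calls: list[HTCall] = []
    for a, b in itertools.combinations(species, 2):
        gene_class = select_gene_class(species_meta[a][0], species_meta[b][0])
        distances: dict[str, float | None] = {}
        reason = ""
        for marker in MARKERS:
            ms = te_set if marker == "TE" else _host_set(lookup, marker,
                                                         gene_class)
            if ms is None or a not in ms.sequences or b not in ms.sequences:
                distances[marker] = None
                reason = f"missing {marker} ({gene_class})"
                continue
            try:
                rec = _pair_distance(ms, a, b, min_sites, freqs)
            except InsufficientDataError as exc:
                distances[marker] = None
                reason = str(exc)
                continue
            if rec.saturated:
                distances[marker] = None
                reason = f"{marker} saturated"
            else:
                distances[marker] = rec.distance
        calls.append(HTCall(
            species_a=a, species_b=b,
            d_te=distances["TE"], d_l3=distances["L3"], d_l4=distances["L4"],
            gene_class=gene_class,
            is_ht=ht_test(distances["TE"], distances["L3"], distances["L4"]),
            reason=reason))

    rows = []
    for call in calls:
        if call.is_ht:
            lin = sorted((species_meta[call.species_a][1],
                          species_meta[call.species_b][1]))
            rows.append({"lineage_a": lin[0], "lineage_b": lin[1]})
    if rows:
        agg = (pd.DataFrame(rows).value_counts().rename("supporting_pairs")
               .reset_index())
    else:
        agg = pd.DataFrame(columns=["lineage_a", "lineage_b",
                                    "supporting_pairs"])
    return calls, agg


def calls_table(calls: list[HTCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "species_a": c.species_a, "species_b": c.species_b,
        "d_te": c.d_te, "d_l3": c.d_l3, "d_l4": c.d_l4,
        "gene_class": c.gene_class,
        "is_ht": "" if c.is_ht is None else str(bool(c.is_ht)),
        "reason": c.reason,
    } for c in calls])


def distance_matrix(ms: MarkerAlignmentSet, min_sites: int = 100) -> pd.DataFrame:
    """Square distance matrix (PHYLIP-style layout when written as TSV)."""
    species = sorted(ms.sequences)
    mat = pd.DataFrame(0.0, index=species, columns=species)
    for a, b in itertools.combinations(species, 2):
        rec = _pair_distance(ms, a, b, min_sites)
        mat.loc[a, b] = mat.loc[b, a] = rec.distance
    return mat


# ---------------------------------------------------------------------------
# Host-gene ranking


def _protein_identity(seq_a: str, seq_b: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    best = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a_blocks, b_blocks = best.aligned
    matches = paired = 0
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        paired += a1 - a0
        matches += sum(1 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]) if x == y)
    return matches / paired if paired else 0.0


def rank_host_genes(families: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    """Rank candidate host-gene families by conservation then length.

    Families are sorted by mean pairwise protein identity (descending), ties
    broken by mean sequence length (descending) — conserved, long, widely
    distributed single-copy genes make the best vertical-descent yardsticks.
    Families with fewer than two species are skipped with a warning.
    """
    rows = []
    for name, seqs in families.items():
        if len(seqs) < 2:
            logger.warning("family %s has < 2 species; skipped", name)
            continue
        identities = [_protein_identity(x, y) for x, y in
                      itertools.combinations(seqs.values(), 2)]
        rows.append({
            "family": name,
            "mean_identity": float(np.mean(identities)),
            "mean_length": float(np.mean([len(s) for s in seqs.values()])),
            "n_species": len(seqs),
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table = (table.sort_values(["mean_identity", "mean_length"],
                                   ascending=False)
                 .reset_index(drop=True))
    return table
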
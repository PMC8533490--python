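"""Synthetic genomes and marker sets with machine-readable ground truth.

Two generators live here:

* element/genome fixtures — transposase proteins with catalytic triads placed
  by construction, full elements (TIR + UTR + ORF + UTR + TIR), and background
  genomes with planted, optionally degraded copies flanked by target-site
  duplications.  Every planting emits a truth table so downstream annotation
  and copy counting can be scored exactly.

* marker-set simulation — L3/L4 host-gene and transposase coding sequences
  evolved along an ultrametric species tree under an HKY substitution process,
  with optional horizontal-transfer events that replace the recipient's
  transposon lineage by the donor's at a given transfer time.  The truth table
  lists which species pairs are HT-positive by construction.

Identifiability guards: the single base just inside and just outside each
planted element terminus is forced to be non-self-complementary across the
element, so that on zero-degradation fixtures the inverted-repeat boundaries
(and hence the truth GFF3) are exactly recoverable.  This perturbs the i.i.d.
background at two bases per insertion and is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .core import (CapacityError, InvalidSpecError, derive_seed, random_dna,
                   random_protein, revcomp, reverse_translate)
from .dde_signature import CatalyticTriad, get_motif_set
from .io import GFF_ELEMENT, GFF_TIR, GFF_TSD, Gff3Record

# ---------------------------------------------------------------------------
# Element specification


@dataclass(frozen=True)
class ElementSpec:
    """Blueprint for one synthetic transposon element.

    Spacer counts are exclusive: ``de_spacer`` is the number of residues
    strictly between the second catalytic D and the E, so the default 82
    yields a DD82E transposase.
    """

    tir_length: int = 30
    tir_seq: str | None = None
    tsd_seq: str = "TATA"
    dd_spacer: int = 90
    de_spacer: int = 82
    orf_length: int = 400
    motif_set: str = "sailor"
    utr5_length: int = 200
    utr3_length: int = 200

    def __post_init__(self):
        if self.tir_length < 4:
            raise InvalidSpecError("tir_length must be >= 4")
        if self.tir_seq is not None and len(self.tir_seq) != self.tir_length:
            raise InvalidSpecError("tir_seq length disagrees with tir_length")
        if not 2 <= len(self.tsd_seq) <= 10:
            raise InvalidSpecError("tsd_seq length must be in [2, 10]")
        if self.de_spacer < 1:
            raise InvalidSpecError("de_spacer must be >= 1")
        ms = get_motif_set(self.motif_set)
        # residues contributed by the motifs themselves between the anchors
        dd_inside = (ms.d1.span - ms.d1.anchor - 1) + ms.d2.anchor
        de_inside = (ms.d2.span - ms.d2.anchor - 1) + ms.e.anchor
        if self.dd_spacer < dd_inside:
            raise InvalidSpecError(
                f"dd_spacer {self.dd_spacer} shorter than the {dd_inside} "
                f"residues contributed by the motifs")
        if self.de_spacer < de_inside:
            raise InvalidSpecError(
                f"de_spacer {self.de_spacer} shorter than the {de_inside} "
                f"residues contributed by the motifs")
        if self.orf_length < self.dd_spacer + self.de_spacer + ms.total_span:
            raise InvalidSpecError("orf_length too short for spacers plus motifs")


@dataclass(frozen=True)
class DegradationSpec:
    """Per-copy degradation applied at planting time."""

    substitution_rate: float = 0.0
    truncation_prob: float = 0.0
    truncation_frac_range: tuple[float, float] = (0.2, 0.6)

    def __post_init__(self):
        for value in (self.substitution_rate, self.truncation_prob,
                      *self.truncation_frac_range):
            if not 0.0 <= value <= 1.0:
                raise InvalidSpecError("degradation rates must lie in [0, 1]")
        if self.truncation_frac_range[0] > self.truncation_frac_range[1]:
            raise InvalidSpecError("truncation_frac_range min > max")


NO_DEGRADATION = DegradationSpec()


# ---------------------------------------------------------------------------
# Transposase and element construction


def _sample_motif(motif, rng: np.random.Generator) -> str:
    """One concrete realization of a positional motif (alternatives resolved)."""
    return "".join(sorted(allowed)[rng.integers(0, len(allowed))]
                   for allowed in motif.positions)


def make_transposase(spec: ElementSpec, seed: int) -> tuple[str, CatalyticTriad]:
    """Synthesize a transposase protein with the triad placed by construction.

    The three consensus motifs of ``spec.motif_set`` are embedded verbatim
    (alternative positions resolved reproducibly from ``seed``) with exactly
    ``dd_spacer`` residues between D1 and D2 and ``de_spacer`` between D2 and
    E.  Filler residues are drawn i.i.d. from the 20 amino acids.
    """
    rng = np.random.default_rng(derive_seed(seed, 1))
    ms = get_motif_set(spec.motif_set)
    m1, m2, m3 = (_sample_motif(m, rng) for m in ms.motifs)
    fill_dd = spec.dd_spacer - (ms.d1.span - ms.d1.anchor - 1) - ms.d2.anchor
    fill_de = spec.de_spacer - (ms.d2.span - ms.d2.anchor - 1) - ms.e.anchor
    occupied = ms.total_span + fill_dd + fill_de
    flex = spec.orf_length - occupied
    if flex < 1:
        raise InvalidSpecError("orf_length leaves no room for the N-terminus")
    c_term_len = flex // 4
    n_term_len = flex - c_term_len
    protein = ("M" + random_protein(n_term_len - 1, rng)
               + m1 + random_protein(fill_dd, rng)
               + m2 + random_protein(fill_de, rng)
               + m3 + random_protein(c_term_len, rng))
    d1 = n_term_len + ms.d1.anchor
    triad = CatalyticTriad(
        d1_pos=d1,
        d2_pos=d1 + 1 + spec.dd_spacer,
        e_pos=d1 + 1 + spec.dd_spacer + 1 + spec.de_spacer,
        motif_mismatches=0,
        motif_set=spec.motif_set,
        e_residue=protein[d1 + 1 + spec.dd_spacer + 1 + spec.de_spacer],
    )
    assert len(protein) == spec.orf_length
    return protein, triad


@dataclass(frozen=True)
class ElementTruth:
    """Ground truth for one master element."""

    spec: ElementSpec
    protein: str
    triad: CatalyticTriad
    tir_seq: str
    orf_start: int          # element-local, 0-based
    orf_end: int            # element-local, half-open (includes stop codon)


def make_element(spec: ElementSpec, seed: int) -> tuple[str, ElementTruth]:
    """Build a full element: 5'TIR + UTR + ORF + UTR + 3'TIR.

    The 3' TIR is the reverse complement of the 5' TIR; the default 5' TIR
    begins with the GT dinucleotide typical of Sailor ends.  The TSD is *not*
    part of the element — it is host sequence duplicated at planting.
    """
    rng = np.random.default_rng(derive_seed(seed, 2))
    protein, triad = make_transposase(spec, seed)
    orf_nt = reverse_translate(protein)
    if spec.tir_seq is not None:
        tir = spec.tir_seq.upper()
    else:
        tir = "GT" + random_dna(spec.tir_length - 2, rng)
    utr5 = random_dna(spec.utr5_length, rng)
    utr3 = random_dna(spec.utr3_length, rng)
    # identifiability guard: the first UTR5 base must not pair with the last
    # UTR3 base in an inverted-repeat alignment, so detected TIRs end exactly
    # at the planted TIR termini.
    if utr5 and utr3 and utr5[0] == revcomp(utr3[-1]):
        utr3 = utr3[:-1] + {"A": "C", "C": "A", "G": "T", "T": "G"}[utr3[-1]]
    element = tir + utr5 + orf_nt + utr3 + revcomp(tir)
    orf_start = len(tir) + len(utr5)
    truth = ElementTruth(spec=spec, protein=protein, triad=triad, tir_seq=tir,
                         orf_start=orf_start, orf_end=orf_start + len(orf_nt))
    return element, truth


# ---------------------------------------------------------------------------
# Planting copies into a background genome


@dataclass
class PlantedGenome:
    """A background genome with planted copies and their truth table."""

    seq_id: str
    sequence: str
    truth: pd.DataFrame      # one row per planted copy
    element: str             # master element sequence
    tsd: str
    tir_length: int

    def truth_gff3(self) -> list[Gff3Record]:
        return truth_to_gff3(self.truth, self.seq_id, self.tir_length,
                             len(self.tsd))


def _degrade(element: str, degradation: DegradationSpec,
             rng: np.random.Generator) -> tuple[str, float, float, bool, bool]:
    """Apply truncation then substitutions; return (seq, identity, coverage,
    left_end_intact, right_end_intact)."""
    seq = element
    kept_start, kept_end = 0, len(element)
    if degradation.truncation_prob > 0 and rng.random() < degradation.truncation_prob:
        lo, hi = degradation.truncation_frac_range
        frac = rng.uniform(lo, hi)
        cut = int(round(frac * len(element)))
        cut = min(cut, len(element) - 1)
        if rng.random() < 0.5:
            kept_start = cut
        else:
            kept_end = len(element) - cut
        seq = element[kept_start:kept_end]
    n_sub = 0
    if degradation.substitution_rate > 0 and len(seq) > 0:
        n_sub = rng.binomial(len(seq), degradation.substitution_rate)
        positions = rng.choice(len(seq), size=n_sub, replace=False)
        chars = list(seq)
        for pos in positions:
            alternatives = [b for b in "ACGT" if b != chars[pos]]
            chars[pos] = alternatives[rng.integers(0, 3)]
        seq = "".join(chars)
    coverage = len(seq) / len(element)
    identity = 1.0 - n_sub / len(seq) if seq else 0.0
    return seq, identity, coverage, kept_start == 0, kept_end == len(element)


def plant_copies(genome_length: int, element: str, n: int,
                 tsd: str = "TATA",
                 degradation: DegradationSpec = NO_DEGRADATION,
                 seed: int = 0,
                 strand: str = "random",
                 seq_id: str = "chr_sim",
                 tir_length: int = 30,
                 edge_margin: int = 2500,
                 min_gap: int = 3000) -> PlantedGenome:
    """Plant ``n`` copies of ``element`` into a random background genome.

    Each copy is flanked by the duplicated ``tsd`` on both sides; insertion
    sites are non-overlapping, at least ``min_gap`` apart and ``edge_margin``
    from the genome ends (so 2-kb flank extraction never clips).  The truth
    table records, per copy, the element interval in final genome coordinates
    (TSDs excluded), strand, percent identity to the master element and
    coverage fraction after truncation.
    """
    if n < 0:
        raise InvalidSpecError("n must be >= 0")
    if strand not in ("random", "+", "-"):
        raise InvalidSpecError("strand must be 'random', '+' or '-'")
    rng = np.random.default_rng(derive_seed(seed, 3))
    background = list(random_dna(genome_length, rng))

    rows = []
    if n == 0:
        genome = "".join(background)
        truth = pd.DataFrame(columns=["copy_id", "start", "end", "strand",
                                      "identity", "coverage", "left_tir",
                                      "right_tir"])
        return PlantedGenome(seq_id, genome, truth, element, tsd, tir_length)

    available = genome_length - 2 * edge_margin - (n - 1) * min_gap
    if available < 0:
        raise CapacityError(
            f"genome of {genome_length} bp cannot host {n} copies with "
            f"{min_gap} bp spacing and {edge_margin} bp margins")
    offsets = np.sort(rng.uniform(0, available, size=n))
    sites = [int(edge_margin + off + i * min_gap) for i, off in enumerate(offsets)]

    inserts = []
    for i, pos in enumerate(sites):
        seq, identity, coverage, left_ok, right_ok = _degrade(element, degradation, rng)
        copy_strand = strand if strand != "random" else ("+-"[rng.integers(0, 2)])
        if copy_strand == "-":
            seq = revcomp(seq)
            left_ok, right_ok = right_ok, left_ok
        # junction guard: four background bases on each side of the insertion
        # site are fixed to distinct non-complementary letters so that neither
        # a spurious inverted-repeat extension nor a chance flanking
        # duplication can straddle the junction.
        for off in range(1, 5):
            background[pos - off] = "C"
            background[pos + off - 1] = "A"
        inserts.append((pos, seq, copy_strand, identity, coverage,
                        left_ok, right_ok))

    parts, cursor, shift = [], 0, 0
    for i, (pos, seq, copy_strand, identity, coverage, left_ok, right_ok) in enumerate(inserts):
        parts.append("".join(background[cursor:pos]))
        start = pos + shift + len(tsd)
        parts.append(tsd + seq + tsd)
        rows.append({
            "copy_id": f"copy_{i:04d}",
            "start": start,
            "end": start + len(seq),
            "strand": copy_strand,
            "identity": identity,
            "coverage": coverage,
            "left_tir": left_ok,
            "right_tir": right_ok,
        })
        shift += 2 * len(tsd) + len(seq)
        cursor = pos
    parts.append("".join(background[cursor:]))
    genome = "".join(parts)
    truth = pd.DataFrame(rows)
    return PlantedGenome(seq_id, genome, truth, element, tsd, tir_length)


def truth_to_gff3(truth: pd.DataFrame, seq_id: str, tir_length: int,
                  tsd_length: int) -> list[Gff3Record]:
    """Truth table rendered as GFF3 records (1-based inclusive)."""
    records = []
    for _, row in truth.iterrows():
        start, end = int(row["start"]), int(row["end"])
        attrs = {"ID": row["copy_id"],
                 "identity": f"{row['identity']:.4f}",
                 "coverage": f"{row['coverage']:.4f}"}
        records.append(Gff3Record(seq_id, GFF_ELEMENT, start + 1, end,
                                  row["strand"], attributes=attrs))
        if bool(row["left_tir"]):
            records.append(Gff3Record(seq_id, GFF_TIR, start + 1,
                                      start + tir_length, row["strand"],
                                      attributes={"Parent": row["copy_id"]}))
        if bool(row["right_tir"]):
            records.append(Gff3Record(seq_id, GFF_TIR, end - tir_length + 1,
                                      end, row["strand"],
                                      attributes={"Parent": row["copy_id"]}))
        for tsd_start in (start - tsd_length, end):
            records.append(Gff3Record(seq_id, GFF_TSD, tsd_start + 1,
                                      tsd_start + tsd_length, "+",
                                      attributes={"Parent": row["copy_id"]}))
    records.sort(key=lambda r: (r.start, r.type, r.end))
    return records


# ---------------------------------------------------------------------------
# Marker-set simulation along a species tree


@dataclass(frozen=True)
class HTScenario:
    """A species tree plus rate scales and optional horizontal transfers.

    ``tree`` is a rooted, ultrametric newick string with branch lengths in
    expected substitutions/site (at rate scale 1).  ``ht_events`` are
    ``(donor, recipient, transfer_time)`` triples with the transfer time
    measured backwards from the present (same units as branch lengths);
    the recipient's transposon lineage is replaced by the donor's at that
    time.  ``te_rate_scale`` defaults to 2.0: transposons evolve essentially
    neutrally, faster than the strongly conserved ribosomal-protein host
    genes, which is the regime in which distance-based HT detection is
    meaningful.
    """

    tree: str
    host_rate_scale: float = 1.0
    te_rate_scale: float = 2.0
    ht_events: tuple[tuple[str, str, float], ...] = ()
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.host_rate_scale <= 0 or self.te_rate_scale <= 0:
            raise InvalidSpecError("rate scales must be > 0")
        if self.kappa <= 0:
            raise InvalidSpecError("kappa must be > 0")


@dataclass
class SimulatedMarkers:
    """Per-species sequences for TE, L3 and L4 plus the HT truth table."""

    species: list[str]
    markers: dict[str, dict[str, str]]       # marker -> species -> sequence
    ht_truth: set[frozenset]                 # HT-positive unordered pairs
    species_tree: str
    te_tree: str
    aligned: bool = True


def _parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise InvalidSpecError("tree must have >= 2 leaves")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise InvalidSpecError("tree must have branch lengths everywhere")
    return tree


def _node_ages(tree: dendropy.Tree, tol: float = 1e-6) -> dict:
    """Ages (time before present) of all nodes; requires ultrametricity."""
    ages = {}

    def walk(node):
        if node.is_leaf():
            ages[node] = 0.0
            return 0.0
        child_ages = []
        for child in node.child_nodes():
            walk(child)
            child_ages.append(ages[child] + (child.edge.length or 0.0))
        if max(child_ages) - min(child_ages) > tol + 1e-9 * max(1.0, max(child_ages)):
            raise InvalidSpecError("HT scenarios require an ultrametric tree")
        ages[node] = float(np.mean(child_ages))
        return ages[node]

    walk(tree.seed_node)
    return ages


def _leaf_by_label(tree: dendropy.Tree, label: str):
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == label:
            return leaf
    raise InvalidSpecError(f"species {label!r} not in tree")


def _apply_ht_event(tree: dendropy.Tree, donor: str, recipient: str,
                    transfer_time: float) -> None:
    """Regraft the recipient leaf onto the donor lineage at ``transfer_time``."""
    ages = _node_ages(tree)
    donor_leaf = _leaf_by_label(tree, donor)
    recipient_leaf = _leaf_by_label(tree, recipient)
    # validate the transfer time against the pair's divergence
    node = donor_leaf
    path = {node}
    while node.parent_node is not None:
        node = node.parent_node
        path.add(node)
    node = recipient_leaf
    while node not in path:
        node = node.parent_node
    mrca_age = ages[node]
    if not 0.0 <= transfer_time < mrca_age:
        raise InvalidSpecError(
            f"transfer_time {transfer_time} outside (0, divergence "
            f"{mrca_age:.6g}) of {donor}/{recipient}")

    # detach the recipient leaf, splicing out its (now unary) parent
    parent = recipient_leaf.parent_node
    parent.remove_child(recipient_leaf)
    if len(parent.child_nodes()) == 1 and parent.parent_node is not None:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        only.edge.length += parent.edge.length
        grand.remove_child(parent)
        grand.add_child(only)
    ages = _node_ages(tree)

    # find the donor-lineage edge spanning transfer_time and bisect it
    node = donor_leaf
    while node.parent_node is not None and ages[node.parent_node] <= transfer_time:
        node = node.parent_node
    parent = node.parent_node
    if parent is None:
        raise InvalidSpecError("transfer_time older than the donor lineage root")
    mid = dendropy.Node()
    parent.remove_child(node)
    parent.add_child(mid)
    mid.edge.length = ages[parent] - transfer_time
    mid.add_child(node)
    node.edge.length = transfer_time - ages[node]
    mid.add_child(recipient_leaf)
    recipient_leaf.edge.length = transfer_time


def _hky_transition(kappa: float, freqs: np.ndarray, t: float) -> np.ndarray:
    """HKY85 transition-probability matrix for branch length ``t`` (expected
    substitutions/site), base order A, C, G, T."""
    a, c, g, u = freqs
    rates = np.array([
        [0, c, kappa * g, u],
        [a, 0, g, kappa * u],
        [kappa * a, c, 0, u],
        [a, kappa * c, g, 0],
    ], dtype=float)
    q = rates.copy()
    np.fill_diagonal(q, -rates.sum(axis=1))
    mean_rate = -(freqs * np.diag(q)).sum()
    q /= mean_rate
    return expm(q * t)


def _evolve_along_tree(tree: dendropy.Tree, length: int, kappa: float,
                       freqs: np.ndarray, scale: float,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Simulate site-independent evolution; returns leaf sequences as codes."""
    cache: dict[float, np.ndarray] = {}

    def transition(t: float) -> np.ndarray:
        key = round(t, 12)
        if key not in cache:
            cache[key] = np.cumsum(_hky_transition(kappa, freqs, t), axis=1)
        return cache[key]

    root_seq = rng.choice(4, size=length, p=freqs)
    sequences = {tree.seed_node: root_seq}
    leaves = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = sequences[node.parent_node]
        t = (node.edge.length or 0.0) * scale
        if t == 0.0:
            child_seq = parent_seq.copy()
        else:
            cum = transition(t)
            u = rng.random(length)
            child_seq = (u[:, None] > cum[parent_seq]).sum(axis=1).astype(np.int64)
        sequences[node] = child_seq
        if node.is_leaf():
            leaves[node.taxon.label] = child_seq
    return leaves


_BASES = np.array(list("ACGT"))


def simulate_marker_set(scenario: HTScenario,
                        marker_length: int = 10_000,
                        base_freqs: tuple[float, float, float, float] =
                        (0.25, 0.25, 0.25, 0.25)) -> SimulatedMarkers:
    """Evolve L3, L4 and TE sequences along the scenario's species tree.

    Host genes follow the species tree at ``host_rate_scale``; the transposon
    follows a copy of the tree modified by the HT events at
    ``te_rate_scale``.  Sequences are substitution-only, hence returned
    aligned.  The truth table flags every unordered pair whose TE-tree
    patristic divergence is smaller than its species-tree divergence.
    """
    freqs = np.asarray(base_freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9 or (freqs <= 0).any():
        raise InvalidSpecError("base_freqs must be positive and sum to 1")

    species_tree = _parse_tree(scenario.tree)
    te_tree = _parse_tree(scenario.tree)
    if scenario.ht_events:
        _node_ages(te_tree)  # enforce ultrametricity up front
        for donor, recipient, t in scenario.ht_events:
            _apply_ht_event(te_tree, donor, recipient, t)

    species = sorted(leaf.taxon.label for leaf in species_tree.leaf_node_iter())

    def patristic(tree):
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        return {frozenset((a, b)): pdm.patristic_distance(taxa[a], taxa[b])
                for i, a in enumerate(species) for b in species[i + 1:]}

    d_species = patristic(species_tree)
    d_te = patristic(te_tree)
    ht_truth = {pair for pair in d_species
                if d_te[pair] < d_species[pair] * (1 - 1e-9)}

    markers = {}
    for i, (marker, scale_attr) in enumerate(
            [("L3", "host_rate_scale"), ("L4", "host_rate_scale"),
             ("TE", "te_rate_scale")]):
        rng = np.random.default_rng(derive_seed(scenario.seed, 10 + i))
        tree = te_tree if marker == "TE" else species_tree
        leaves = _evolve_along_tree(tree, marker_length, scenario.kappa,
                                    freqs, getattr(scenario, scale_attr), rng)
        markers[marker] = {sp: "".join(_BASES[leaves[sp]]) for sp in species}

    return SimulatedMarkers(
        species=species, markers=markers, ht_truth=ht_truth,
        species_tree=species_tree.as_string(schema="newick").strip(),
        te_tree=te_tree.as_string(schema="newick").strip())
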
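"""Catalytic-triad (DDE/D) location and DDxE signature classification.

IS630-Tc1-mariner transposases carry three acidic catalytic residues (D, D,
E or D).  Families are told apart by the number of residues *strictly
between* the second D and the terminal E/D — the "x" of the DDxE signature —
so DD82E means exactly 82 intervening residues.  The triad is located by
anchored motif scanning: each catalytic residue sits at a fixed position
inside a short conserved consensus motif (for the Sailor superfamily:
[I/V]VYLDET around D1, VIIMDNA around D2 and HCELNPIEL around E; for
Tc1/mariner: VLWSDES, IFQQDNA/D and SPDLNPIEN).  Motif tables are shipped as
a plain-text resource and are extensible.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .core import ConfigurationError

# ---------------------------------------------------------------------------
# Motif tables


@dataclass(frozen=True)
class Motif:
    """A positional consensus motif with a catalytic anchor position."""

    name: str
    positions: tuple[frozenset, ...]   # accepted residues per position
    anchor: int                        # 0-based index of the catalytic residue
    anchor_residues: frozenset         # residues accepted at the anchor

    @property
    def span(self) -> int:
        return len(self.positions)

    def mismatches(self, window: str) -> int:
        """Mismatch count of a window of length ``span`` against the motif."""
        return sum(1 for aa, allowed in zip(window, self.positions)
                   if aa not in allowed)


@dataclass(frozen=True)
class MotifSet:
    name: str
    d1: Motif
    d2: Motif
    e: Motif

    @property
    def motifs(self) -> tuple[Motif, Motif, Motif]:
        return (self.d1, self.d2, self.e)

    @property
    def total_span(self) -> int:
        return self.d1.span + self.d2.span + self.e.span


def _parse_pattern(pattern: str) -> tuple[frozenset, ...]:
    positions, i = [], 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            positions.append(frozenset(pattern[i + 1:j]))
            i = j + 1
        else:
            positions.append(frozenset(pattern[i]))
            i += 1
    return tuple(positions)


def _load_motif_sets() -> dict[str, MotifSet]:
    text = resources.files("sailorte.data").joinpath("motifs.tsv").read_text()
    rows: dict[str, dict[str, Motif]] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("motif_set\t"):
            continue
        set_name, slot, pattern, anchor, anchor_res = line.split("\t")
        motif = Motif(name=f"{set_name}:{slot}",
                      positions=_parse_pattern(pattern),
                      anchor=int(anchor),
                      anchor_residues=frozenset(anchor_res))
        rows.setdefault(set_name, {})[slot] = motif
    sets = {}
    for set_name, slots in rows.items():
        missing = {"d1", "d2", "e"} - slots.keys()
        if missing:
            raise ConfigurationError(f"motif set {set_name!r} missing slots {missing}")
        sets[set_name] = MotifSet(set_name, slots["d1"], slots["d2"], slots["e"])
    return sets


MOTIF_SETS: dict[str, MotifSet] = _load_motif_sets()


def get_motif_set(name: str) -> MotifSet:
    try:
        return MOTIF_SETS[name]
    except KeyError:
        raise ConfigurationError(f"unknown motif set {name!r}") from None


# ---------------------------------------------------------------------------
# Triad types and scanning


@dataclass(frozen=True)
class CatalyticTriad:
    """Residue indices of the catalytic triad plus bookkeeping.

    Spacers use the exclusive convention throughout the package:
    ``dd_spacer = d2_pos - d1_pos - 1`` and ``de_spacer = e_pos - d2_pos - 1``.
    """

    d1_pos: int
    d2_pos: int
    e_pos: int
    motif_mismatches: int
    motif_set: str
    e_residue: str = "E"

    def __post_init__(self):
        if not self.d1_pos < self.d2_pos < self.e_pos:
            raise ConfigurationError("triad positions must be strictly increasing")

    @property
    def dd_spacer(self) -> int:
        return self.d2_pos - self.d1_pos - 1

    @property
    def de_spacer(self) -> int:
        return self.e_pos - self.d2_pos - 1


@dataclass(frozen=True)
class TriadCandidate:
    """An ordered co-occurrence of the three motifs in one protein."""

    motif_set: str
    starts: tuple[int, int, int]          # motif start positions
    anchors: tuple[int, int, int]         # catalytic residue positions
    mismatches: tuple[int, int, int]

    @property
    def total_mismatches(self) -> int:
        return sum(self.mismatches)


def motif_matches(protein: str, motif: Motif, max_mismatch: int):
    """All (start, mismatches) windows matching ``motif`` within tolerance."""
    out = []
    for start in range(len(protein) - motif.span + 1):
        mm = motif.mismatches(protein[start:start + motif.span])
        if mm <= max_mismatch:
            out.append((start, mm))
    return out


def scan_triads(protein: str, motif_set: str,
                max_mismatch_per_motif: int = 1) -> list[TriadCandidate]:
    """Ordered triples of motif hits, ranked by total mismatches then position.

    Anchor residues are *not* checked here; :func:`locate_triad` enforces the
    D/D/E identity so that near-miss candidates remain visible to callers that
    want them (e.g. degraded-copy diagnostics).
    """
    ms = get_motif_set(motif_set)
    hits = [motif_matches(protein, m, max_mismatch_per_motif) for m in ms.motifs]
    candidates = []
    for s1, mm1 in hits[0]:
        a1 = s1 + ms.d1.anchor
        for s2, mm2 in hits[1]:
            a2 = s2 + ms.d2.anchor
            if a2 <= a1:
                continue
            for s3, mm3 in hits[2]:
                a3 = s3 + ms.e.anchor
                if a3 <= a2:
                    continue
                candidates.append(TriadCandidate(
                    motif_set=motif_set, starts=(s1, s2, s3),
                    anchors=(a1, a2, a3), mismatches=(mm1, mm2, mm3)))
    candidates.sort(key=lambda c: (c.total_mismatches, c.anchors[0]))
    return candidates


def locate_triad(protein: str, motif_set: str = "sailor",
                 max_mismatch: int = 1) -> CatalyticTriad | None:
    """Best anchored catalytic triad of ``protein``, or ``None``.

    A candidate is accepted only if the residues at the three anchor
    positions are the catalytic D, D and E (or D, for DDxD motif sets),
    regardless of the mismatch budget spent elsewhere in the motifs.
    """
    ms = get_motif_set(motif_set)
    for cand in scan_triads(protein, motif_set, max_mismatch):
        a1, a2, a3 = cand.anchors
        if (protein[a1] in ms.d1.anchor_residues
                and protein[a2] in ms.d2.anchor_residues
                and protein[a3] in ms.e.anchor_residues):
            return CatalyticTriad(
                d1_pos=a1, d2_pos=a2, e_pos=a3,
                motif_mismatches=cand.total_mismatches,
                motif_set=motif_set, e_residue=protein[a3])
    return None


def signature(triad: CatalyticTriad) -> str:
    """DDxE/D signature string, e.g. ``DD82E``."""
    return f"DD{triad.de_spacer}{triad.e_residue}"


# ---------------------------------------------------------------------------
# Superfamily assignment


@dataclass(frozen=True)
class SuperfamilyRule:
    name: str
    spacer_min: int
    spacer_max: int
    motif_set: str

    def __post_init__(self):
        if self.spacer_min > self.spacer_max:
            raise ConfigurationError(
                f"rule {self.name}: spacer_min > spacer_max")


def _load_rules() -> tuple[SuperfamilyRule, ...]:
    text = resources.files("sailorte.data").joinpath("superfamily_rules.tsv").read_text()
    rules = []
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, motif_set, lo, hi = line.split("\t")
        rules.append(SuperfamilyRule(name, int(lo), int(hi), motif_set))
    return tuple(rules)


DEFAULT_RULES: tuple[SuperfamilyRule, ...] = _load_rules()


def _check_rules(rules) -> None:
    by_set: dict[str, list[SuperfamilyRule]] = {}
    for rule in rules:
        by_set.setdefault(rule.motif_set, []).append(rule)
    for group in by_set.values():
        group = sorted(group, key=lambda r: r.spacer_min)
        for a, b in zip(group, group[1:]):
            if b.spacer_min <= a.spacer_max:
                raise ConfigurationError(
                    f"overlapping rules {a.name} and {b.name} for motif set "
                    f"{a.motif_set!r}")


def assign_superfamily(triad: CatalyticTriad,
                       rules=DEFAULT_RULES) -> str:
    """Superfamily name whose spacer range covers the triad, or "unassigned"."""
    _check_rules(rules)
    for rule in rules:
        if (rule.motif_set == triad.motif_set
                and rule.spacer_min <= triad.de_spacer <= rule.spacer_max):
            return rule.name
    return "unassigned"
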
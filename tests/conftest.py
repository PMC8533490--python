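"""Shared fixtures and independent oracles for the test suite.

The oracle functions here are deliberately simple, brute-force
implementations kept separate from the package code paths they check.
"""

from __future__ import annotations

from math import log

import numpy as np
import pytest

from sailorte import ElementSpec, make_element, plant_copies
from sailorte.core import random_dna, revcomp

SIX_TAXON_TREE = ("((A:0.08,B:0.08):0.17,"
                  "((C:0.08,D:0.08):0.085,(E:0.08,F:0.08):0.085):0.085);")


@pytest.fixture(scope="session")
def default_spec():
    return ElementSpec()


@pytest.fixture(scope="session")
def default_element(default_spec):
    """Master element plus its construction truth (seed fixed)."""
    return make_element(default_spec, seed=1)


@pytest.fixture(scope="session")
def planted_genome(default_element):
    """120-kb genome with six clean planted copies."""
    element, _ = default_element
    return plant_copies(120_000, element, 6, seed=7, seq_id="chr_fix")


# ---------------------------------------------------------------------------
# Oracles


def tn93_oracle(seq_a: str, seq_b: str) -> float:
    """Closed-form TN93 distance computed with plain Python loops."""
    pur = {"A", "G"}
    pyr = {"C", "T"}
    n = p1 = p2 = q = 0
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in counts or y not in counts:
            continue
        n += 1
        counts[x] += 1
        counts[y] += 1
        if x != y:
            if x in pur and y in pur:
                p1 += 1
            elif x in pyr and y in pyr:
                p2 += 1
            else:
                q += 1
    total = sum(counts.values())
    ga, gc, gg, gt = (counts[b] / total for b in "ACGT")
    gr, gy = ga + gg, gc + gt
    p1, p2, q = p1 / n, p2 / n, q / n
    k1 = 2 * ga * gg / gr
    k2 = 2 * gt * gc / gy
    k3 = 2 * (gr * gy - ga * gg * gy / gr - gt * gc * gr / gy)
    return (-k1 * log(1 - p1 / k1 - q / (2 * gr))
            - k2 * log(1 - p2 / k2 - q / (2 * gy))
            - k3 * log(1 - q / (2 * gr * gy)))


def jc69_oracle(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor closed form from the raw mismatch proportion."""
    pairs = [(x, y) for x, y in zip(seq_a, seq_b)
             if x in "ACGT" and y in "ACGT"]
    p = sum(1 for x, y in pairs if x != y) / len(pairs)
    return -0.75 * log(1 - 4 * p / 3)


def global_align_score_oracle(a: str, b: str, match=1, mismatch=-1,
                              gap_open=-5, gap_extend=-1) -> float:
    """Gotoh global alignment score by explicit DP (first gap residue costs
    ``gap_open``, each further residue ``gap_extend``)."""
    inf = float("-inf")
    n, m = len(a), len(b)
    M2 = [[inf] * (m + 1) for _ in range(n + 1)]
    X2 = [[inf] * (m + 1) for _ in range(n + 1)]
    Y2 = [[inf] * (m + 1) for _ in range(n + 1)]
    M2[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = match if a[i - 1] == b[j - 1] else mismatch
                M2[i][j] = max(M2[i - 1][j - 1], X2[i - 1][j - 1],
                               Y2[i - 1][j - 1]) + s
            if i > 0:
                X2[i][j] = max(X2[i - 1][j] + gap_extend,
                               max(M2[i - 1][j], Y2[i - 1][j]) + gap_open)
            if j > 0:
                Y2[i][j] = max(Y2[i][j - 1] + gap_extend,
                               max(M2[i][j - 1], X2[i][j - 1]) + gap_open)
    return max(M2[n][m], X2[n][m], Y2[n][m])


def aligned_pair_score(aligned_a: str, aligned_b: str, match=1, mismatch=-1,
                       gap_open=-5, gap_extend=-1) -> float:
    """Score of a concrete alignment under the same convention."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(aligned_a, aligned_b):
        if x == "-":
            score += gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += match if x == y else mismatch
            in_gap_a = in_gap_b = False
    return score


def best_ungapped_ir_oracle(locus: str, min_len: int, min_identity: float):
    """Exhaustive ungapped inverted-repeat search over a small locus.

    Returns (score, left_start, right_start, length) of the best-scoring
    (+1/-1) repeat pair meeting the bounds, or None.  Left copy must precede
    the right copy.
    """
    best = None
    n = len(locus)
    rc = revcomp(locus)
    for length in range(min_len, n // 2 + 1):
        for i in range(n - 2 * length + 1):
            left = locus[i:i + length]
            for j in range(i + length, n - length + 1):
                right_rc = rc[n - j - length:n - j]
                matches = sum(1 for x, y in zip(left, right_rc) if x == y)
                identity = matches / length
                if identity < min_identity:
                    continue
                score = matches - (length - matches)
                key = (score, length, -i)
                if best is None or key > best[0]:
                    best = (key, i, j, length)
    if best is None:
        return None
    key, i, j, length = best
    return key[0], i, j, length


def make_tir_locus(rng: np.random.Generator, tir: str, core_len: int = 120,
                   flank_len: int = 40, right_tir: str | None = None) -> str:
    """A locus with planted TIRs and junction-guarded random context."""
    # 4-base non-complementary junction guards so the best inverted repeat
    # is exactly the planted pair (no chance extensions past the termini)
    core = "CCCC" + random_dna(core_len - 8, rng) + "AAAA"
    flank_l = random_dna(flank_len - 4, rng) + "CCCC"
    flank_r = "AAAA" + random_dna(flank_len - 4, rng)
    rtir = right_tir if right_tir is not None else revcomp(tir)
    return flank_l + tir + core + rtir + flank_r
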
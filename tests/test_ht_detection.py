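"""Distances, the HT decision rule and pair scanning."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (SIX_TAXON_TREE, aligned_pair_score,
                      global_align_score_oracle, jc69_oracle, tn93_oracle)
from sailorte import (ConfigurationError, HTScenario, InsufficientDataError,
                      MarkerAlignmentSet, ht_test, pairwise_align, scan_pairs,
                      select_gene_class, simulate_marker_set, tn93_distance,
                      rank_host_genes)
from sailorte.core import random_dna


class TestPairwiseAlign:
    def test_identical_sequences_align_gapless(self):
        a, b = pairwise_align("ACGTACGT", "ACGTACGT")
        assert a == b == "ACGTACGT"

    def test_single_deletion_gets_one_gap(self):
        a, b = pairwise_align("ACGT", "AGT")
        assert a == "ACGT"
        assert b.count("-") == 1

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=10),
           st.text(alphabet="ACGT", min_size=1, max_size=10))
    def test_alignment_score_matches_dp_oracle(self, a, b):
        aligned_a, aligned_b = pairwise_align(a, b)
        achieved = aligned_pair_score(aligned_a, aligned_b)
        assert achieved == global_align_score_oracle(a, b)


class TestTn93:
    def test_identical_sequences_have_zero_distance(self):
        seq = random_dna(1000, np.random.default_rng(1))
        rec = tn93_distance(seq, seq)
        assert rec.distance == 0.0
        assert rec.sites_used == 1000

    def test_pairwise_deletion_drops_gap_columns(self):
        rec = tn93_distance("ACGT-A", "ACGTTA", min_sites=1)
        assert rec.sites_used == 5
        assert rec.distance == 0.0

    def test_matches_independent_oracle_on_count_configurations(self):
        """Fixed substitution-count fixtures agree with the closed form."""
        rng = np.random.default_rng(2)
        for n_ag, n_ct, n_tv in [(50, 30, 40), (10, 10, 10), (80, 5, 20),
                                 (0, 40, 25), (33, 0, 12)]:
            base = "ACGT" * 250
            seq_b = list(base)
            pos = iter(rng.permutation(1000))
            swaps = ({"A": "G", "G": "A"}, {"C": "T", "T": "C"},
                     {"A": "T", "C": "G", "G": "C", "T": "A"})
            for count, table in zip((n_ag, n_ct, n_tv), swaps):
                placed = 0
                while placed < count:
                    p = next(pos)
                    if seq_b[p] in table:
                        seq_b[p] = table[seq_b[p]]
                        placed += 1
            seq_b = "".join(seq_b)
            rec = tn93_distance(base, seq_b)
            assert rec.distance == pytest.approx(tn93_oracle(base, seq_b),
                                                 abs=1e-10)

    def test_uniform_limit_equals_jc69(self):
        """Balanced substitutions at uniform composition reduce TN93 to the
        Jukes-Cantor closed form."""
        length = 99_996
        base = "ACGT" * (length // 4)
        seq_b = list(base)
        per_type = 500
        rng = np.random.default_rng(3)
        positions = iter(rng.permutation(length))
        pairs = [(x, y) for x in "ACGT" for y in "ACGT" if x != y]
        for x, y in pairs:
            placed = 0
            while placed < per_type:
                p = next(positions)
                if seq_b[p] == x:
                    seq_b[p] = y
                    placed += 1
        seq_b = "".join(seq_b)
        rec = tn93_distance(base, seq_b)
        assert rec.distance == pytest.approx(jc69_oracle(base, seq_b),
                                             abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = random_dna(2000, rng)
        b = list(a)
        for p in rng.choice(2000, 200, replace=False):
            b[p] = {"A": "G", "C": "T", "G": "A", "T": "C"}[b[p]]
        b = "".join(b)
        assert tn93_distance(a, b).distance == tn93_distance(b, a).distance

    def test_too_few_sites_raises(self):
        with pytest.raises(InsufficientDataError):
            tn93_distance("ACGT" * 10, "ACGT" * 10)

    def test_saturated_pair_is_flagged_and_capped(self):
        a = random_dna(1000, np.random.default_rng(5))
        rotate = {"A": "C", "C": "G", "G": "T", "T": "A"}
        b = "".join(rotate[c] for c in a)
        rec = tn93_distance(a, b, saturation_cap=5.0)
        assert rec.saturated
        assert rec.distance == 5.0

    def test_agrees_with_ape_reference_implementation(self, tmp_path):
        """Independent cross-check against ape::dist.dna(model='TN93')."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is expected on PATH in this environment")
        rng = np.random.default_rng(6)
        a = random_dna(800, rng)
        b = list(a)
        for p in rng.choice(800, 120, replace=False):
            b[p] = "ACGT"[("ACGT".index(b[p]) + int(rng.integers(1, 4))) % 4]
        b = "".join(b)
        fasta = tmp_path / "pair.fa"
        fasta.write_text(f">a\n{a}\n>b\n{b}\n")
        out = subprocess.run(
            ["Rscript", "-e",
             f'library(ape); d <- read.dna("{fasta}", format="fasta");'
             'cat(sprintf("%.12f", dist.dna(d, model="TN93",'
             ' pairwise.deletion=TRUE)))'],
            capture_output=True, text=True, check=True)
        assert tn93_distance(a, b).distance == pytest.approx(
            float(out.stdout), abs=1e-9)


class TestDecisionRule:
    @pytest.mark.parametrize("d,expected", [
        ((0.10, 0.30, 0.25), True),
        ((0.28, 0.30, 0.25), False),
        ((0.25, 0.25, 0.40), False),   # equality is not "lower than"
    ])
    def test_rule_examples(self, d, expected):
        assert ht_test(*d) is expected

    def test_missing_distance_is_untestable(self):
        assert ht_test(None, 0.3, 0.2) is None
        assert ht_test(0.1, None, 0.2) is None

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.floats(0, 2), st.floats(0, 2), st.floats(0, 2),
           st.floats(0, 1))
    def test_monotonicity_in_te_distance(self, d_te, d_l3, d_l4, shrink):
        """Decreasing the transposon distance never turns a positive call
        negative."""
        if ht_test(d_te, d_l3, d_l4):
            assert ht_test(d_te * shrink, d_l3, d_l4)

    @pytest.mark.parametrize("domains,expected", [
        (("prokaryote", "eukaryote"), "organelle"),
        (("eukaryote", "eukaryote"), "cytoplasmic"),
        (("prokaryote", "prokaryote"), "prokaryotic"),
    ])
    def test_gene_class_selection(self, domains, expected):
        assert select_gene_class(*domains) == expected

    def test_unknown_domain_rejected(self):
        with pytest.raises(ConfigurationError):
            select_gene_class("archaeon", "eukaryote")


def _sets_from(sim, gene_class="cytoplasmic"):
    return [
        MarkerAlignmentSet("TE", "na", sim.markers["TE"], aligned=True),
        MarkerAlignmentSet("L3", gene_class, sim.markers["L3"], aligned=True),
        MarkerAlignmentSet("L4", gene_class, sim.markers["L4"], aligned=True),
    ]


def _meta(sim):
    return {sp: ("eukaryote", "fixture") for sp in sim.species}


class TestScanPairs:
    def test_single_ht_event_flags_exactly_the_transferred_pair(self):
        sim = simulate_marker_set(
            HTScenario(tree=SIX_TAXON_TREE, seed=31,
                       ht_events=(("A", "B", 0.008),)))
        calls, agg = scan_pairs(_sets_from(sim), _meta(sim))
        flagged = {frozenset((c.species_a, c.species_b))
                   for c in calls if c.is_ht}
        assert flagged == sim.ht_truth == {frozenset(("A", "B"))}
        assert agg.supporting_pairs.sum() == 1

    def test_vertical_scenario_flags_nothing(self):
        sim = simulate_marker_set(HTScenario(tree=SIX_TAXON_TREE, seed=32))
        calls, agg = scan_pairs(_sets_from(sim), _meta(sim))
        assert not any(c.is_ht for c in calls)
        assert agg.empty

    def test_species_missing_l4_yields_untestable_pairs(self):
        sim = simulate_marker_set(HTScenario(tree=SIX_TAXON_TREE, seed=33))
        sets = _sets_from(sim)
        del sets[2].sequences["C"]
        calls, agg = scan_pairs(sets, _meta(sim))
        untestable = [c for c in calls if c.is_ht is None]
        assert {c.species_a for c in untestable} | \
               {c.species_b for c in untestable} >= {"C"}
        assert all("L4" in c.reason for c in untestable)
        assert len(untestable) == 5
        # untestable pairs never contribute to the lineage aggregation
        assert agg.empty or "C" not in set(agg.lineage_a)

    def test_shared_params_mode_gives_similar_distances(self):
        sim = simulate_marker_set(HTScenario(tree="(A:0.05,B:0.05);",
                                             seed=34), marker_length=5000)
        per_pair, _ = scan_pairs(_sets_from(sim), _meta(sim))
        pooled, _ = scan_pairs(_sets_from(sim), _meta(sim),
                               shared_params=True)
        assert per_pair[0].d_te == pytest.approx(pooled[0].d_te, rel=0.02)


class TestRankHostGenes:
    def test_more_conserved_family_ranks_first(self):
        families = {
            "rpl3": {"s1": "MKTAYIAKQR" * 20, "s2": "MKTAYIAKQR" * 20},
            "rpl9": {"s1": "MKTAYIAKQR" * 20,
                     "s2": "MKTAYIAKQR" * 10 + "LLNPQRSTVW" * 10},
        }
        table = rank_host_genes(families)
        assert list(table.family) == ["rpl3", "rpl9"]

    def test_equal_identity_breaks_tie_by_length(self):
        families = {
            "short": {"s1": "MKTAYIAKQR" * 15, "s2": "MKTAYIAKQR" * 15},
            "long": {"s1": "MKTAYIAKQR" * 21, "s2": "MKTAYIAKQR" * 21},
        }
        table = rank_host_genes(families)
        assert list(table.family) == ["long", "short"]

    def test_single_species_family_skipped(self):
        table = rank_host_genes({"solo": {"s1": "MKTA" * 50}})
        assert table.empty
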
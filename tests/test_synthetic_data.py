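"""Generator correctness: transposases, elements, planting, marker evolution."""

import numpy as np
import pytest

from conftest import SIX_TAXON_TREE, jc69_oracle
from sailorte import (DegradationSpec, ElementSpec, HTScenario,
                      InvalidSpecError, CapacityError, locate_triad,
                      make_element, make_transposase, plant_copies, revcomp,
                      signature, simulate_marker_set, tn93_distance)


class TestMakeTransposase:
    def test_default_spec_builds_dd82e_sailor_protein(self):
        protein, triad = make_transposase(ElementSpec(), seed=3)
        assert len(protein) == 400
        assert triad.de_spacer == 82
        assert protein[triad.d1_pos] == "D"
        assert protein[triad.d2_pos] == "D"
        assert protein[triad.e_pos] == "E"
        located = locate_triad(protein, "sailor", max_mismatch=0)
        assert signature(located) == "DD82E"

    def test_tc1_spacer_gives_dd34e(self):
        spec = ElementSpec(de_spacer=34, motif_set="tc1")
        protein, _ = make_transposase(spec, seed=3)
        located = locate_triad(protein, "tc1", max_mismatch=0)
        assert signature(located) == "DD34E"

    def test_same_seed_is_deterministic(self):
        a, _ = make_transposase(ElementSpec(), seed=9)
        b, _ = make_transposase(ElementSpec(), seed=9)
        assert a == b
        c, _ = make_transposase(ElementSpec(), seed=10)
        assert a != c

    def test_exclusive_spacer_counts_hold_exactly(self):
        # residues strictly between the anchors define the signature number
        for de in (78, 95, 111):
            protein, triad = make_transposase(ElementSpec(de_spacer=de), seed=1)
            assert triad.e_pos - triad.d2_pos - 1 == de
            assert locate_triad(protein, "sailor", 0).de_spacer == de

    @pytest.mark.parametrize("bad", [
        dict(tir_length=3),
        dict(tsd_seq="A"),
        dict(tsd_seq="ACGTACGTACG"),
        dict(de_spacer=5),
        dict(orf_length=150),
    ])
    def test_inconsistent_specs_rejected(self, bad):
        with pytest.raises(InvalidSpecError):
            ElementSpec(**bad)


class TestMakeElement:
    def test_tirs_are_reverse_complements(self):
        element, truth = make_element(ElementSpec(tir_length=30), seed=2)
        assert element[:30] == revcomp(element[-30:])
        assert element[:2] == "GT"

    def test_length_arithmetic(self):
        spec = ElementSpec(tir_length=25, orf_length=350,
                           utr5_length=200, utr3_length=200)
        element, _ = make_element(spec, seed=2)
        assert len(element) == 25 + 200 + (350 * 3 + 3) + 200 + 25 == 1503

    def test_orf_encodes_the_transposase(self):
        from sailorte.core import translate

        element, truth = make_element(ElementSpec(), seed=4)
        orf_nt = element[truth.orf_start:truth.orf_end]
        assert translate(orf_nt)[:-1] == truth.protein


class TestPlantCopies:
    def test_zero_copies_gives_background_only(self):
        pg = plant_copies(5000, "GTACGT" * 50, 0, seed=1)
        assert len(pg.sequence) == 5000
        assert pg.truth.empty

    def test_clean_copies_have_full_identity_and_tsds(self, default_element):
        element, _ = default_element
        pg = plant_copies(100_000, element, 5, seed=11)
        assert len(pg.truth) == 5
        assert (pg.truth.identity == 1.0).all()
        assert (pg.truth.coverage == 1.0).all()
        for _, row in pg.truth.iterrows():
            s, e = int(row.start), int(row.end)
            assert pg.sequence[s - 4:s] == "TATA"
            assert pg.sequence[e:e + 4] == "TATA"
            planted = pg.sequence[s:e]
            assert planted == (element if row.strand == "+"
                               else revcomp(element))

    def test_determinism_is_byte_exact(self, default_element):
        element, _ = default_element
        a = plant_copies(50_000, element, 3, seed=5)
        b = plant_copies(50_000, element, 3, seed=5)
        assert a.sequence == b.sequence
        assert a.truth.equals(b.truth)

    def test_capacity_error_when_genome_too_short(self, default_element):
        element, _ = default_element
        with pytest.raises(CapacityError):
            plant_copies(10_000, element, 5, seed=1)

    def test_minus_strand_plant_mirrors_plus_fixture(self, default_element):
        """Planting on the minus strand then reverse-complementing the genome
        restores the plus-strand insert with its TSD flanks."""
        element, _ = default_element
        pg = plant_copies(30_000, element, 1, seed=6, strand="-")
        row = pg.truth.iloc[0]
        s, e = int(row.start), int(row.end)
        assert pg.sequence[s:e] == revcomp(element)
        rc = revcomp(pg.sequence)
        L = len(pg.sequence)
        assert rc[L - e:L - s] == element
        assert rc[L - e - 4:L - e] == "TATA"

    def test_truncation_and_substitution_truth_is_recorded(self, default_element):
        element, _ = default_element
        deg = DegradationSpec(substitution_rate=0.05, truncation_prob=1.0,
                              truncation_frac_range=(0.5, 0.5))
        pg = plant_copies(100_000, element, 4, seed=8, degradation=deg)
        assert np.allclose(pg.truth.coverage, 0.5, atol=0.01)
        assert (pg.truth.identity < 1.0).all()
        for _, row in pg.truth.iterrows():
            assert int(row.end) - int(row.start) == round(
                row.coverage * len(element))
            # one side lost its TIR to the truncation
            assert bool(row.left_tir) != bool(row.right_tir)


class TestSimulateMarkers:
    def test_zero_branch_lengths_give_zero_distances(self):
        sim = simulate_marker_set(HTScenario(tree="(A:0.0,B:0.0);", seed=1),
                                  marker_length=500)
        for marker in ("TE", "L3", "L4"):
            assert sim.markers[marker]["A"] == sim.markers[marker]["B"]

    def test_tn93_recovers_branch_length_sum(self):
        """Empirical TN93 distance converges to the simulated divergence."""
        sim = simulate_marker_set(
            HTScenario(tree="(A:0.1,B:0.1);", seed=2, te_rate_scale=1.0),
            marker_length=10_000)
        d = tn93_distance(sim.markers["L3"]["A"], sim.markers["L3"]["B"])
        assert d.distance == pytest.approx(0.2, rel=0.10)

    def test_equal_rates_give_comparable_te_and_host_distances(self):
        sim = simulate_marker_set(
            HTScenario(tree=SIX_TAXON_TREE, seed=3, te_rate_scale=1.0),
            marker_length=10_000)
        species = sim.species
        d_te, d_l3 = [], []
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                d_te.append(tn93_distance(sim.markers["TE"][a],
                                          sim.markers["TE"][b]).distance)
                d_l3.append(tn93_distance(sim.markers["L3"][a],
                                          sim.markers["L3"][b]).distance)
        assert np.mean(d_te) == pytest.approx(np.mean(d_l3), rel=0.10)

    def test_ht_event_shrinks_only_the_transferred_pair(self):
        sim = simulate_marker_set(
            HTScenario(tree=SIX_TAXON_TREE, seed=4,
                       ht_events=(("A", "B", 0.0016),)),
            marker_length=10_000)
        assert sim.ht_truth == {frozenset(("A", "B"))}
        d_ab = tn93_distance(sim.markers["TE"]["A"],
                             sim.markers["TE"]["B"]).distance
        d_ab_host = tn93_distance(sim.markers["L3"]["A"],
                                  sim.markers["L3"]["B"]).distance
        assert d_ab < 0.2 * d_ab_host
        # a pair not involved in the transfer keeps TE divergence >= host
        d_cd = tn93_distance(sim.markers["TE"]["C"],
                             sim.markers["TE"]["D"]).distance
        d_cd_host = tn93_distance(sim.markers["L3"]["C"],
                                  sim.markers["L3"]["D"]).distance
        assert d_cd > d_cd_host

    def test_ht_event_requires_time_within_shared_history(self):
        with pytest.raises(InvalidSpecError):
            simulate_marker_set(
                HTScenario(tree=SIX_TAXON_TREE, seed=5,
                           ht_events=(("A", "B", 0.5),)),
                marker_length=100)

    def test_jc_limit_simulation_matches_jc_oracle_loosely(self):
        # sanity: our HKY simulator at kappa=1 behaves like JC
        sim = simulate_marker_set(
            HTScenario(tree="(A:0.05,B:0.05);", seed=6, kappa=1.0,
                       te_rate_scale=1.0),
            marker_length=20_000)
        a, b = sim.markers["TE"]["A"], sim.markers["TE"]["B"]
        assert jc69_oracle(a, b) == pytest.approx(0.1, rel=0.10)
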
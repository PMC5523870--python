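"""Polyclave matching and information-gain character selection."""

import math

import pytest

import clavis
from clavis.traversal import key_metrics

from conftest import make_key


class TestMatch:
    def test_partial_observation_keeps_macrocarpa(self, syagrus_taxon_matrix):
        obs = clavis.Observation({"lamina_thickness": 0.2,
                                  "adaxial_minor_veins": "absent",
                                  "mesophyll_minor_veins": "few_or_none"})
        result = clavis.match(syagrus_taxon_matrix, obs, tolerance=0)
        assert "Syagrus macrocarpa" in result.taxa

    def test_ranking_ascending_with_alphabetical_ties(
            self, syagrus_taxon_matrix):
        obs = clavis.Observation({"lamina_thickness": 0.2})
        result = clavis.match(syagrus_taxon_matrix, obs, tolerance=3)
        keys = [(e.mismatches, e.taxon) for e in result.entries]
        assert keys == sorted(keys)

    def test_tolerance_monotonicity(self, syagrus_taxon_matrix):
        obs = clavis.Observation({"lamina_thickness": 0.3,
                                  "stem_habit": "aerial",
                                  "mesophyll_minor_veins": "absent"})
        previous = set()
        for tol in range(4):
            current = set(clavis.match(syagrus_taxon_matrix, obs, tol).taxa)
            assert previous <= current
            previous = current

    def test_polymorphic_taxon_compatible_with_either_state(
            self, syagrus_taxon_matrix):
        # S. kellyana keys out on both sides of couplet 1
        for state in ("over_one_third", "absent"):
            obs = clavis.Observation({"adaxial_fb_extent": state})
            result = clavis.match(syagrus_taxon_matrix, obs, tolerance=0)
            assert "Syagrus kellyana" in result.taxa

    def test_negative_tolerance_rejected(self, syagrus_taxon_matrix):
        with pytest.raises(ValueError):
            clavis.match(syagrus_taxon_matrix, clavis.Observation({}), -1)

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_full_truth_row_matches_exactly_one_taxon(self, seed):
        bundle = clavis.generate_key(n_taxa=10, n_characters=8, seed=seed)
        m = clavis.induce_matrix(bundle.key, level="taxon")
        for taxon, row in bundle.truth.items():
            result = clavis.match(m, clavis.Observation(dict(row)),
                                  tolerance=0)
            assert result.taxa == [taxon]


class TestInformationGain:
    @pytest.fixture()
    def four_candidate_matrix(self):
        chars = (
            "char_id\tlabel\tkind\tstates\tunits\tsymbol\tdescription\n"
            "split\teven split\tbinary\t\t\t\t\n"
            "lopsided\tuneven split\tbinary\t\t\t\t\n"
            "useless\tshared state\tcategorical\tx,y\t\t\t\n")
        rows = (
            "1\ta\ts\tsplit=present\tC:2\n"
            "1\tb\ts\tsplit=absent\tC:3\n"
            "2\ta\tl\tlopsided=present\tT:Genus a\n"
            "2\tb\tl\tlopsided=absent\tT:Genus b\n"
            "3\ta\tl\tlopsided=present\tT:Genus c\n"
            "3\tb\tl\tlopsided=absent\tT:Genus d\n")
        key = make_key(rows, characters=chars)
        return clavis.induce_matrix(key, level="taxon")

    def test_even_binary_split_gains_one_bit(self, four_candidate_matrix):
        gain = clavis.gain_of(four_candidate_matrix,
                              list(four_candidate_matrix.rows), "split")
        assert gain == pytest.approx(1.0)

    def test_character_compatible_with_everything_gains_zero(
            self, four_candidate_matrix):
        gain = clavis.gain_of(four_candidate_matrix,
                              list(four_candidate_matrix.rows), "useless")
        assert gain == 0.0

    def test_best_character_maximizes_gain(self, four_candidate_matrix):
        best = clavis.next_best_character(four_candidate_matrix,
                                          list(four_candidate_matrix.rows))
        assert best.informative
        assert best.gain_bits == pytest.approx(1.0)
        # both binary characters split 2/2; the tie breaks by char_id
        assert best.char_id == "lopsided"

    def test_none_informative_result(self, four_candidate_matrix):
        result = clavis.next_best_character(
            four_candidate_matrix, list(four_candidate_matrix.rows),
            answered=["split", "lopsided"])
        assert not result.informative
        assert result.gain_bits == 0.0

    def test_gain_nonnegative_everywhere(self, syagrus_taxon_matrix):
        candidates = list(syagrus_taxon_matrix.rows)
        for char_id in syagrus_taxon_matrix.characters:
            assert clavis.gain_of(syagrus_taxon_matrix, candidates,
                                  char_id) >= 0.0

    def test_quantitative_answer_space_partitions_at_endpoints(
            self, syagrus_taxon_matrix):
        gain = clavis.gain_of(syagrus_taxon_matrix,
                              list(syagrus_taxon_matrix.rows),
                              "lamina_thickness")
        assert gain > 0.0

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_greedy_questioning_identifies_within_key_depth(self, seed):
        bundle = clavis.generate_key(n_taxa=12, n_characters=8, seed=seed)
        m = clavis.induce_matrix(bundle.key, level="taxon")
        depth = key_metrics(bundle.key).max_depth
        for taxon, row in bundle.truth.items():
            candidates, asked = clavis.greedy_identify(
                m, clavis.Observation(dict(row)))
            assert candidates == [taxon]
            assert len(asked) <= depth
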
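"""Matrix induction: thresholds, polymorphism, soundness, CSV round trip."""

import math

import pytest

import clavis

from conftest import make_key


class TestInducedConstraints:
    def test_macrocarpa_lamina_below_quarter_millimetre(self,
                                                        syagrus_taxon_matrix):
        con = clavis.constraint_of(syagrus_taxon_matrix,
                                   "Syagrus macrocarpa", "lamina_thickness")
        (iv,) = con.interval.parts
        assert iv.lo == 0 and iv.hi == 0.25 and not iv.hi_closed
        assert con.allows(0.2) and not con.allows(0.25)

    def test_kellyana_polymorphic_for_fiber_bundle_extent(
            self, syagrus_taxon_matrix):
        con = clavis.constraint_of(syagrus_taxon_matrix,
                                   "Syagrus kellyana", "adaxial_fb_extent")
        assert con.polymorphic
        assert "over_one_third" in con.states
        assert {"absent", "under_one_third"} <= con.states

    def test_romanzoffiana_rachis_from_deep_occurrence(
            self, syagrus_taxon_matrix):
        con = clavis.constraint_of(syagrus_taxon_matrix,
                                   "Syagrus romanzoffiana",
                                   "leaf_rachis_length")
        (iv,) = con.interval.parts
        assert (iv.lo, iv.hi) == (167, 440)
        assert con.provenance == ((59, "b"),)

    def test_rupicola_vein_count_lower_bound(self, syagrus_taxon_matrix):
        con = clavis.constraint_of(syagrus_taxon_matrix, "Syagrus rupicola",
                                   "abaxial_minor_vein_count")
        (iv,) = con.interval.parts
        assert iv.lo == 9 and iv.lo_closed and math.isinf(iv.hi)

    def test_unmentioned_character_is_unconstrained(self):
        key = make_key(
            "1\ta\tred\tcolor=red\tT:Genus alpha\n"
            "1\tb\tblue\tcolor=blue\tC:2\n"
            "2\ta\tsmall\tsize<5\tT:Genus beta\n"
            "2\tb\tlarge\tsize>=5\tT:Genus gamma\n")
        m = clavis.induce_matrix(key, level="taxon")
        assert clavis.constraint_of(m, "Genus alpha", "size") is None
        assert clavis.constraint_of(m, "Genus alpha", "hairy") is None
        assert clavis.constraint_of(m, "Genus beta", "size") is not None

    def test_unknown_taxon_and_character_raise(self, syagrus_taxon_matrix):
        with pytest.raises(clavis.KeyError_):
            clavis.constraint_of(syagrus_taxon_matrix, "Syagrus imaginaria",
                                 "lamina_thickness")
        with pytest.raises(clavis.KeyError_):
            clavis.constraint_of(syagrus_taxon_matrix, "Syagrus macrocarpa",
                                 "wing_color")

    def test_fixture_has_no_contradictory_paths(self, syagrus_taxon_matrix):
        assert syagrus_taxon_matrix.contradictions == []

    def test_disjunctive_clause_kept_not_flattened(
            self, syagrus_occurrence_matrix):
        # the "attached to both surfaces and/or hairy trichomes" contrast
        row = syagrus_occurrence_matrix.rows["Syagrus itapebiensis#1"]
        chars_in_clauses = {p.char_id
                           for clause, _prov in row.residual_clauses
                           for p in clause.predicates}
        assert {"most_veins_attached", "abaxial_trichomes"} <= chars_in_clauses


class TestLevels:
    def test_taxon_level_has_67_rows(self, syagrus_taxon_matrix):
        # 65 species + 2 non-autonym subspecies
        assert len(syagrus_taxon_matrix.rows) == 67
        assert "Syagrus graminifolia" in syagrus_taxon_matrix.rows
        assert "Syagrus graminifolia subsp. cabraliensis" \
            in syagrus_taxon_matrix.rows
        assert "Syagrus graminifolia subsp. glazioviana" \
            in syagrus_taxon_matrix.rows

    def test_occurrence_level_has_72_rows(self, syagrus_occurrence_matrix):
        assert len(syagrus_occurrence_matrix.rows) == 72

    def test_taxon_union_covers_each_occurrence(self, syagrus,
                                                syagrus_taxon_matrix):
        occ_m = syagrus_taxon_matrix.occurrence_matrix
        for label, occ_row in occ_m.rows.items():
            taxon_row = syagrus_taxon_matrix.rows[
                occ_row.occurrences[0].taxon_key]
            for cid, con in occ_row.constraints.items():
                merged = taxon_row.constraints[cid]
                if con.states is not None:
                    assert con.states <= merged.states
                else:
                    for iv in con.interval.parts:
                        assert merged.interval.contains(iv.sample_point())


class TestSoundness:
    def test_every_fixture_occurrence_keys_back_to_itself(
            self, syagrus, syagrus_occurrence_matrix):
        for label in syagrus_occurrence_matrix.rows:
            obs = clavis.representative_observation(
                syagrus_occurrence_matrix, label)
            result = clavis.traverse(syagrus, obs, mode="strict")
            assert result.status == "identified", (label, result.status)
            assert result.outcome.label == label

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_synthetic_constraints_equal_ground_truth(self, seed):
        bundle = clavis.generate_key(n_taxa=11, n_characters=8, seed=seed)
        m = clavis.induce_matrix(bundle.key, level="taxon")
        for taxon, row_truth in bundle.truth.items():
            row = m.rows[taxon]
            for cid, con in row.constraints.items():
                assert con.allows(row_truth[cid]), (taxon, cid)
            obs = clavis.representative_observation(m, taxon)
            result = clavis.traverse(bundle.key, obs, mode="strict")
            assert result.status == "identified"
            assert result.outcome.species_name == taxon


class TestCSV:
    def test_round_trip_reproduces_constraints(self, syagrus,
                                               syagrus_taxon_matrix):
        text = clavis.export_matrix(syagrus_taxon_matrix)
        again = clavis.parse_matrix_csv(text, syagrus)
        assert set(again.rows) == set(syagrus_taxon_matrix.rows)
        for label, row in syagrus_taxon_matrix.rows.items():
            row2 = again.rows[label]
            assert set(row2.constraints) == set(row.constraints)
            for cid, con in row.constraints.items():
                con2 = row2.constraints[cid]
                assert con2.states == con.states
                assert con2.polymorphic == con.polymorphic
                if con.interval is not None:
                    assert str(con2.interval) == str(con.interval)

    def test_synthetic_export_matches_truth(self):
        bundle = clavis.generate_key(n_taxa=8, n_characters=6, seed=5)
        m = clavis.induce_matrix(bundle.key, level="taxon")
        text = clavis.export_matrix(m)
        again = clavis.parse_matrix_csv(text, bundle.key)
        for taxon, row_truth in bundle.truth.items():
            for cid, con in again.rows[taxon].constraints.items():
                assert con.allows(row_truth[cid])
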
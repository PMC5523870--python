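"""Clade/region congruence measures against the packaged reference tables."""

import pytest

import clavis
from clavis.congruence import normalize_clade_label

from conftest import make_key

LYTOCARYUM = ["Syagrus itapebiensis", "Syagrus weddelliana",
              "Syagrus hoehnei", "Syagrus insignis"]
EASTERN_MOLECULAR = ["Syagrus cearensis", "Syagrus coronata",
                     "Syagrus glaucescens", "Syagrus kellyana",
                     "Syagrus oleracea"]
RAIN_FOREST_MOLECULAR = ["Syagrus amara", "Syagrus orinocensis",
                         "Syagrus stenopetala", "Syagrus botryophora",
                         "Syagrus cocoides", "Syagrus vermicularis",
                         "Syagrus sancona", "Syagrus ruschiana"]


class TestCladeTable:
    def test_three_normalized_clades(self, clades):
        assert clades.clades == ["Clustered stemmed", "Eastern Brazilian",
                                 "Rain Forest"]

    def test_label_normalization_rule(self):
        assert normalize_clade_label("Rain Forest/ Lytocaryum") == \
            "Rain Forest"

    def test_all_names_resolve_against_the_key(self, clades):
        assert clades.unmatched == []

    def test_molecular_versus_listed_membership(self, clades):
        molecular = clades.members("Clustered stemmed", "molecular")
        assert molecular == {"Syagrus campylospatha", "Syagrus cerqueirana",
                             "Syagrus macrocarpa", "Syagrus flexuosa"}
        listed = clades.members("Clustered stemmed", "listed")
        assert "Syagrus flexuosa" not in listed  # it keys out in branch 57′
        assert "Syagrus graminifolia" in listed

    def test_unresolvable_name_reported(self, syagrus):
        text = ("clade\tkey_branch\ttaxon\tmolecular\tlisted\n"
                "Fancy\t1\tX. nonexistens\t1\t1\n")
        table = clavis.CladeTable.from_tsv(text, syagrus)
        assert table.unmatched == ["X. nonexistens"]


class TestCrownBranch:
    def test_lytocaryum_crown_is_branch_53(self, syagrus):
        assert clavis.crown_branch(syagrus, LYTOCARYUM) == ["53"]

    def test_eastern_molecular_clade_spans_the_root(self, syagrus):
        assert clavis.crown_branch(syagrus, EASTERN_MOLECULAR) == ["ROOT"]

    def test_singleton_crown_is_its_terminal_lead(self, syagrus):
        assert clavis.crown_branch(syagrus, ["Syagrus duartei"]) == ["25"]

    def test_crown_unique_along_root_to_leaf_chain(self, syagrus):
        # single-entry species: exactly one crown lead
        crown = clavis.crown_branch(syagrus, ["Syagrus hoehnei",
                                              "Syagrus insignis"])
        assert crown == ["55′"]  # the lead whose subtree is exactly couplet 56

    def test_group_absent_from_key_rejected(self, syagrus):
        with pytest.raises(clavis.KeyError_):
            clavis.crown_branch(syagrus, ["Syagrus imaginaria"])


class TestBranchPurity:
    def test_lytocaryum_at_53_is_pure_and_complete(self, syagrus):
        assert clavis.branch_purity(syagrus, LYTOCARYUM, "53") == (1.0, 1.0)

    def test_rain_forest_molecular_recall_misses_only_ruschiana(
            self, syagrus):
        precision, recall = clavis.branch_purity(
            syagrus, RAIN_FOREST_MOLECULAR, "57'")
        assert recall == pytest.approx(7 / 8)
        branch = clavis.branch_membership(syagrus, "57'", "species")
        assert "Syagrus ruschiana" not in branch
        assert precision == pytest.approx(7 / 13)

    def test_recall_at_root_is_one(self, syagrus):
        _precision, recall = clavis.branch_purity(
            syagrus, EASTERN_MOLECULAR, "ROOT")
        assert recall == 1.0

    def test_recall_at_crown_is_one_by_construction(self, syagrus, clades):
        for clade in clades.clades:
            members = clades.members(clade, "molecular")
            crown = clavis.crown_branch(syagrus, members)
            _p, recall = clavis.branch_purity(syagrus, members, crown[0])
            assert recall == 1.0


class TestRegionHomogeneity:
    def test_branch_53_is_uniformly_atlantic_forest(self, syagrus, regions):
        assert clavis.region_homogeneity(syagrus, regions, "53") == 1.0

    def test_two_disjoint_singleton_regions_give_half(self, syagrus):
        key = make_key(
            "1\ta\tred\tcolor=red\tT:Genus alpha\n"
            "1\tb\tblue\tcolor=blue\tT:Genus beta\n")
        table = clavis.RegionTable.from_tsv(
            "taxon\tregion_codes\nGenus alpha\tNorth\nGenus beta\tSouth\n",
            key)
        assert clavis.region_homogeneity(key, table, "ROOT") == 0.5

    def test_all_fixture_branches_in_unit_interval_and_deterministic(
            self, syagrus, regions):
        values = {}
        for lead in syagrus.leads():
            label = lead.branch_label
            try:
                values[label] = clavis.region_homogeneity(syagrus, regions,
                                                          label)
            except clavis.KeyError_:
                continue  # no region data below this lead
        assert values
        assert all(0.0 <= v <= 1.0 for v in values.values())
        again = {label: clavis.region_homogeneity(syagrus, regions, label)
                 for label in values}
        assert again == values

    def test_every_key_species_is_present_or_reported_missing(
            self, syagrus, regions):
        present = set(regions.regions)
        missing = set(regions.missing_species(syagrus))
        assert present | missing == \
            clavis.branch_membership(syagrus, "ROOT", "species")
        assert not (present & missing)


class TestReport:
    def test_full_report_shapes(self, syagrus, clades, regions):
        report = clavis.congruence_report(syagrus, clades, regions)
        assert [c.clade for c in report.clades] == clades.clades
        rf = [c for c in report.clades if c.clade == "Rain Forest"][0]
        # the merged Rain Forest molecular clade includes the two
        # molecularly analyzed former-Lytocaryum species
        assert {"Syagrus itapebiensis", "Syagrus weddelliana"} <= \
            set(rf.members)
        for c in report.clades:
            assert 0.0 <= c.crown_precision <= 1.0
            assert c.crown_recall == 1.0
        for value in report.branch_homogeneity.values():
            assert 0.0 <= value <= 1.0
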
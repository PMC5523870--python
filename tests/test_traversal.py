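"""Key execution, paths, branch membership, metrics."""

import pytest

import clavis
from clavis.traversal import key_metrics, subtree_occurrences

from conftest import make_key


MACROCARPA_OBS = {
    "adaxial_fb_extent": "over_one_third",
    "mesophyll_minor_veins": "few_or_none",
    "marginal_vein_exaggerated": "absent_or_small",
    "adaxial_minor_veins": "absent",
    "lamina_thickness": 0.2,
}


class TestTraverse:
    def test_strict_identifies_macrocarpa(self, syagrus):
        result = clavis.traverse(syagrus,
                                 clavis.Observation(dict(MACROCARPA_OBS)),
                                 mode="strict")
        assert result.status == "identified"
        assert [cid for cid, _slot in result.path] == [1, 2, 3, 10, 12]
        assert result.outcome.species_name == "Syagrus macrocarpa"

    def test_explore_with_empty_observation_returns_everything(self, syagrus):
        result = clavis.traverse(syagrus, clavis.Observation({}),
                                 mode="explore")
        assert result.status == "ambiguous"
        assert len(result.outcomes) == 72

    def test_strict_halts_at_undetermined_couplet(self, syagrus):
        result = clavis.traverse(
            syagrus,
            clavis.Observation({"adaxial_fb_extent": "over_one_third"}),
            mode="strict")
        assert result.status == "ambiguous"
        assert result.unresolved == [2]
        assert result.path == [(1, "a")]

    def test_contradictory_observation_reported(self, toy_key):
        # color=white satisfies both lead 1 predicates in this rigged key
        key = make_key(
            "1\ta\tpale\tcolor in {red,white}\tT:Genus alpha\n"
            "1\tb\tlight\tcolor in {blue,white}\tT:Genus beta\n")
        result = clavis.traverse(key, clavis.Observation({"color": "white"}),
                                 mode="strict")
        assert result.status == "contradiction"
        assert result.contradictions == [1]

    def test_unknown_observation_character_rejected(self, syagrus):
        with pytest.raises(clavis.KeyError_):
            clavis.traverse(syagrus,
                            clavis.Observation({"wing_color": "red"}))

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_truth_rows_reach_their_taxa(self, seed):
        bundle = clavis.generate_key(n_taxa=10, n_characters=8, seed=seed)
        for taxon, row in bundle.truth.items():
            result = clavis.traverse(bundle.key, clavis.Observation(dict(row)),
                                     mode="strict")
            assert result.status == "identified"
            assert result.outcome.species_name == taxon


class TestPaths:
    def test_deep_path(self, syagrus):
        assert clavis.path_to(syagrus, "Syagrus cardenasii") == \
            [1, 37, 46, 51, 53, 57, 60, 70, 71]

    def test_shallow_path(self, syagrus):
        assert clavis.path_to(syagrus, "Syagrus allagopteroides") == \
            [1, 2, 3, 4, 5]

    def test_root_adjacent_terminal(self, toy_key):
        assert clavis.path_to(toy_key, "Genus alpha") == [1, 2]

    def test_unknown_occurrence(self, syagrus):
        with pytest.raises(clavis.KeyError_):
            clavis.path_to(syagrus, "Syagrus imaginaria")


class TestBranchMembership:
    def test_branch_53_is_former_lytocaryum(self, syagrus):
        assert clavis.branch_membership(syagrus, "53", "species") == {
            "Syagrus itapebiensis", "Syagrus weddelliana",
            "Syagrus hoehnei", "Syagrus insignis"}

    def test_branch_57_prime_has_13_rain_forest_species(self, syagrus):
        members = clavis.branch_membership(syagrus, "57′", "species")
        assert len(members) == 13
        assert {"Syagrus amara", "Syagrus cardenasii",
                "Syagrus vermicularis"} <= members

    def test_ascii_prime_accepted(self, syagrus):
        assert clavis.branch_membership(syagrus, "57'", "species") == \
            clavis.branch_membership(syagrus, "57′", "species")

    def test_root_splits_into_the_two_first_leads(self, syagrus):
        union = clavis.branch_membership(syagrus, "1", "species") | \
            clavis.branch_membership(syagrus, "1′", "species")
        assert union == clavis.branch_membership(syagrus, "ROOT", "species")

    def test_unknown_branch(self, syagrus):
        with pytest.raises(clavis.KeyError_):
            clavis.branch_membership(syagrus, "99", "species")

    def test_subtree_conservation_at_every_couplet(self, syagrus):
        """Each couplet's subtree is the disjoint union of its two leads'."""
        for couplet in syagrus.couplets.values():
            a, b = couplet.leads
            sa = subtree_occurrences(syagrus, a)
            sb = subtree_occurrences(syagrus, b)
            assert not (sa & sb)
            parent = syagrus.parent_lead(couplet.couplet_id)
            if parent is not None:
                assert sa | sb == subtree_occurrences(syagrus, parent)

    def test_ancestor_contains_descendant(self, syagrus):
        deep = clavis.branch_membership(syagrus, "53", "species")
        shallow = clavis.branch_membership(syagrus, "46′", "species")
        assert deep <= shallow


class TestMetrics:
    def test_fixture_depths(self, syagrus):
        m = key_metrics(syagrus)
        assert m.min_depth >= 4
        assert m.min_depth <= m.mean_depth <= m.max_depth
        assert m.expected_depth == m.mean_depth
        assert m.subtree_sizes[syagrus.root] == 72

    def test_perfectly_balanced_key_has_uniform_depth(self):
        chars = (
            "char_id\tlabel\tkind\tstates\tunits\tsymbol\tdescription\n"
            "c1\tsplit 1\tbinary\t\t\t\t\n"
            "c2\tsplit 2\tbinary\t\t\t\t\n"
            "c3\tsplit 3\tbinary\t\t\t\t\n")
        rows = []
        # couplet 1 on c1; couplets 2-3 on c2; couplets 4-7 on c3
        rows.append("1\ta\tx\tc1=present\tC:2")
        rows.append("1\tb\tx\tc1=absent\tC:3")
        for cid, (lo, hi) in {2: (4, 5), 3: (6, 7)}.items():
            rows.append(f"{cid}\ta\tx\tc2=present\tC:{lo}")
            rows.append(f"{cid}\tb\tx\tc2=absent\tC:{hi}")
        for i, cid in enumerate(range(4, 8)):
            rows.append(f"{cid}\ta\tx\tc3=present\tT:Genus t{2 * i + 1}")
            rows.append(f"{cid}\tb\tx\tc3=absent\tT:Genus t{2 * i + 2}")
        key = make_key("\n".join(rows) + "\n", characters=chars)
        m = key_metrics(key)
        assert m.min_depth == m.max_depth == 3

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_depth_ordering_invariant(self, seed):
        bundle = clavis.generate_key(n_taxa=9, n_characters=7, seed=seed)
        m = key_metrics(bundle.key)
        assert m.min_depth <= m.mean_depth <= m.max_depth
        # brute-force path enumeration agrees with the recursive sizes
        assert sum(1 for _ in bundle.key.terminal_leads()) == \
            m.subtree_sizes[bundle.key.root]
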
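import random

import pandas as pd
import pytest

import eolkit as ek
from eolkit import fixtures as fx, taxtree
from eolkit.errors import (
    AmbiguityError,
    ConsistencyError,
    ContractError,
    MissingDataError,
    ParseError,
    RankOrderError,
)

from conftest import hierarchy_set_from_specs
from oracles import oracle_canonical, tree_canonical

BEARS = set(fx.BEAR_LINEAGES)


def build_random(seed, n_tips, n_ranks, missing_prob=0.0):
    specs = fx.random_taxonomy(seed, n_tips, n_ranks, missing_prob)
    return hierarchy_set_from_specs(specs), specs


class TestMakeTreeData:
    def test_direct_construction_with_one_missing_cell(self):
        specs = [
            fx.HierSpec(entry_id=1, provider="P",
                        taxon=ek.RankedName("Aus bus", "species"),
                        ancestors=[ek.RankedName("Animalia", "kingdom"),
                                   ek.RankedName("Chordata", "phylum")]),
            fx.HierSpec(entry_id=2, provider="P",
                        taxon=ek.RankedName("Cus dus", "species"),
                        ancestors=[ek.RankedName("Animalia", "kingdom")]),
        ]
        data = ek.make_tree_data(hierarchy_set_from_specs(specs))
        assert data.rank_order == ["kingdom", "phylum", "species"]
        assert data.matrix.shape == (2, 3)
        assert data.missing_cells() == [("Cus dus", "phylum")]

    def test_bear_set_shows_missing_cells(self, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        missing = data.missing_cells()
        assert missing, "disparate lineages must leave gaps in the matrix"
        assert {rank for _, rank in missing} == {"order"}
        assert {taxon for taxon, _ in missing} == {"Xerophyllum tenax", "Acanthus mollis"}

    def test_rank_order_matches_generator_on_complete_taxonomies(self):
        hset, _ = build_random(seed=1, n_tips=12, n_ranks=6)
        data = ek.make_tree_data(hset)
        assert data.rank_order == list(fx.LINNAEAN_RANKS[:6])

    def test_unranked_levels_get_synthetic_slots(self):
        specs = [fx.HierSpec(entry_id=1, provider="P",
                             taxon=ek.RankedName("Aus bus", "species"),
                             ancestors=[ek.RankedName("Animalia", "kingdom"),
                                        ek.RankedName("Bilateria", None)])]
        data = ek.make_tree_data(hierarchy_set_from_specs(specs))
        assert data.rank_order == ["kingdom", "clade_depth_1", "species"]
        assert data.matrix.at["Aus bus", "clade_depth_1"] == "Bilateria"

    def test_cyclic_rank_orders_rejected(self):
        specs = [
            fx.HierSpec(entry_id=1, provider="P",
                        taxon=ek.RankedName("Aus", None),
                        ancestors=[ek.RankedName("X", "alpha"),
                                   ek.RankedName("Y", "beta")]),
            fx.HierSpec(entry_id=2, provider="P",
                        taxon=ek.RankedName("Bus", None),
                        ancestors=[ek.RankedName("Y2", "beta"),
                                   ek.RankedName("X2", "alpha")]),
        ]
        with pytest.raises(RankOrderError):
            ek.make_tree_data(hierarchy_set_from_specs(specs))

    def test_tsv_renders_missing_as_na(self, bear_hierarchy, tmp_path):
        data = ek.make_tree_data(bear_hierarchy)
        out = tmp_path / "treedata.tsv"
        data.to_tsv(out)
        body = out.read_text(encoding="utf-8")
        assert "\tNA" in body and "Ursidae" in body


class TestMakeHierarchyTree:
    def test_smallest_branching_case(self):
        specs = [
            fx.HierSpec(entry_id=1, provider="P", taxon=ek.RankedName("A", "species"),
                        ancestors=[ek.RankedName("R", "genus")]),
            fx.HierSpec(entry_id=2, provider="P", taxon=ek.RankedName("B", "species"),
                        ancestors=[ek.RankedName("R", "genus")]),
        ]
        data = ek.make_tree_data(hierarchy_set_from_specs(specs))
        tree = ek.make_hierarchy_tree(data, "error")
        assert ek.write_newick(tree, branch_lengths=False) == "(A,B)R;"

    def test_bear_tree_has_exactly_the_six_tips(self, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        tree = ek.make_hierarchy_tree(data, "drop_ranks")
        assert set(tree.tip_labels()) == BEARS

    def test_bear_tree_splits_plants_from_animals(self, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        tree = ek.make_hierarchy_tree(data, "drop_ranks")
        tip_sets = [
            {t.label for t in ek.TaxonTree(root=child).tips()}
            for child in tree.root.children
        ]
        plants = {"Xerophyllum tenax", "Acanthus mollis"}
        assert plants in tip_sets
        assert BEARS - plants in tip_sets

    def test_policy_is_mandatory(self, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        with pytest.raises(TypeError):
            ek.make_hierarchy_tree(data)
        with pytest.raises(ContractError):
            ek.make_hierarchy_tree(data, "keep_everything")

    def test_error_policy_lists_offending_cells(self, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        with pytest.raises(MissingDataError) as err:
            ek.make_hierarchy_tree(data, "error")
        assert ("Acanthus mollis", "order") in err.value.cells

    def test_drop_taxa_removes_incomplete_rows(self, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        tree = ek.make_hierarchy_tree(data, "drop_taxa")
        assert set(tree.tip_labels()) == BEARS - {"Xerophyllum tenax", "Acanthus mollis"}

    def test_identical_retained_paths_merge_into_one_terminal(self):
        # two congeners with the species rank missing for one of them:
        # drop_ranks produces a genus-level tree with merged terminals
        specs = [
            fx.HierSpec(entry_id=1, provider="P", taxon=ek.RankedName("G one", "species"),
                        ancestors=[ek.RankedName("F", "family"), ek.RankedName("G", "genus")]),
            fx.HierSpec(entry_id=2, provider="P", taxon=ek.RankedName("G two", "species"),
                        ancestors=[ek.RankedName("F", "family"), ek.RankedName("G", "genus")]),
            fx.HierSpec(entry_id=3, provider="P", taxon=ek.RankedName("H one", "species"),
                        ancestors=[ek.RankedName("F", "family"), ek.RankedName("H", "genus")]),
        ]
        data = ek.make_tree_data(hierarchy_set_from_specs(specs))
        data.matrix.at["G two", "species"] = None
        with pytest.warns(UserWarning, match="merging"):
            tree = ek.make_hierarchy_tree(data, "drop_ranks")
        assert sorted(tree.tip_labels()) == ["G", "H"]

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_and_order_invariance(self, seed):
        rng = random.Random(seed)
        n_tips = rng.randrange(2, 31)
        n_ranks = rng.randrange(2, 9)
        specs = fx.random_taxonomy(seed, n_tips, n_ranks)
        paths = [[a.name for a in s.ancestors] + [s.taxon.name] for s in specs]
        expected = oracle_canonical(paths)

        hset = hierarchy_set_from_specs(specs)
        tree = ek.make_hierarchy_tree(ek.make_tree_data(hset), "error")
        assert tree_canonical(tree) == expected

        rng.shuffle(specs)
        for i, s in enumerate(specs):
            s.entry_id = i + 1
        permuted = hierarchy_set_from_specs(specs)
        tree2 = ek.make_hierarchy_tree(ek.make_tree_data(permuted), "error")
        assert tree_canonical(tree2) == expected
        assert ek.write_newick(tree2) == ek.write_newick(tree)


class TestMissingRankPolicies:
    @pytest.mark.parametrize("seed", range(10))
    def test_policies_match_direct_set_computation(self, seed):
        specs = fx.random_taxonomy(seed, n_tips=15, n_ranks=6, missing_prob=0.3)
        data = ek.make_tree_data(hierarchy_set_from_specs(specs))
        missing = data.missing_cells()
        bad_taxa = {t for t, _ in missing}
        bad_ranks = {r for _, r in missing}
        complete_rows = [t for t in data.terminal_names if t not in bad_taxa]
        complete_ranks = [r for r in data.rank_order if r not in bad_ranks]

        if complete_rows:
            tree = ek.make_hierarchy_tree(data, "drop_taxa")
            assert sorted(tree.tip_labels()) == sorted(complete_rows)
        else:
            with pytest.raises(MissingDataError):
                ek.make_hierarchy_tree(data, "drop_taxa")

        assert complete_ranks, "terminal rank is never missing by construction"
        tree = ek.make_hierarchy_tree(data, "drop_ranks")
        deepest = complete_ranks[-1]
        expected_tips = sorted({data.matrix.at[t, deepest] for t in data.terminal_names})
        assert sorted(set(tree.tip_labels())) == expected_tips


class TestNewick:
    def test_single_tip(self):
        tree = ek.TaxonTree(root=taxtree.TreeNode(label="A"))
        assert ek.write_newick(tree) == "A;"
        assert ek.parse_newick("A;") == tree

    def test_labels_with_spaces_are_quoted(self):
        tree = ek.TaxonTree(root=taxtree.TreeNode(label="Ursus maritimus"))
        assert ek.write_newick(tree) == "'Ursus maritimus';"

    def test_internal_labels_parse(self):
        tree = ek.parse_newick("((A,B)G,C)F;")
        assert sorted(tree.tip_labels()) == ["A", "B", "C"]
        assert tree.root.label == "F"
        assert tree.root.children[0].label == "G"

    def test_syntax_error_raises(self):
        with pytest.raises(ParseError):
            ek.parse_newick("((A,B;")

    @pytest.mark.parametrize("seed", range(25))
    def test_roundtrip_on_random_trees(self, seed):
        hset, _ = build_random(seed=1000 + seed,
                               n_tips=random.Random(seed).randrange(2, 20),
                               n_ranks=random.Random(seed).randrange(2, 7))
        tree = ek.make_hierarchy_tree(ek.make_tree_data(hset), "error")
        text = ek.write_newick(tree)
        assert ek.parse_newick(text) == tree
        assert ek.write_newick(ek.parse_newick(text)) == text


class TestEdgeLabels:
    def _chain_data(self):
        specs = [
            fx.HierSpec(entry_id=1, provider="P", taxon=ek.RankedName("S1", "species"),
                        ancestors=[ek.RankedName("K", "kingdom"),
                                   ek.RankedName("P1", "phylum"),
                                   ek.RankedName("G1", "genus")]),
            fx.HierSpec(entry_id=2, provider="P", taxon=ek.RankedName("S2", "species"),
                        ancestors=[ek.RankedName("K", "kingdom"),
                                   ek.RankedName("P2", "phylum"),
                                   ek.RankedName("G2", "genus")]),
        ]
        data = ek.make_tree_data(hierarchy_set_from_specs(specs))
        return data, ek.make_hierarchy_tree(data, "error")

    def test_recent_keeps_least_inclusive_name(self):
        data, tree = self._chain_data()
        labels = ek.make_edge_labels(data, tree, "recent").by_child_label()
        # each phylum→genus chain collapsed onto the edge above the tip's parent
        assert labels["S1"] == "S1"
        node = tree.root.children[0]
        assert node.collapsed_labels  # a chain was collapsed here
        assert labels[node.label] == node.label

    def test_oldest_keeps_most_inclusive_name(self):
        data, tree = self._chain_data()
        labels = ek.make_edge_labels(data, tree, "oldest")
        for node, label in labels.items():
            candidates = node.collapsed_labels + [node.label]
            assert label == candidates[0]

    @pytest.mark.parametrize("seed", range(10))
    def test_all_policy_conserves_clade_names(self, seed):
        hset, specs = build_random(seed=2000 + seed, n_tips=12, n_ranks=6)
        data = ek.make_tree_data(hset)
        tree = ek.make_hierarchy_tree(data, "error")
        emap = ek.make_edge_labels(data, tree, "all")
        # every distinct clade name lands on exactly one edge, except the
        # names sitting on the root (which has no edge above it)
        on_root = 0 if tree.root.label == "root" else 1 + len(tree.root.collapsed_labels)
        assert emap.total_label_count() == len(data.clade_names()) - on_root

    def test_mismatched_tree_rejected(self, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        foreign = ek.parse_newick("((A,B)G,C)F;")
        with pytest.raises(ConsistencyError):
            ek.make_edge_labels(data, foreign, "recent")

    def test_invalid_policy_rejected(self, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        tree = ek.make_hierarchy_tree(data, "drop_ranks")
        with pytest.raises(ContractError):
            ek.make_edge_labels(data, tree, "newest")


class TestMatchDataToTreeTips:
    def test_rows_reordered_to_tip_order(self, bear_pages, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        tree = ek.make_hierarchy_tree(data, "drop_ranks")
        table = ek.get_richness_scores(bear_pages).sample(frac=1.0, random_state=41)
        matched = ek.match_data_to_tree_tips(tree, table)
        assert matched["taxon_name"].tolist() == tree.tip_labels()

    def test_missing_tip_gets_na_row(self, bear_pages, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        tree = ek.make_hierarchy_tree(data, "drop_ranks")
        table = ek.get_richness_scores(bear_pages)
        table = table[table["taxon_name"] != "Acanthus mollis"]
        matched = ek.match_data_to_tree_tips(tree, table)
        assert len(matched) == len(tree.tip_labels())
        row = matched[matched["taxon_name"] == "Acanthus mollis"]
        assert pd.isna(row["richness_score"].iloc[0])

    def test_unmatched_rows_dropped_with_warning(self, bear_pages, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        tree = ek.make_hierarchy_tree(data, "drop_ranks")
        table = ek.get_richness_scores(bear_pages)
        extra = pd.concat([table, pd.DataFrame([{"taxon_name": "Extra taxon",
                                                 "eol_page_id": 1,
                                                 "richness_score": 1.0}])],
                          ignore_index=True)
        with pytest.warns(UserWarning, match="Extra taxon"):
            matched = ek.match_data_to_tree_tips(tree, extra)
        assert len(matched) == len(tree.tip_labels())

    def test_duplicate_rows_for_one_tip_rejected(self, bear_pages, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        tree = ek.make_hierarchy_tree(data, "drop_ranks")
        table = ek.get_richness_scores(bear_pages)
        doubled = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(AmbiguityError):
            ek.match_data_to_tree_tips(tree, doubled)

    def test_reorder_is_idempotent(self, bear_pages, bear_hierarchy):
        data = ek.make_tree_data(bear_hierarchy)
        tree = ek.make_hierarchy_tree(data, "drop_ranks")
        table = ek.get_richness_scores(bear_pages).sample(frac=1.0, random_state=43)
        once = ek.match_data_to_tree_tips(tree, table)
        twice = ek.match_data_to_tree_tips(tree, once)
        pd.testing.assert_frame_equal(once, twice)
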
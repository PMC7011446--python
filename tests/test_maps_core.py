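"""Species-tree validation, duplication mapping, subtree sorting."""

import random

import pytest

from wgdkit.core_io import SpeciesTree, read_newick
from wgdkit.errors import StructureError
from wgdkit.maps_core import (OccupancyRule, SpeciesIndex, collect_subtrees,
                              family_filter, map_duplications, maps_profile,
                              validate_species_tree)
from wgdkit.simulate import ladder_species_tree

from conftest import random_gene_tuple, tuple_to_gene_tree
from oracles import SpeciesLCA, apparent_duplications


def ladder_tuple(taxa):
    tree = (taxa[0], taxa[1])
    for t in taxa[2:]:
        tree = (tree, t)
    return tree


class TestValidateSpeciesTree:
    def test_ladder_numbered_tipmost_to_root(self):
        sp = ladder_species_tree(list("ABCDE"))
        order = validate_species_tree(sp)
        assert len(order) == 4
        assert sorted(order[0].leaf_labels()) == ["A", "B"]     # N1
        assert sorted(order[-1].leaf_labels()) == list("ABCDE")  # N4 = root

    def test_balanced_tree_rejected(self):
        root = read_newick("((A,B),(C,D));")
        with pytest.raises(StructureError, match="pectinate"):
            validate_species_tree(SpeciesTree(root=root))

    def test_size_warning_outside_6_to_8(self, recwarn):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            validate_species_tree(ladder_species_tree(list("ABCDEFG")))
        with pytest.warns(UserWarning, match="taxa"):
            validate_species_tree(ladder_species_tree(list("ABCDE")))
        with pytest.warns(UserWarning, match="taxa"):
            validate_species_tree(ladder_species_tree(list("ABCDEFGHI")))


class TestMapDuplications:
    def test_shared_cherry_duplication_maps_to_cherry_ancestor(self, ladder4):
        gene = tuple_to_gene_tree((("A_1", "B_1"), ("A_2", "B_2")))
        (ev,) = map_duplications(gene, ladder4)
        assert ev.mapped_node == "N1"
        assert ev.left_taxa == ev.right_taxa == frozenset({"A", "B"})

    def test_within_taxon_duplication_maps_to_terminal_branch(self, ladder4):
        gene = tuple_to_gene_tree((("A_1", "A_2"), "B_1"))
        (ev,) = map_duplications(gene, ladder4)
        assert ev.mapped_node == "A"

    def test_concordant_single_copy_tree_has_no_events(self, ladder4):
        gene = tuple_to_gene_tree(((("A_1", "B_1"), "C_1"), "D_1"))
        assert map_duplications(gene, ladder4) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_lca_apparent_duplication_oracle(self, seed, ladder4):
        rng = random.Random(seed)
        sp_tuple = ladder_tuple(list("ABCD"))
        lca = SpeciesLCA(sp_tuple)
        index = SpeciesIndex(ladder4)
        # align oracle node keys with package labels
        key_to_label = _oracle_key_to_label(sp_tuple, lca, index)
        for _ in range(50):
            tup = random_gene_tuple(rng, list("ABCD"), 12)
            gene = tuple_to_gene_tree(tup)
            got = sorted(e.mapped_node for e in map_duplications(gene, index))
            expected = sorted(key_to_label[k] for k in apparent_duplications(
                tup, lca, lambda leaf: leaf.split("_")[0]))
            assert got == expected


def _oracle_key_to_label(sp_tuple, lca: SpeciesLCA, index: SpeciesIndex):
    """Map oracle species-node keys to the package's N-labels/taxon names."""
    mapping = {}

    def taxa_of(sub):
        if isinstance(sub, tuple):
            return taxa_of(sub[0]) | taxa_of(sub[1])
        return {sub}

    def walk(sub):
        key = id(sub) if isinstance(sub, tuple) else sub
        mask = index.taxon_mask(taxa_of(sub))
        mapping[key] = index.mrca_label(mask)
        if isinstance(sub, tuple):
            for child in sub:
                walk(child)

    walk(sp_tuple)
    return mapping


class TestCollectSubtrees:
    def test_occupancy_minimum_is_ceiling(self):
        rule = OccupancyRule(0.45)
        assert rule.min_taxa(5) == 3
        assert rule.min_taxa(2) == 1
        assert rule.min_taxa(7) == 4

    def test_sparse_subtree_excluded_by_occupancy(self):
        sp = ladder_species_tree(list("ABCDE"))
        # clade(N4) has 5 taxa -> needs ceil(0.45*5)=3 distinct taxa
        gene = tuple_to_gene_tree(("A_1", "E_1"))
        recs = collect_subtrees(gene, sp, OccupancyRule(0.45))
        assert [r for r in recs if r.species_node == "N4"] == []
        recs0 = collect_subtrees(gene, sp, OccupancyRule(1e-9))
        assert [r.species_node for r in recs0] == ["N4"]

    def test_zero_occupancy_counts_maximal_clade_duplications(self, ladder7):
        # with the occupancy filter vacuous, the counted shared duplications
        # are exactly the unfiltered duplication events that sit at the root
        # of a maximal per-node clade (events strictly inside a counted
        # clade are covered by that clade, not counted twice); every counted
        # duplication corresponds to a mapped event
        rng = random.Random(7)
        rule = OccupancyRule(1e-9)
        index = SpeciesIndex(ladder7)
        saw_equal = 0
        for _ in range(60):
            gene = tuple_to_gene_tree(random_gene_tuple(rng, list("ABCDEFG"), 8))
            internal = {f"N{i}" for i in range(1, 7)}
            events = [e for e in map_duplications(gene, ladder7)
                      if e.mapped_node in internal]
            recs = collect_subtrees(gene, ladder7, rule)
            dup_recs = [r for r in recs if r.is_shared_duplication]
            assert len(dup_recs) <= len(events)
            # every counted duplication matches an event at the same node
            # with the same union taxon set
            ev_keys = {(e.mapped_node, frozenset(e.left_taxa | e.right_taxa))
                       for e in events}
            assert {(r.species_node, r.taxa) for r in dup_recs} <= ev_keys
            if len(dup_recs) == len(events):
                saw_equal += 1
        assert saw_equal >= 10  # equality is the common, non-nested case

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_maximal_clade_oracle(self, seed, ladder7):
        rng = random.Random(seed)
        rule = OccupancyRule(0.45)
        index = SpeciesIndex(ladder7)
        clades = {lab: (set(_mask_taxa(index, c)), set(_mask_taxa(index, d1)),
                        set(_mask_taxa(index, d2)))
                  for lab, c, d1, d2 in index.clades()}
        for _ in range(20):
            gene = tuple_to_gene_tree(random_gene_tuple(rng, list("ABCDEFG"), 12))
            got = {(r.species_node, r.taxa, r.is_shared_duplication)
                   for r in collect_subtrees(gene, ladder7, rule)}
            expected = set()
            # brute force: enumerate every gene clade with its ancestor chain
            chains = _clade_chains(gene.root)
            for lab, (C, D1, D2) in clades.items():
                need = rule.min_taxa(len(C))

                def q(node):
                    taxa = {l.split("_")[0] for l in node.leaf_labels()}
                    return (taxa <= C and taxa & D1 and taxa & D2
                            and len(taxa) >= need)

                for node, ancestors in chains:
                    if not q(node) or any(q(a) for a in ancestors):
                        continue
                    taxa = frozenset(l.split("_")[0]
                                     for l in node.leaf_labels())
                    dup = False
                    if node.children:
                        tl = {l.split("_")[0]
                              for l in node.children[0].leaf_labels()}
                        tr = {l.split("_")[0]
                              for l in node.children[1].leaf_labels()}
                        union_mask = index.taxon_mask(tl | tr)
                        dup = bool(tl & tr) \
                            and index.mrca_label(union_mask) == lab \
                            and len(tl) >= need and len(tr) >= need
                    expected.add((lab, taxa, dup))
            assert got == expected


def _mask_taxa(index, mask):
    return {t for t, b in index.bit.items() if mask & b}


def _clade_chains(root):
    out = []

    def walk(node, ancestors):
        out.append((node, list(ancestors)))
        for child in node.children:
            walk(child, ancestors + [node])

    walk(root, [])
    return out

    def test_occupancy_monotone(self, ladder7):
        rng = random.Random(8)
        trees = [tuple_to_gene_tree(random_gene_tuple(rng, list("ABCDEFG"), 14))
                 for _ in range(30)]
        prev = None
        for f in (1e-9, 0.35, 0.45, 0.75, 1.0):
            prof = maps_profile(trees, ladder7, OccupancyRule(f))
            for node in prof.node_order:
                assert prof.n_dup[node] <= prof.n_subtrees[node]
                if prev is not None:
                    assert prof.n_subtrees[node] <= prev.n_subtrees[node]
                    assert prof.n_dup[node] <= prev.n_dup[node]
            prev = prof


class TestMapsProfile:
    def test_toy_all_duplicated_trees_give_100_percent(self, ladder4):
        trees = [tuple_to_gene_tree((("A_1", "B_1"), ("A_2", "B_2")),
                                    name=f"g{i}") for i in range(10)]
        prof = maps_profile(trees, ladder4, OccupancyRule(1e-9))
        assert prof.n_subtrees["N1"] == 10
        assert prof.n_dup["N1"] == 10
        assert prof.pct_dup("N1") == 100.0

    def test_single_copy_trees_give_zero_percent(self, ladder4):
        trees = [tuple_to_gene_tree(((("A_1", "B_1"), "C_1"), "D_1"),
                                    name=f"g{i}") for i in range(5)]
        prof = maps_profile(trees, ladder4, OccupancyRule(0.45))
        for node in prof.node_order:
            if prof.n_subtrees[node]:
                assert prof.pct_dup(node) == 0.0

    def test_order_invariant(self, ladder4):
        rng = random.Random(9)
        trees = [tuple_to_gene_tree(random_gene_tuple(rng, list("ABCD"), 8),
                                    name=f"g{i}") for i in range(10)]
        prof1 = maps_profile(trees, ladder4, OccupancyRule(0.45))
        prof2 = maps_profile(list(reversed(trees)), ladder4, OccupancyRule(0.45))
        assert prof1.to_frame().equals(prof2.to_frame())


class TestFamilyFilter:
    def test_missing_taxon_dropped_and_multicopy_kept(self):
        full = tuple_to_gene_tree((( ("A_1", "A_2"), ("B_1", "C_1")), "D_1"))
        partial = tuple_to_gene_tree((("A_1", "B_1"), "C_1"))
        kept = family_filter([full, partial], {"A", "B", "C", "D"})
        assert kept == [full]

    def test_matches_set_comparison_oracle(self):
        rng = random.Random(10)
        taxa = set("ABCD")
        trees = [tuple_to_gene_tree(random_gene_tuple(rng, list(taxa),
                                                      rng.randint(2, 10)),
                                    name=f"g{i}") for i in range(50)]
        kept = family_filter(trees, taxa)
        expected = [t for t in trees
                    if {l.split("_")[0] for l in t.root.leaf_labels()} == taxa]
        assert kept == expected
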
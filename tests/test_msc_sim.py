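"""Coalescent simulator and topology census, checked against closed forms,
brute-force enumeration, and an independent coalescent implementation."""

import itertools
import math

import numpy as np
import pytest

from polyprof.msc_sim import (
    GeneTreeNode,
    TopologyCensus,
    census_topologies,
    compile_species_tree,
    ils_test,
    prepare_species_tree,
    scale_branch_lengths,
    scale_for_organelle,
    simulate_gene_tree,
    simulate_gene_trees,
    three_taxon_concordance,
    tree_from_newick,
)


def leaf_depths(tree):
    depths = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


class TestSpeciesTreePreparation:
    def test_four_taxon_depths_equalized(self):
        tree = tree_from_newick("((a:9,b:9):0.3,(c:9,d:9):0.1);")
        prep = prepare_species_tree(tree, terminal_length=1.0)
        depths = leaf_depths(prep)
        assert all(abs(d - 1.3) < 1e-12 for d in depths.values())

    def test_second_application_is_stable(self):
        tree = tree_from_newick("((a:2,b:2):0.3,(c:1,d:1):0.1);")
        once = prepare_species_tree(tree)
        twice = prepare_species_tree(once)
        assert leaf_depths(once) == leaf_depths(twice)

    def test_unrooted_input_rejected(self):
        tree = tree_from_newick("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="rooted"):
            prepare_species_tree(tree)

    def test_organelle_scaling_doubles_branches(self):
        tree = tree_from_newick("((a:1,b:1):0.3,c:1.3);")
        scaled = scale_for_organelle(tree, 2.0)
        internal = [
            e.length
            for e in scaled.preorder_edge_iter()
            if e.length is not None and not e.head_node.is_leaf()
        ]
        assert internal == [0.6]
        same = scale_branch_lengths(tree, 1.0)
        assert leaf_depths(same) == leaf_depths(tree)

    def test_negative_branch_rejected(self):
        tree = tree_from_newick("((a:1,b:1):-0.3,c:1);")
        with pytest.raises(ValueError, match="negative"):
            compile_species_tree(tree)


class TestSimulator:
    def test_single_population_pair_coalescence_is_exponential(self):
        tree = tree_from_newick("(a:1,b:1);")  # both lineages meet at the root
        n = 3000
        # heights above the root junction (age 1) are Exp(1) waiting times
        heights = [
            simulate_gene_tree(tree, 1, rng=np.random.default_rng((5, i))).height - 1.0
            for i in range(n)
        ]
        mean = float(np.mean(heights))
        se = 1.0 / math.sqrt(n)  # Exp(1) has sd 1
        assert abs(mean - 1.0) < 3 * se

    def test_two_species_topology_is_forced(self):
        tree = tree_from_newick("(a:1,b:1);")
        gt = simulate_gene_tree(tree, 1, seed=7)
        assert sorted(lf.species for lf in gt.leaves()) == ["a", "b"]
        assert len(gt.children) == 2

    @pytest.mark.parametrize("t", [0.5, 2.0])
    def test_three_taxon_concordance_closed_form(self, t):
        tree = tree_from_newick(f"((A:1,B:1):{t},C:{1 + t});")
        n = 20_000
        census = census_topologies(
            simulate_gene_trees(tree, n, 1, seed=3),
            {"A": "A", "B": "B", "C": "C"},
            "((A,B),C);",
        )
        expect = three_taxon_concordance(t)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(census.fraction_match - expect) < 3 * se

    def test_same_seed_gives_bitwise_identical_newicks(self):
        tree = tree_from_newick("((A:1,B:1):1,C:2);")
        first = [t.newick() for t in simulate_gene_trees(tree, 40, 2, seed=9)]
        second = [t.newick() for t in simulate_gene_trees(tree, 40, 2, seed=9)]
        assert first == second
        third = [t.newick() for t in simulate_gene_trees(tree, 40, 2, seed=10)]
        assert first != third


# ---------------------------------------------------------------------------
# Census vs brute-force enumeration
# ---------------------------------------------------------------------------

def all_rooted_topologies(leaves):
    """Every rooted binary tree over the leaf labels, as nested frozensets."""
    leaves = list(leaves)
    if len(leaves) == 1:
        return [leaves[0]]
    out = []
    first = leaves[0]
    rest = leaves[1:]
    for k in range(len(rest) + 1):
        for left_rest in itertools.combinations(rest, k):
            left = [first, *left_rest]
            right = [x for x in rest if x not in left_rest]
            if not right:
                continue
            for lt in all_rooted_topologies(left):
                for rt in all_rooted_topologies(right):
                    out.append((lt, rt))
    return out


def to_gene_tree(node, height=1.0):
    if not isinstance(node, tuple):
        species = node.split("^")[0]
        return GeneTreeNode(label=node, species=species)
    left = to_gene_tree(node[0], height / 2)
    right = to_gene_tree(node[1], height / 2)
    return GeneTreeNode(children=(left, right), height=height)


def oracle_leafsets(node, acc):
    """Leaf label sets of every subtree (independent recursion on tuples)."""
    if not isinstance(node, tuple):
        acc.append(frozenset([node]))
        return frozenset([node])
    ls = oracle_leafsets(node[0], acc) | oracle_leafsets(node[1], acc)
    acc.append(ls)
    return ls


def oracle_census(topology, clade_of, sizes, target_check):
    acc = []
    oracle_leafsets(topology, acc)
    clade_sets = {
        c: frozenset(l for l in _all_leaves(topology) if clade_of[l] == c)
        for c in sizes
    }
    mono = all(cs in acc for cs in clade_sets.values())
    if not mono:
        return False, False
    return True, target_check(topology, clade_of)


def _all_leaves(node):
    if not isinstance(node, tuple):
        return [node]
    return _all_leaves(node[0]) + _all_leaves(node[1])


class TestCensusAgainstEnumeration:
    def test_all_fifteen_four_tip_topologies(self):
        clades = ["I", "II", "III", "IV"]
        leaves = [f"{c}^0" for c in clades]
        topologies = all_rooted_topologies(leaves)
        assert len(topologies) == 15
        clade_map = {c: c for c in clades}

        def is_default_match(topo, clade_of):
            # clade III alone on one side of the root split
            sides = [frozenset(_all_leaves(s)) for s in topo]
            return frozenset(["III^0"]) in sides

        n_match = 0
        for topo in topologies:
            tree = to_gene_tree(topo)
            census = census_topologies([tree], clade_map, "(III,(I,II,IV));")
            assert census.n_monophyletic == 1  # singleton clades always qualify
            expected = is_default_match(topo, None)
            assert census.n_match == int(expected)
            n_match += census.n_match
        # of 15 rooted topologies exactly 3 put III sister to the rest
        assert n_match == 3

    def test_five_tip_suite_with_a_two_sample_clade(self):
        leaves = ["I^0", "I^1", "II^0", "III^0", "IV^0"]
        clade_of = {l: l.split("^")[0] for l in leaves}
        clade_map = {c: c for c in ["I", "II", "III", "IV"]}
        topologies = all_rooted_topologies(leaves)
        assert len(topologies) == 105

        def strict_check(topo, _):
            # strict organelle shape: (III,(I,(II,IV))) after collapsing clade I
            acc = []
            oracle_leafsets(topo, acc)
            return (
                frozenset(["II^0", "IV^0"]) in acc
                and frozenset(["I^0", "I^1", "II^0", "IV^0"]) in acc
            )

        sizes = {"I": 2, "II": 1, "III": 1, "IV": 1}
        for topo in topologies:
            tree = to_gene_tree(topo)
            census = census_topologies(
                [tree], clade_map, "(III,(I,(II,IV)));"
            )
            mono, match = oracle_census(topo, clade_of, sizes, strict_check)
            assert census.n_monophyletic == int(mono)
            assert census.n_match == int(mono and match)

    def test_clade_nested_inside_another_is_not_monophyletic(self):
        # a clade-II lineage inside clade III's subtree
        topo = ((("III^0", "II^0"), "III^1"), ("I^0", "IV^0"))
        tree = to_gene_tree(topo)
        census = census_topologies(
            [tree], {c: c for c in ["I", "II", "III", "IV"]}, "(III,(I,II,IV));"
        )
        assert census.n_monophyletic == 0


class TestIlsTest:
    SPECIES = "(out2:10,(out1:8,(I:6,(II:5,(III:4,IV:4):1):1):2):2);"
    CLADES = {
        "I": "I", "II": "II", "III": "III", "IV": "IV",
        "out1": "outgroup", "out2": "outgroup",
    }

    def test_species_topology_fraction_grows_with_scale(self):
        """ILS vanishes as internal branches lengthen, so the species-tree
        topology is recovered increasingly often."""
        tree = tree_from_newick(self.SPECIES)
        table, _ = ils_test(
            tree, self.CLADES, "(I,(II,(III,IV)));", n_trees=4000, seed=5,
            scales=(0.25, 1.0, 4.0),
        )
        fractions = list(table["fraction"])
        assert fractions[0] < fractions[1] < fractions[2]
        assert fractions[2] > 0.9

    def test_star_tree_topology_frequencies_follow_labeled_histories(self):
        """With four exchangeable lineages, the coalescent is uniform over
        labeled histories, so balanced topologies occur at 1/9 (two histories
        each) and caterpillars at 1/18 (one history each)."""
        star = tree_from_newick("((A:1,B:1):1e-9,(C:1,D:1):1e-9);")
        n = 15_000
        trees = list(simulate_gene_trees(star, n, 1, seed=6))
        cm = {c: c for c in "ABCD"}
        expectations = {
            "((A,B),(C,D));": 1 / 9,
            "(((A,B),C),D);": 1 / 18,
            "(((C,D),A),B);": 1 / 18,
        }
        for target, expect in expectations.items():
            census = census_topologies(trees, cm, target)
            se = math.sqrt(expect * (1 - expect) / n)
            assert abs(census.fraction_match - expect) < 3 * se

    def test_census_report_table_shape_and_cv(self):
        tree = tree_from_newick(self.SPECIES)
        table, cv = ils_test(
            tree, self.CLADES, n_trees=1500, seed=2, scales=(0.5, 1.0)
        )
        assert list(table.columns) == [
            "scale", "n_total", "n_monophyletic", "n_match", "fraction", "se"
        ]
        assert (table["n_monophyletic"] <= table["n_total"]).all()
        assert cv is None or cv >= 0

    def test_census_counts_validate(self):
        with pytest.raises(ValueError):
            TopologyCensus(10, 11, 0)
        assert TopologyCensus(10, 0, 0).fraction_match is None


class TestAgainstMsprime:
    def test_three_taxon_concordance_matches_msprime(self):
        """Independent cross-check: msprime's coalescent, configured so one
        generation equals one coalescent unit, must agree on the concordance
        probability of a 3-taxon species tree."""
        msprime = pytest.importorskip("msprime")
        t = 1.0
        n = 4000
        demography = msprime.Demography()
        for name in ["A", "B", "C", "AB", "ABC"]:
            demography.add_population(name=name, initial_size=1.0)
        demography.add_population_split(time=1.0, derived=["A", "B"], ancestral="AB")
        demography.add_population_split(time=2.0, derived=["AB", "C"], ancestral="ABC")
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1},
            demography=demography,
            ploidy=1,
            num_replicates=n,
            random_seed=42,
        )
        conc = 0
        for ts in reps:
            tree = ts.first()
            a, b, c = (ts.samples(population=p)[0] for p in range(3))
            conc += tree.mrca(a, b) != tree.root
        ours = census_topologies(
            simulate_gene_trees(
                tree_from_newick("((A:1,B:1):1,C:2);"), n, 1, seed=8
            ),
            {"A": "A", "B": "B", "C": "C"},
            "((A,B),C);",
        )
        expect = three_taxon_concordance(t)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(conc / n - expect) < 3 * se
        assert abs(ours.fraction_match - conc / n) < 3 * math.sqrt(2) * se
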
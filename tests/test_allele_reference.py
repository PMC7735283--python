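"""Candidate selection, gene screening, NJ tree inference, and the F1 filter."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyprof.io_core import Alignment, Sequence
from polyprof.allele_reference import (
    GeneModel,
    ReferenceConfig,
    build_reference,
    f1_filter,
    infer_gene_tree,
    jc_distance_matrix,
    load_panel,
    neighbor_joining,
    nested_clade,
    root_on_outgroup,
    screen_gene,
    select_candidate_exons,
    sister_group,
    write_panel,
)
from polyprof.msc_sim import tree_from_newick


class TestCandidateExons:
    def test_longest_exon_above_insert_selected(self):
        genes = [GeneModel("gA", [(0, 300), (400, 1000)])]
        assert select_candidate_exons(genes, 550) == {"gA": (400, 1000)}

    def test_gene_without_long_exon_excluded(self):
        genes = [GeneModel("gB", [(0, 300), (400, 900)])]
        assert select_candidate_exons(genes, 550) == {}

    def test_toy_set_hand_counted(self):
        lengths = [300, 551, 550, 600, 549, 800, 100, 1200, 552, 10]
        genes = [
            GeneModel(f"g{i}", [(0, L)]) for i, L in enumerate(lengths)
        ]
        chosen = select_candidate_exons(genes, 550)
        # strictly greater than the insert: 551, 600, 800, 1200, 552
        assert sorted(chosen) == ["g1", "g3", "g5", "g7", "g8"]

    def test_gene_model_validates_intervals(self):
        with pytest.raises(ValueError):
            GeneModel("bad", [(0, 100), (50, 150)])


def ids_for(counts: dict[str, int]) -> list[str]:
    return [f"{clade}.{i}" for clade, n in counts.items() for i in range(n)]


class TestScreening:
    def test_thresholds_inclusive_at_equality(self):
        counts = {"I": 4, "II": 4, "III": 4, "IV": 4,
                  "outgroup1": 1, "outgroup2": 1, "F1": 12}
        ids = ids_for(counts)  # 30 sequences total
        cmap = {i: i.split(".")[0] for i in ids}
        assert screen_gene(ids, cmap).passed

    def test_missing_congener_reported(self):
        counts = {"I": 8, "II": 8, "III": 8, "IV": 8, "outgroup1": 1}
        ids = ids_for(counts)
        cmap = {i: i.split(".")[0] for i in ids}
        result = screen_gene(ids, cmap)
        assert not result.passed
        assert result.reasons == ["missing_congener:outgroup2"]

    def test_unknown_sequence_id_errors(self):
        with pytest.raises(KeyError):
            screen_gene(["mystery"], {})

    @settings(max_examples=150, derandomize=True)
    @given(
        counts=st.fixed_dictionaries(
            {
                c: st.integers(0, 8)
                for c in ["I", "II", "III", "IV", "outgroup1", "outgroup2", "F1"]
            }
        )
    )
    def test_randomized_panels_match_direct_predicates(self, counts):
        ids = ids_for(counts)
        cmap = {i: i.split(".")[0] for i in ids}
        result = screen_gene(ids, cmap)
        expect = (
            counts["outgroup1"] >= 1
            and counts["outgroup2"] >= 1
            and all(counts[c] >= 4 for c in ["I", "II", "III", "IV"])
            and len(ids) >= 30
        )
        assert result.passed == expect


class TestDistances:
    def test_jc_correction_on_known_mismatch_fraction(self):
        a = Sequence("a", "A" * 90 + "C" * 10)
        b = Sequence("b", "A" * 100)
        labels, d, warn = jc_distance_matrix(Alignment([a, b]))
        expect = -0.75 * math.log(1 - 4 / 3 * 0.1)
        assert warn == 0
        assert d[0, 1] == pytest.approx(expect)

    def test_masked_sites_excluded_and_no_overlap_flagged(self):
        a = Sequence("a", "ACGT" + "N" * 4)
        b = Sequence("b", "ACGA" + "N" * 4)
        c = Sequence("c", "NNNN" + "ACGT")
        labels, d, warn = jc_distance_matrix(Alignment([a, b, c]))
        assert warn == 2  # (a,c) and (b,c) share no sites
        # their distance falls back to the maximum observed finite distance
        assert d[0, 2] == pytest.approx(d[0, 1])


def unrooted_splits(tree):
    """Non-trivial bipartitions of an (unrooted) dendropy tree as frozensets."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(frozenset([side, all_leaves - side]))
    return splits


def all_unrooted_five_taxon_topologies(labels):
    """The 15 unrooted binary topologies on 5 labels, as split sets."""
    out = {}
    la = list(labels)
    full = frozenset(la)
    # an unrooted 5-taxon tree has exactly two non-trivial splits: a 2|3 pair
    # of cherries sharing no leaf
    for cherry1 in itertools.combinations(la, 2):
        rest = [x for x in la if x not in cherry1]
        for cherry2 in itertools.combinations(rest, 2):
            s1 = frozenset([frozenset(cherry1), full - frozenset(cherry1)])
            s2 = frozenset([frozenset(cherry2), full - frozenset(cherry2)])
            key = frozenset([s1, s2])
            out[key] = (frozenset(cherry1), frozenset(cherry2))
    assert len(out) == 15
    return out


def least_squares_topology(labels, dmat):
    """Exhaustive OLS topology search over all 15 five-taxon topologies."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    best, best_sse = None, np.inf
    for key, (cherry1, cherry2) in sorted(
        all_unrooted_five_taxon_topologies(labels).items(), key=str
    ):
        # edges: 5 terminal + 2 internal (one per cherry)
        cols = []
        for i, j in pairs:
            li, lj = labels[i], labels[j]
            row = [0.0] * 7
            row[i] = row[j] = 1.0
            # internal edge of a cherry lies on the path iff exactly one of
            # the two endpoints is inside the cherry
            row[5] = float((li in cherry1) != (lj in cherry1))
            row[6] = float((li in cherry2) != (lj in cherry2))
            cols.append(row)
        A = np.array(cols)
        d = np.array([dmat[i, j] for i, j in pairs])
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        sse = float(((A @ x - d) ** 2).sum())
        if sse < best_sse - 1e-12:
            best_sse, best = sse, key
    return best


def evolve_on_topology(seed, inner=0.15, outer=0.05, L=800):
    """Alignment of 5 sequences evolved by site flips along ((a,b),(c,d),e)."""
    rng = np.random.default_rng(seed)

    def mutate(seq, p):
        flip = rng.random(L) < p
        out = seq.copy()
        out[flip] = (out[flip] + rng.integers(1, 4, flip.sum())) % 4
        return out

    root = rng.integers(0, 4, L)
    ab = mutate(root, inner)
    cd = mutate(root, inner)
    seqs = {
        "a": mutate(ab, outer), "b": mutate(ab, outer),
        "c": mutate(cd, outer), "d": mutate(cd, outer),
        "e": mutate(root, inner + outer),
    }
    return Alignment(
        Sequence(k, "".join("ACGT"[x] for x in v)) for k, v in sorted(seqs.items())
    )


class TestNeighborJoining:
    def test_clear_four_taxon_grouping(self):
        rows = {
            "a": "A" * 20 + "C",
            "b": "A" * 20 + "T",
            "c": "G" * 10 + "A" * 10 + "C",
            "d": "G" * 10 + "A" * 10 + "T",
        }
        aln = Alignment(Sequence(k, v) for k, v in rows.items())
        tree = infer_gene_tree(aln)
        assert unrooted_splits(tree) == {
            frozenset([frozenset(["a", "b"]), frozenset(["c", "d"])])
        }

    def test_duplicate_sequence_placed_as_zero_length_sister(self):
        aln = evolve_on_topology(2)
        dup = Alignment([*aln, Sequence("a2", aln.get("a").residues)])
        labels, d, _ = jc_distance_matrix(dup)
        tree = neighbor_joining(labels, d)
        sisters = sister_group(tree, "a2")
        assert sisters == ["a"]

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_exhaustive_least_squares(self, seed):
        aln = evolve_on_topology(seed)
        labels, d, _ = jc_distance_matrix(aln)
        nj_splits = unrooted_splits(neighbor_joining(labels, d))
        ls_key = least_squares_topology(labels, d)
        assert frozenset(nj_splits) == ls_key

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_biopython_nj(self, seed):
        from Bio.Phylo.TreeConstruction import (
            DistanceMatrix,
            DistanceTreeConstructor,
        )

        aln = evolve_on_topology(seed, inner=0.1, outer=0.08)
        labels, d, _ = jc_distance_matrix(aln)
        lower = [[float(d[i, j]) for j in range(i + 1)] for i in range(len(labels))]
        bp_tree = DistanceTreeConstructor().nj(DistanceMatrix(labels, lower))
        bp_splits = set()
        all_leaves = frozenset(labels)
        for clade in bp_tree.get_nonterminals():
            side = frozenset(t.name for t in clade.get_terminals())
            if 1 < len(side) < len(all_leaves) - 1:
                bp_splits.add(frozenset([side, all_leaves - side]))
        assert bp_splits == unrooted_splits(neighbor_joining(labels, d))

    def test_too_few_sequences_rejected(self):
        aln = Alignment([Sequence("a", "AC"), Sequence("b", "AG")])
        with pytest.raises(ValueError):
            infer_gene_tree(aln)


class TestRooting:
    def test_outgroup_becomes_sister_to_everything(self):
        aln = evolve_on_topology(4)
        tree = root_on_outgroup(infer_gene_tree(aln), "e")
        kids = tree.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids]
        assert frozenset(["e"]) in sides

    def test_rooting_on_already_basal_outgroup_is_stable(self):
        aln = evolve_on_topology(4)
        once = root_on_outgroup(infer_gene_tree(aln), "e")
        twice = root_on_outgroup(once, "e")
        assert unrooted_splits(once) == unrooted_splits(twice)

    def test_missing_outgroup_errors(self):
        aln = evolve_on_topology(4)
        with pytest.raises(ValueError):
            root_on_outgroup(infer_gene_tree(aln), "nope")


class TestF1Filter:
    CMAP = {
        "Ia": "I", "Ib": "I", "IVa": "IV", "IVb": "IV",
        "F1h1": "F1", "F1h2": "F1", "out": "outgroup1",
    }

    def _tree(self, newick):
        t = tree_from_newick(newick)
        t.is_rooted = True
        return t

    def test_one_allele_per_parent_clade_is_informative(self):
        tree = self._tree("(out,((F1h1,(Ia,Ib)),(F1h2,(IVa,IVb))));")
        assert f1_filter(tree, ["F1h1", "F1h2"], self.CMAP)

    def test_both_alleles_in_one_clade_uninformative(self):
        tree = self._tree("(out,(((F1h1,Ia),(F1h2,Ib)),(IVa,IVb)));")
        assert not f1_filter(tree, ["F1h1", "F1h2"], self.CMAP)

    def test_mixed_sister_group_uninformative(self):
        tree = self._tree("(out,((F1h1,(Ia,IVa)),(F1h2,(Ib,IVb))));")
        assert not f1_filter(tree, ["F1h1", "F1h2"], self.CMAP)

    def test_requires_exactly_two_alleles(self):
        tree = self._tree("(out,(F1h1,(Ia,Ib)));")
        with pytest.raises(ValueError):
            f1_filter(tree, ["F1h1"], self.CMAP)

    def test_nested_clade_helper(self):
        assert nested_clade(["Ia", "Ib"], self.CMAP) == "I"
        assert nested_clade(["Ia", "IVa"], self.CMAP) is None
        assert nested_clade(["out"], self.CMAP) is None


class TestPanelBuild:
    def test_stage_counts_additive_and_deterministic(self, small_bundle):
        from polyprof import pipeline

        panel, _ = pipeline.build_panel_from_bundle(
            small_bundle, use_true_alleles=True
        )
        sc = panel.stage_counts
        assert (
            sc["failed_screen"] + sc["failed_f1"] + sc["retained"] == sc["input"]
        )
        panel2, _ = pipeline.build_panel_from_bundle(
            small_bundle, use_true_alleles=True
        )
        assert panel.manifest.to_csv(index=False) == panel2.manifest.to_csv(
            index=False
        )

    def test_removing_a_congener_fails_every_gene(self, small_bundle):
        alignments = small_bundle.panel_alignments()
        cmap = small_bundle.clade_map
        stripped = {
            g: a.drop([i for i in a.ids if cmap.get(i) == "outgroup2"])
            for g, a in alignments.items()
        }
        with pytest.raises(ValueError, match="empty reference panel"):
            build_reference(stripped, cmap)

    def test_panel_round_trip(self, small_panel, tmp_path):
        write_panel(small_panel, tmp_path / "panel")
        back = load_panel(tmp_path / "panel")
        assert sorted(back.genes) == sorted(small_panel.genes)
        g = small_panel.gene_ids[0]
        assert back.genes[g].alignment.ids == small_panel.genes[g].alignment.ids
        assert back.f1_ids[g] == small_panel.f1_ids[g]
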
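"""Multispecies-coalescent gene-tree simulation and rooted-topology censusing.

Implements the incomplete-lineage-sorting (ILS) test: simulate gene trees under
the multispecies coalescent (MSC) on a species tree whose branch lengths are in
coalescent units (time / 2N generations), then census how often a target rooted
topology over clades is produced among trees where every ingroup clade is
monophyletic. The organelle variant doubles all branch lengths to reflect the
smaller effective population size of uniparentally inherited genomes.

The simulator is a direct implementation of the standard MSC: within a species
branch carrying k lineages, the waiting time to the next coalescence is
Exponential with rate k(k-1)/2 in that branch's coalescent units, the coalescing
pair is uniform, and uncoalesced lineages are passed to the parent branch. The
root branch is treated as infinitely long so every replicate fully coalesces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import dendropy
import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Species-tree preparation
# ---------------------------------------------------------------------------

def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def _require_rooted_binary(tree: dendropy.Tree) -> None:
    root_children = tree.seed_node.child_nodes()
    if len(root_children) != 2:
        raise ValueError(
            f"species tree must be rooted (binary root), found {len(root_children)} "
            "children at the root"
        )


def prepare_species_tree(
    tree: dendropy.Tree, terminal_length: float = 1.0
) -> dendropy.Tree:
    """Set all terminal branches to ``terminal_length``, then make ultrametric.

    Internal branch lengths (assumed to be in coalescent units) are kept; each
    tip branch is first reset to ``terminal_length`` and then extended so that
    every root-to-tip path equals the maximum root-to-tip depth.
    """
    _require_rooted_binary(tree)
    out = tree.clone(depth=1)
    for leaf in out.leaf_node_iter():
        leaf.edge.length = terminal_length
    for node in out.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("internal branch lengths must be set")
    depths = {}
    for node in out.preorder_node_iter():
        parent = node.parent_node
        depths[node] = 0.0 if parent is None else depths[parent] + node.edge.length
    max_depth = max(depths[leaf] for leaf in out.leaf_node_iter())
    for leaf in out.leaf_node_iter():
        leaf.edge.length += max_depth - depths[leaf]
    return out


def scale_branch_lengths(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    """Multiply every branch length by ``factor``; topology unchanged."""
    if factor <= 0:
        raise ValueError(f"factor must be positive, got {factor}")
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return out


def scale_for_organelle(tree: dendropy.Tree, factor: float = 2.0) -> dendropy.Tree:
    """Organelle rescaling: branch lengths doubled (halved effective size)."""
    return scale_branch_lengths(tree, factor)


# ---------------------------------------------------------------------------
# Gene-tree simulation
# ---------------------------------------------------------------------------

class GeneTreeNode:
    """Lightweight rooted gene-tree node; leaves carry their species label."""

    __slots__ = ("label", "species", "children", "height")

    def __init__(self, label=None, species=None, children=(), height=0.0):
        self.label = label
        self.species = species
        self.children = tuple(children)
        self.height = height

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["GeneTreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(reversed(node.children))

    def newick(self) -> str:
        def fmt(node: GeneTreeNode, parent_height: float | None) -> str:
            if node.is_leaf:
                body = node.label
            else:
                body = "(" + ",".join(fmt(c, node.height) for c in node.children) + ")"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - node.height:.6g}"

        return fmt(self, None) + ";"


@dataclass(frozen=True)
class _Branch:
    """Compiled species-tree branch: label (leaves), length, child branches."""

    label: str | None
    length: float
    age: float  # age of the node at the bottom of this branch (tips at 0)
    children: tuple


def compile_species_tree(tree: dendropy.Tree) -> _Branch:
    """Compile a dendropy species tree into a nested branch structure.

    Negative branch lengths error; zero-length terminal branches are allowed.
    """
    _require_rooted_binary(tree)

    def build(node: dendropy.Node) -> _Branch:
        length = node.edge.length
        if node.parent_node is None:
            length = math.inf  # root branch: coalesce everything
        if length is None:
            raise ValueError("all branch lengths must be set")
        if length < 0:
            raise ValueError(f"negative branch length {length}")
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            return _Branch(label, float(length), 0.0, ())
        children = tuple(build(c) for c in node.child_nodes())
        age = max(c.age + c.length for c in children)
        return _Branch(None, float(length), age, children)

    return build(tree.seed_node)


def _coalesce(
    lineages: list[GeneTreeNode],
    t_start: float,
    duration: float,
    rng: np.random.Generator,
) -> list[GeneTreeNode]:
    t = t_start
    lin = lineages
    k = len(lin)
    while k > 1:
        rate = k * (k - 1) / 2.0
        t = t + rng.exponential() / rate
        if t - t_start >= duration:
            break
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = lin[i], lin[j]
        merged = GeneTreeNode(children=(a, b), height=t)
        lin = [x for n, x in enumerate(lin) if n != i and n != j]
        lin.append(merged)
        k -= 1
    return lin


def _simulate_compiled(
    root: _Branch,
    samples_per_species: int | Mapping[str, int],
    rng: np.random.Generator,
) -> GeneTreeNode:
    def n_samples(species: str) -> int:
        if isinstance(samples_per_species, Mapping):
            return int(samples_per_species.get(species, 0))
        return int(samples_per_species)

    def run(branch: _Branch) -> list[GeneTreeNode]:
        if not branch.children:
            n = n_samples(branch.label)
            if n < 0:
                raise ValueError("samples_per_species must be >= 0")
            lineages = [
                GeneTreeNode(label=f"{branch.label}^{i}", species=branch.label)
                for i in range(n)
            ]
        else:
            lineages = []
            for child in branch.children:
                lineages.extend(run(child))
        return _coalesce(lineages, branch.age, branch.length, rng)

    result = run(root)
    if len(result) != 1:
        raise RuntimeError("lineages failed to coalesce above the root")
    return result[0]


def simulate_gene_tree(
    species_tree: dendropy.Tree | _Branch,
    samples_per_species: int | Mapping[str, int] = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GeneTreeNode:
    """Simulate one MSC gene tree on a species tree in coalescent units."""
    compiled = (
        species_tree
        if isinstance(species_tree, _Branch)
        else compile_species_tree(species_tree)
    )
    if rng is None:
        rng = np.random.default_rng(seed)
    return _simulate_compiled(compiled, samples_per_species, rng)


def simulate_gene_trees(
    species_tree: dendropy.Tree | _Branch,
    n_trees: int,
    samples_per_species: int | Mapping[str, int] = 1,
    seed: int = 0,
) -> Iterator[GeneTreeNode]:
    """Yield ``n_trees`` gene trees, each from its own counter-derived stream.

    Tree i is drawn from ``default_rng((seed, i))``, so the sequence is
    reproducible and trivially parallelisable.
    """
    compiled = (
        species_tree
        if isinstance(species_tree, _Branch)
        else compile_species_tree(species_tree)
    )
    for i in range(n_trees):
        rng = np.random.default_rng((seed, i))
        yield _simulate_compiled(compiled, samples_per_species, rng)


# ---------------------------------------------------------------------------
# Topology census
# ---------------------------------------------------------------------------

@dataclass
class TopologyCensus:
    """Counts from a census of rooted gene-tree topologies over clades."""

    n_total: int
    n_monophyletic: int
    n_match: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_match <= self.n_monophyletic <= self.n_total:
            raise ValueError("census counts must nest: match <= monophyletic <= total")

    @property
    def fraction_match(self) -> float | None:
        """Fraction of all-clades-monophyletic trees matching the target.

        Undefined (None) when no simulated tree had all clades monophyletic.
        """
        if self.n_monophyletic == 0:
            return None
        return self.n_match / self.n_monophyletic

    @property
    def standard_error(self) -> float | None:
        f = self.fraction_match
        if f is None:
            return None
        return math.sqrt(f * (1 - f) / self.n_monophyletic)


def target_clusters(
    target_topology: dendropy.Tree | str,
) -> tuple[frozenset, set[frozenset]]:
    """Clade-label leaf set and non-trivial rooted clusters of the target.

    The target may contain polytomies: an unresolved (I,II,IV) below the first
    split constrains nothing among those three clades.
    """
    tree = (
        tree_from_newick(target_topology)
        if isinstance(target_topology, str)
        else target_topology
    )
    clusters: set[frozenset] = set()
    leafsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            leafsets[node] = frozenset([label])
        else:
            ls = frozenset().union(*(leafsets[c] for c in node.child_nodes()))
            leafsets[node] = ls
    all_labels = leafsets[tree.seed_node]
    for node, ls in leafsets.items():
        if 1 < len(ls) < len(all_labels):
            clusters.add(ls)
    return all_labels, clusters


def _census_one(
    root: GeneTreeNode,
    species_index: Mapping[str, int],
    sizes: list[int],
) -> tuple[bool, set[frozenset]]:
    """(all ingroup clades monophyletic?, induced clusters as clade-index sets).

    Clusters are computed on the restriction to ingroup leaves (outgroup
    lineages pruned); strict rooted monophyly additionally requires that no
    outgroup leaf sits inside the clade's subtree.
    """
    n_clades = len(sizes)
    mono = [False] * n_clades
    clusters: set[frozenset] = set()

    def visit(node: GeneTreeNode) -> list[int]:
        if node.is_leaf:
            counts = [0] * (n_clades + 1)
            counts[species_index[node.species]] = 1
        else:
            counts = list(visit(node.children[0]))
            for child in node.children[1:]:
                for k, v in enumerate(visit(child)):
                    counts[k] += v
        present = [k for k in range(n_clades) if counts[k] > 0]
        if present and all(counts[k] == sizes[k] for k in present):
            clusters.add(frozenset(present))
            if len(present) == 1 and counts[n_clades] == 0:
                mono[present[0]] = True
        return counts

    visit(root)
    return all(mono), clusters


def census_topologies(
    gene_trees: Iterable[GeneTreeNode],
    clade_map: Mapping[str, str],
    target_topology: dendropy.Tree | str,
) -> TopologyCensus:
    """Census rooted gene-tree topologies against a target clade topology.

    ``clade_map`` maps species labels to clade labels; species mapping to clades
    absent from the target topology (e.g. outgroups) are ignored for monophyly
    and pruned before topology comparison. A gene tree counts as monophyletic
    iff every target clade's samples form a rooted monophyletic group; among
    those, it matches iff every non-trivial rooted cluster of the target is a
    cluster of the gene tree once each clade is collapsed to one tip.
    """
    labels, label_clusters = target_clusters(target_topology)
    ingroup = sorted(labels)
    clade_index = {c: i for i, c in enumerate(ingroup)}
    n_clades = len(ingroup)
    clusters = {
        frozenset(clade_index[c] for c in cluster) for cluster in label_clusters
    }
    species_index: dict[str, int] = {}
    for species, clade in clade_map.items():
        species_index[species] = clade_index.get(clade, n_clades)
    sizes: list[int] | None = None
    n_total = n_mono = n_match = 0
    for tree in gene_trees:
        if sizes is None:
            counts = [0] * n_clades
            for leaf in tree.leaves():
                if leaf.species not in species_index:
                    raise KeyError(
                        f"leaf species {leaf.species!r} has no clade assignment"
                    )
                idx = species_index[leaf.species]
                if idx < n_clades:
                    counts[idx] += 1
            if 0 in counts:
                missing = [c for c, i in clade_index.items() if counts[i] == 0]
                raise ValueError(f"no samples for target clades {missing}")
            sizes = counts
        n_total += 1
        try:
            mono, induced = _census_one(tree, species_index, sizes)
        except KeyError as exc:
            raise KeyError(f"leaf species {exc} has no clade assignment") from exc
        if mono:
            n_mono += 1
            if clusters <= induced:
                n_match += 1
    return TopologyCensus(n_total, n_mono, n_match)


#: default organelle target: clade III sister to everything else, with the
#: relationships among clades I, II and IV left unconstrained.
DEFAULT_ORGANELLE_TARGET = "(III,(I,II,IV));"


def ils_test(
    species_tree: dendropy.Tree,
    clade_map: Mapping[str, str],
    target_topology: dendropy.Tree | str = DEFAULT_ORGANELLE_TARGET,
    n_trees: int = 100_000,
    samples_per_species: int | Mapping[str, int] = 1,
    seed: int = 0,
    scales: Iterable[float] = (1.0,),
    terminal_length: float = 1.0,
    organelle_factor: float = 2.0,
) -> tuple[pd.DataFrame, float | None]:
    """Test whether a target (organelle) topology is explainable by ILS alone.

    The species tree is prepared (terminal branches set to ``terminal_length``
    and made ultrametric) and its branch lengths doubled to emulate organelle
    effective population size; the census is then repeated over a grid of
    global branch-length scale factors, which stands in for the mutation-rate /
    population-size combinations that only rescale coalescent units.

    Returns a per-scale table (scale, n_total, n_monophyletic, n_match,
    fraction, se) and the coefficient of variation of the fraction across the
    grid (None if fewer than two scales yield a defined fraction).
    """
    base = scale_for_organelle(
        prepare_species_tree(species_tree, terminal_length), organelle_factor
    )
    rows = []
    for si, scale in enumerate(scales):
        scaled = scale_branch_lengths(base, scale)
        compiled = compile_species_tree(scaled)
        trees = (
            _simulate_compiled(
                compiled, samples_per_species, np.random.default_rng((seed, si, i))
            )
            for i in range(n_trees)
        )
        census = census_topologies(trees, clade_map, target_topology)
        rows.append(
            {
                "scale": scale,
                "n_total": census.n_total,
                "n_monophyletic": census.n_monophyletic,
                "n_match": census.n_match,
                "fraction": census.fraction_match,
                "se": census.standard_error,
            }
        )
    table = pd.DataFrame(rows)
    fractions = table["fraction"].dropna()
    cv = None
    if len(fractions) >= 2 and fractions.mean() > 0:
        cv = float(fractions.std(ddof=1) / fractions.mean())
    return table, cv


def three_taxon_concordance(t: float) -> float:
    """Closed-form MSC probability that a gene tree matches ((A,B),C).

    For a rooted 3-taxon species tree with internal branch t (coalescent
    units), the concordance probability is 1 - (2/3)e^{-t}.
    """
    return 1.0 - (2.0 / 3.0) * math.exp(-t)
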
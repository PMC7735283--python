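"""Construction of the phylogenetically informative reference allele panel.

The panel is the backbone of the genome-composition analysis: for each
single-copy gene whose longest exon exceeds the sequencing insert size, the
phased diploid alleles plus two congener outgroup sequences form an alignment.
Genes are screened on three criteria — (i) at least one sequence per congener,
(ii) at least four sequences in each of the four nuclear clades, (iii) at
least 30 sequences in total — and a rooted per-gene tree is inferred. A gene
is phylogenetically informative only if the two alleles of the built-in F1
hybrid (one C3 clade-I parent, one C4 clade-IV parent) are nested within
clades I and IV respectively; genes failing this control are discarded as
insufficiently variable or potentially paralogous.

Tree inference is neighbor joining on Jukes–Cantor-corrected distances with
lexicographic tie-breaking, chosen for determinism: downstream consumers use
only the clade membership of nested leaves, not branch support.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .io_core import Alignment, Sequence, write_fasta, read_fasta, ParseError

NUCLEAR_CLADES = ("I", "II", "III", "IV")
CONGENER_CLADES = ("outgroup1", "outgroup2")
#: congener used for rooting (the more distant outgroup)
ROOT_CLADE = "outgroup1"

_JC_MAX_P = 0.75 - 1e-9


# ---------------------------------------------------------------------------
# Candidate exon selection
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Exon structure of one gene; intervals are 0-based half-open, sorted."""

    gene_id: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def longest_exon(self) -> tuple[int, int]:
        return max(self.exons, key=lambda ival: (ival[1] - ival[0], -ival[0]))

    @property
    def longest_exon_length(self) -> int:
        s, e = self.longest_exon
        return e - s


def select_candidate_exons(
    gene_models: Iterable[GeneModel], insert_size: int
) -> dict[str, tuple[int, int]]:
    """Pick the longest exon of every gene whose longest exon exceeds the insert.

    The strict inequality matters: a read pair can only be fully contained in
    an exon longer than its insert.
    """
    if insert_size <= 0:
        raise ValueError("insert_size must be positive")
    return {
        g.gene_id: g.longest_exon
        for g in gene_models
        if g.longest_exon_length > insert_size
    }


# ---------------------------------------------------------------------------
# Gene screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    passed: bool
    reasons: list[str]
    counts: dict[str, int]


def screen_gene(
    alignment: Alignment | Iterable[str],
    clade_map: Mapping[str, str],
    min_per_clade: int = 4,
    min_total: int = 30,
    congener_clades: tuple[str, ...] = CONGENER_CLADES,
) -> ScreenResult:
    """Apply the three gene-retention criteria to one gene's sequence set.

    (i) every congener contributes at least one sequence; (ii) every nuclear
    clade has at least ``min_per_clade`` sequences; (iii) the total sequence
    count (all sequences, congeners included) reaches ``min_total``. All
    thresholds are inclusive ("at least").
    """
    ids = alignment.ids if isinstance(alignment, Alignment) else list(alignment)
    counts: dict[str, int] = {}
    for seq_id in ids:
        if seq_id not in clade_map:
            raise KeyError(f"sequence {seq_id!r} missing from clade map")
        clade = clade_map[seq_id]
        counts[clade] = counts.get(clade, 0) + 1
    counts["total"] = len(ids)
    reasons = []
    for cong in congener_clades:
        if counts.get(cong, 0) < 1:
            reasons.append(f"missing_congener:{cong}")
    for clade in NUCLEAR_CLADES:
        if counts.get(clade, 0) < min_per_clade:
            reasons.append(f"clade_below_min:{clade}")
    if counts["total"] < min_total:
        reasons.append("total_below_min")
    return ScreenResult(not reasons, reasons, counts)


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

def jc_distance_matrix(
    alignment: Alignment,
) -> tuple[list[str], np.ndarray, int]:
    """Jukes–Cantor distances on shared ungapped, non-N sites.

    Pairs with zero shared sites receive the maximum observed finite distance
    and are counted in the returned warning tally. Observed mismatch fractions
    at or beyond the JC saturation bound (3/4) are clipped just below it.
    """
    labels = alignment.ids
    mat = alignment.to_matrix()
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    pair_valid = valid[:, None, :] & valid[None, :, :]
    mismatch = (mat[:, None, :] != mat[None, :, :]) & pair_valid
    shared = pair_valid.sum(axis=2)
    mism = mismatch.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(shared > 0, mism / np.maximum(shared, 1), np.nan)
    p = np.clip(p, 0.0, _JC_MAX_P)
    d = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    np.fill_diagonal(d, 0.0)
    no_overlap = ~np.isfinite(d)
    n_warn = int(no_overlap.sum() // 2)
    if n_warn:
        finite = d[np.isfinite(d)]
        d[no_overlap] = finite.max() if finite.size else 1.0
    return labels, d, n_warn


class _NJNode:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=()):
        self.label = label
        self.children = tuple(children)  # (child, branch_length) pairs

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def _to_dendropy(root: _NJNode) -> dendropy.Tree:
    """Convert an _NJNode topology to a dendropy tree without newick parsing."""
    tree = dendropy.Tree()
    tns = tree.taxon_namespace

    def build(node: _NJNode, dnode: dendropy.Node) -> None:
        if not node.children:
            dnode.taxon = tns.new_taxon(label=node.label)
            return
        for child, length in node.children:
            cnode = dendropy.Node()
            cnode.edge.length = float(length)
            dnode.add_child(cnode)
            build(child, cnode)

    build(root, tree.seed_node)
    tree.is_rooted = False
    return tree


def neighbor_joining(labels: list[str], dist: np.ndarray) -> dendropy.Tree:
    """Deterministic neighbor joining; ties resolve in lexicographic label order.

    Input rows are sorted by label before clustering, and the minimum-Q pair is
    taken in row-major order, so identical inputs give identical trees. The
    result is an unrooted tree with a trifurcating root node; negative branch
    lengths are clipped to zero.
    """
    n = len(labels)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 sequences, got {n}")
    order = sorted(range(n), key=lambda i: labels[i])
    d = dist[np.ix_(order, order)].astype(float).copy()
    nodes: list[_NJNode] = [_NJNode(label=labels[i]) for i in order]

    while len(nodes) > 3:
        r = len(nodes)
        totals = d.sum(axis=1)
        q = (r - 2) * d - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = divmod(int(np.argmin(q)), r)
        if i > j:
            i, j = j, i
        bi = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (r - 2))
        bj = d[i, j] - bi
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        new_node = _NJNode(children=((nodes[i], bi), (nodes[j], bj)))
        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = np.maximum(d_new[keep], 0.0)
        nodes = [nodes[k] for k in keep] + [new_node]

    # join the final three nodes at an unrooted trifurcation
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    b0 = max(0.5 * (d01 + d02 - d12), 0.0)
    b1 = max(0.5 * (d01 + d12 - d02), 0.0)
    b2 = max(0.5 * (d02 + d12 - d01), 0.0)
    root = _NJNode(
        children=((nodes[0], b0), (nodes[1], b1), (nodes[2], b2))
    )
    return _to_dendropy(root)


def infer_gene_tree(alignment: Alignment, engine: str = "nj") -> dendropy.Tree:
    """Infer an unrooted tree for one gene alignment.

    The default (and currently only) engine is neighbor joining on JC-corrected
    distances; the ``engine`` slot exists so a likelihood engine can be swapped
    in for parity experiments.
    """
    if engine != "nj":
        raise ValueError(f"unknown tree engine {engine!r}")
    if len(alignment) < 4:
        raise ValueError(f"need >= 4 sequences, got {len(alignment)}")
    labels, dist, _ = jc_distance_matrix(alignment)
    return neighbor_joining(labels, dist)


def root_on_outgroup(
    tree: dendropy.Tree, outgroup_labels: str | Iterable[str],
    inplace: bool = False,
) -> dendropy.Tree:
    """Root a tree so the outgroup (leaf or its clade) is sister to the rest."""
    if isinstance(outgroup_labels, str):
        outgroup_labels = [outgroup_labels]
    wanted = set(outgroup_labels)
    out = tree if inplace else tree.clone(depth=1)
    leaves = [
        lf for lf in out.leaf_node_iter()
        if (lf.taxon.label if lf.taxon else lf.label) in wanted
    ]
    if not leaves:
        raise ValueError(f"outgroup {sorted(wanted)} not found in tree")
    if len(leaves) == 1:
        target = leaves[0]
    else:
        target = out.mrca(taxa=[lf.taxon for lf in leaves])
        target_leaves = {lf.taxon.label for lf in target.leaf_iter()}
        if target_leaves != {
            lf.taxon.label if lf.taxon else lf.label for lf in leaves
        }:
            # outgroup not monophyletic under current rooting: fall back to
            # rooting on its first leaf (lexicographic)
            target = min(
                leaves, key=lambda lf: lf.taxon.label if lf.taxon else lf.label
            )
    edge = target.edge
    if edge.tail_node is None:
        return out  # already the root
    length = edge.length or 0.0
    out.reroot_at_edge(edge, length1=length / 2, length2=length / 2)
    out.is_rooted = True
    return out


# ---------------------------------------------------------------------------
# Nesting utilities (shared with placement)
# ---------------------------------------------------------------------------

def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon else node.label


def sister_group(
    tree: dendropy.Tree, leaf_label: str, ignore: Iterable[str] = ()
) -> list[str]:
    """Leaf labels of the query leaf's sister group in a rooted tree.

    The sister group is the set of leaves under the query's parent, excluding
    the query itself and any ``ignore`` labels; if that set is empty the search
    walks toward the root until a non-empty group is found.
    """
    ignored = set(ignore) | {leaf_label}
    target = None
    for lf in tree.leaf_node_iter():
        if _leaf_label(lf) == leaf_label:
            target = lf
            break
    if target is None:
        raise ValueError(f"leaf {leaf_label!r} not in tree")
    node = target.parent_node
    prev = target
    while node is not None:
        labels = [
            _leaf_label(lf)
            for child in node.child_nodes()
            if child is not prev
            for lf in ([child] if child.is_leaf() else child.leaf_iter())
            if _leaf_label(lf) not in ignored
        ]
        if labels:
            return sorted(labels)
        prev, node = node, node.parent_node
    return []


def nested_clade(
    sister_labels: Iterable[str],
    clade_map: Mapping[str, str],
    nuclear_clades: tuple[str, ...] = NUCLEAR_CLADES,
) -> str | None:
    """The single nuclear clade a sister group belongs to, else None."""
    clades = {clade_map.get(lbl, "?") for lbl in sister_labels}
    if len(clades) == 1:
        clade = clades.pop()
        if clade in nuclear_clades:
            return clade
    return None


def f1_filter(
    rooted_tree: dendropy.Tree,
    f1_allele_ids: Iterable[str],
    clade_map: Mapping[str, str],
    required_clades: tuple[str, str] = ("I", "IV"),
    ignore: Iterable[str] = (),
) -> bool:
    """Is the gene informative: one F1 allele nested in each required clade?

    Nesting means the allele's sister group consists exclusively of leaves of
    one nuclear clade. The two F1 alleles must land one in clade I (the C3
    parent) and one in clade IV (the C4 parent); anything else marks the gene
    as insufficiently variable or paralogous.
    """
    ids = list(f1_allele_ids)
    if len(ids) != 2:
        raise ValueError(f"expected exactly two F1 alleles, got {ids}")
    placements = []
    for fid in ids:
        sisters = sister_group(rooted_tree, fid, ignore=ignore)
        placements.append(nested_clade(sisters, clade_map))
    return sorted(p for p in placements if p is not None) == sorted(
        required_clades
    ) and None not in placements


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

@dataclass
class ReferenceConfig:
    min_per_clade: int = 4
    min_total: int = 30
    engine: str = "nj"
    root_clade: str = ROOT_CLADE
    f1_required_clades: tuple[str, str] = ("I", "IV")


@dataclass
class GeneEntry:
    gene_id: str
    alignment: Alignment
    tree: dendropy.Tree | None
    informative: bool
    drop_reason: str | None
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ReferencePanel:
    """Retained per-gene alignments and rooted trees, plus a full manifest."""

    genes: dict[str, GeneEntry]
    manifest: pd.DataFrame
    clade_map: dict[str, str]
    f1_ids: dict[str, list[str]]
    config: ReferenceConfig
    stage_counts: dict[str, int]

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.genes)


def _find_f1_ids(alignment: Alignment, clade_map: Mapping[str, str]) -> list[str]:
    return sorted(i for i in alignment.ids if clade_map.get(i) == "F1")


def build_reference(
    gene_alignments: Mapping[str, Alignment],
    clade_map: Mapping[str, str],
    config: ReferenceConfig | None = None,
) -> ReferencePanel:
    """Screen, build trees for, and F1-filter every gene alignment.

    ``gene_alignments`` maps gene id to an alignment of phased alleles plus
    congener sequences; ``clade_map`` assigns every sequence id a clade in
    {I..IV, outgroup1, outgroup2, F1}. The returned panel contains exactly the
    genes passing both the screening criteria and the F1 informativeness
    filter, with stage-wise counts for the report.
    """
    config = config or ReferenceConfig()
    entries: dict[str, GeneEntry] = {}
    rows = []
    n_screen = n_f1 = n_kept = 0
    f1_ids: dict[str, list[str]] = {}
    for gene_id in sorted(gene_alignments):
        aln = gene_alignments[gene_id]
        screen = screen_gene(
            aln, clade_map, config.min_per_clade, config.min_total
        )
        tree = None
        informative = False
        drop = None
        if not screen.passed:
            n_screen += 1
            drop = "screen:" + ";".join(screen.reasons)
        else:
            unrooted = infer_gene_tree(aln, engine=config.engine)
            root_ids = [
                i for i in aln.ids if clade_map.get(i) == config.root_clade
            ]
            tree = root_on_outgroup(unrooted, root_ids)
            ids = _find_f1_ids(aln, clade_map)
            f1_ids[gene_id] = ids
            informative = f1_filter(
                tree, ids, clade_map, config.f1_required_clades
            )
            if not informative:
                n_f1 += 1
                drop = "f1_filter"
            else:
                n_kept += 1
        if drop is None:
            entries[gene_id] = GeneEntry(
                gene_id, aln, tree, informative, None, screen.counts
            )
        row = {"gene_id": gene_id, "n_seqs": len(aln), "informative": informative,
               "drop_reason": drop or ""}
        for clade in NUCLEAR_CLADES + CONGENER_CLADES:
            row[f"n_{clade}"] = screen.counts.get(clade, 0)
        rows.append(row)
    stage_counts = {
        "input": len(gene_alignments),
        "failed_screen": n_screen,
        "failed_f1": n_f1,
        "retained": n_kept,
    }
    if not entries:
        raise ValueError(f"empty reference panel; stage counts: {stage_counts}")
    return ReferencePanel(
        genes=entries,
        manifest=pd.DataFrame(rows),
        clade_map=dict(clade_map),
        f1_ids={g: f1_ids.get(g, []) for g in entries},
        config=config,
        stage_counts=stage_counts,
    )


def write_panel(panel: ReferencePanel, directory: str | os.PathLike) -> None:
    """Serialize a panel as per-gene FASTA + Newick plus a TSV manifest."""
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    panel.manifest.to_csv(
        os.path.join(directory, "manifest.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [{"sequence_id": k, "clade": v} for k, v in sorted(panel.clade_map.items())]
    ).to_csv(os.path.join(directory, "clade_map.tsv"), sep="\t", index=False)
    for gene_id, entry in panel.genes.items():
        write_fasta(
            entry.alignment, os.path.join(directory, f"{gene_id}.fasta")
        )
        if entry.tree is not None:
            entry.tree.write(
                path=os.path.join(directory, f"{gene_id}.nwk"), schema="newick",
                unquoted_underscores=True,
            )


def load_panel(
    directory: str | os.PathLike, config: ReferenceConfig | None = None
) -> ReferencePanel:
    """Load a panel directory written by :func:`write_panel`."""
    directory = str(directory)
    manifest = pd.read_csv(
        os.path.join(directory, "manifest.tsv"), sep="\t",
        keep_default_na=False, na_values=[],
    )
    clade_df = pd.read_csv(os.path.join(directory, "clade_map.tsv"), sep="\t")
    clade_map = dict(zip(clade_df["sequence_id"], clade_df["clade"]))
    genes: dict[str, GeneEntry] = {}
    f1_ids: dict[str, list[str]] = {}
    for row in manifest.itertuples(index=False):
        if row.drop_reason:
            continue
        gene_id = row.gene_id
        fasta = os.path.join(directory, f"{gene_id}.fasta")
        if not os.path.exists(fasta):
            raise ParseError(f"panel missing FASTA for retained gene {gene_id}")
        aln = Alignment(read_fasta(fasta))
        tree = dendropy.Tree.get(
            path=os.path.join(directory, f"{gene_id}.nwk"),
            schema="newick", preserve_underscores=True,
        )
        tree.is_rooted = True
        genes[gene_id] = GeneEntry(gene_id, aln, tree, True, None, {})
        f1_ids[gene_id] = _find_f1_ids(aln, clade_map)
    retained = len(genes)
    return ReferencePanel(
        genes=genes,
        manifest=manifest,
        clade_map=clade_map,
        f1_ids=f1_ids,
        config=config or ReferenceConfig(),
        stage_counts={"input": len(manifest), "retained": retained},
    )
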
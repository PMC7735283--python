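"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: a rooted species tree with
two outgroup lineages and four ingroup nuclear clades, per-gene coalescent
gene trees (so loci disagree, as under incomplete lineage sorting), sequences
evolved site-independently under a two-parameter substitution model, diploid
individuals carrying two phased alleles per gene, an F1 hybrid with one
clade-I and one clade-IV allele, polyploids assembled as known mixtures of
clade subgenomes, and paired-end reads shredded from the alleles with
configurable error — every read pair carrying a truth label of its clade of
origin so each pipeline stage can be scored.

Two features of real data are deliberately absent: indels/structural variation
(reads are ungapped relative to their exon) and realistic quality-score
profiles (qualities encode the configured error rate uniformly).
"""

from __future__ import annotations

import dataclasses
import math
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .io_core import Alignment, Sequence, write_fasta, write_fastq
from .msc_sim import GeneTreeNode, compile_species_tree, _simulate_compiled, tree_from_newick
from .allele_reference import NUCLEAR_CLADES

_BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

#: species tree emulating the nuclear backbone: four ingroup clades with
#: clade II sister to (III,IV), two successively deeper outgroups. Node ages
#: (coalescent units): (III,IV)=4, +II=5, +I=6, +outgroup1=8, root=10. Long
#: terminal branches let within-clade lineages coalesce, so clades are almost
#: always monophyletic per gene while still heterogeneous across loci.
DEFAULT_SPECIES_TREE = (
    "(outgroup2:10,(outgroup1:8,(I:6,(II:5,(III:4,IV:4):1):1):2):2);"
)


@dataclass
class PolyploidSpec:
    """A polyploid as a mixture of clade subgenomes, e.g. 2:2:2 over II/III/IV."""

    individual_id: str
    composition: list[tuple[str, int]]

    @property
    def ploidy(self) -> int:
        return sum(n for _, n in self.composition)


def default_polyploids() -> list[PolyploidSpec]:
    return [
        PolyploidSpec("hex1", [("II", 2), ("III", 2), ("IV", 2)]),
        PolyploidSpec("dod1", [("II", 4), ("III", 4), ("IV", 4)]),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 50
    exon_length_range: tuple[int, int] = (600, 900)
    diploids_per_clade: int = 4
    species_tree_newick: str = DEFAULT_SPECIES_TREE
    #: substitutions per site per coalescent unit
    rate_per_unit: float = 0.01
    #: transition/transversion rate ratio of the substitution model
    kappa: float = 2.0
    read_length: int = 250
    insert_size: int = 550
    #: mean sequencing coverage per haploid genome copy (per allele)
    depth: float = 20.0
    error_rate: float = 0.0
    include_f1: bool = True
    f1_id: str = "F1"
    f1_parents: tuple[str, str] = ("I", "IV")
    polyploids: list[PolyploidSpec] = field(default_factory=default_polyploids)

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length")
        if self.n_genes <= 0 or self.diploids_per_clade <= 0:
            raise ValueError("counts must be positive")

    @property
    def base_quality(self) -> int:
        if self.error_rate == 0:
            return 40
        return int(round(-10 * math.log10(self.error_rate)))


@dataclass
class IndividualInfo:
    individual_id: str
    kind: str  # diploid | f1 | polyploid | congener
    clades: list[tuple[str, int]]  # (clade, n alleles per gene)

    @property
    def ploidy(self) -> int:
        return sum(n for _, n in self.clades)


@dataclass
class GeneData:
    gene_id: str
    exon_length: int
    gene_tree: GeneTreeNode
    alleles: Alignment  # individual-labelled allele sequences (all individuals)
    allele_clades: dict[str, str]  # allele id -> clade of origin
    diagnostic_sites: dict[str, list[int]]  # clade -> 0-based positions
    flank_left: str
    flank_right: str

    @property
    def scaffold_offset(self) -> int:
        return len(self.flank_left)

    @property
    def exon_interval(self) -> tuple[int, int]:
        off = self.scaffold_offset
        return (off, off + self.exon_length)

    def scaffold(self, allele_id: str) -> str:
        return self.flank_left + self.alleles.get(allele_id).residues + self.flank_right


@dataclass
class SyntheticBundle:
    """Everything one generator run produced, ready for the pipeline."""

    config: SimulationConfig
    individuals: dict[str, IndividualInfo]
    genes: dict[str, GeneData]
    clade_map: dict[str, str]  # panel sequence id -> clade (F1 alleles -> "F1")
    reads: pd.DataFrame  # aligned-read table (scaffold coordinates)
    truth_pairs: pd.DataFrame

    @property
    def panel_individuals(self) -> list[str]:
        return [
            i.individual_id
            for i in self.individuals.values()
            if i.kind in ("diploid", "f1")
        ]

    def panel_alignments(self) -> dict[str, Alignment]:
        """Per-gene alignments of the true panel alleles (diploids+F1+congeners)."""
        out = {}
        for gene_id, gd in self.genes.items():
            out[gene_id] = Alignment(
                s for s in gd.alleles if s.id in self.clade_map
            )
        return out


# ---------------------------------------------------------------------------
# Individuals and allele allocation
# ---------------------------------------------------------------------------

def plan_individuals(config: SimulationConfig) -> dict[str, IndividualInfo]:
    """Deterministic roster: diploids per clade, the F1 hybrid, polyploids,
    and one sequence per congener."""
    roster: dict[str, IndividualInfo] = {}
    for clade in NUCLEAR_CLADES:
        for i in range(1, config.diploids_per_clade + 1):
            ind = f"{clade}d{i}"
            roster[ind] = IndividualInfo(ind, "diploid", [(clade, 2)])
    if config.include_f1:
        a, b = config.f1_parents
        roster[config.f1_id] = IndividualInfo(
            config.f1_id, "f1", [(a, 1), (b, 1)]
        )
    for spec in config.polyploids:
        if spec.individual_id in roster:
            raise ValueError(f"duplicate individual {spec.individual_id}")
        roster[spec.individual_id] = IndividualInfo(
            spec.individual_id, "polyploid", list(spec.composition)
        )
    roster["cong1"] = IndividualInfo("cong1", "congener", [("outgroup1", 1)])
    roster["cong2"] = IndividualInfo("cong2", "congener", [("outgroup2", 1)])
    return roster


def _samples_per_species(roster: dict[str, IndividualInfo]) -> dict[str, int]:
    need: dict[str, int] = {}
    for info in roster.values():
        for clade, n in info.clades:
            need[clade] = need.get(clade, 0) + n
    return need


def _allele_allocation(
    roster: dict[str, IndividualInfo], gene_id: str
) -> list[tuple[str, str, str]]:
    """(pool label, allele id, clade) per allele; pool labels are the gene-tree
    leaf names ``{species}^{k}``. Allocation is without replacement within each
    clade, so polyploid subgenomes come from distinct simulated lineages."""
    next_index: dict[str, int] = {}
    rows = []
    for ind in sorted(roster):
        info = roster[ind]
        hap = 0
        for clade, n in info.clades:
            for _ in range(n):
                k = next_index.get(clade, 0)
                next_index[clade] = k + 1
                hap += 1
                if info.kind == "congener":
                    allele_id = f"{ind}_{gene_id}"
                elif info.kind in ("diploid", "f1"):
                    allele_id = f"{ind}_{gene_id}_h{hap}"
                else:
                    allele_id = f"{ind}_{gene_id}_a{hap}"
                rows.append((f"{clade}^{k}", allele_id, clade))
    return rows


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def transition_matrix(t: float, kappa: float) -> np.ndarray:
    """Two-parameter (transition-biased) substitution probabilities for a
    branch of expected length ``t`` substitutions per site."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    q = np.full((4, 4), 1.0)
    # order A C G T; transitions A<->G (0,2) and C<->T (1,3)
    q[0, 2] = q[2, 0] = q[1, 3] = q[3, 1] = kappa
    np.fill_diagonal(q, 0.0)
    q /= q.sum(axis=1).mean()  # mean rate 1 under uniform base frequencies
    np.fill_diagonal(q, -q.sum(axis=1))
    # q is symmetric, so the exponential comes from an orthogonal eigenbasis
    w, v = np.linalg.eigh(q * t)
    p = (v * np.exp(w)) @ v.T
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


def _evolve_sequences(
    root: GeneTreeNode,
    length: int,
    rate: float,
    kappa: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Site-independent evolution along the gene tree; returns base indices."""
    out: dict[str, np.ndarray] = {}

    def walk(node: GeneTreeNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            out[node.label] = seq
            return
        for child in node.children:
            t = (node.height - child.height) * rate
            if t <= 0:
                child_seq = seq.copy()
            else:
                p_cum = np.cumsum(transition_matrix(t, kappa), axis=1)
                u = rng.random(length)
                child_seq = np.empty(length, dtype=np.int8)
                for b in range(4):
                    idx = np.flatnonzero(seq == b)
                    child_seq[idx] = np.searchsorted(p_cum[b], u[idx], side="right")
            walk(child, np.minimum(child_seq, 3))

    root_seq = rng.integers(0, 4, size=length).astype(np.int8)
    walk(root, root_seq)
    return out


def _diagnostic_sites(
    seqs: dict[str, np.ndarray], clade_of: dict[str, str]
) -> dict[str, list[int]]:
    """Positions where one clade's alleles share a base absent elsewhere."""
    labels = list(seqs)
    mat = np.stack([seqs[l] for l in labels])
    out: dict[str, list[int]] = {}
    for clade in NUCLEAR_CLADES:
        inside = np.array([clade_of[l] == clade for l in labels])
        if not inside.any() or inside.all():
            out[clade] = []
            continue
        sub = mat[inside]
        rest = mat[~inside]
        fixed = (sub == sub[0]).all(axis=0)
        absent = (rest != sub[0]).all(axis=0)
        out[clade] = [int(i) for i in np.flatnonzero(fixed & absent)]
    return out


def simulate_alleles(
    config: SimulationConfig,
    roster: dict[str, IndividualInfo] | None = None,
) -> dict[str, GeneData]:
    """Per gene: a coalescent gene tree over all required samples, evolved
    sequences, individual-labelled alleles, flanks, and diagnostic sites."""
    roster = roster or plan_individuals(config)
    species_tree = tree_from_newick(config.species_tree_newick)
    compiled = compile_species_tree(species_tree)
    samples = _samples_per_species(roster)
    tip_labels = {
        lf.taxon.label if lf.taxon else lf.label
        for lf in species_tree.leaf_node_iter()
    }
    unknown = sorted(set(samples) - tip_labels)
    if unknown:
        raise ValueError(
            f"individuals request alleles from unknown clades {unknown}; "
            f"species tree tips are {sorted(tip_labels)}"
        )
    lo, hi = config.exon_length_range
    genes: dict[str, GeneData] = {}
    for g in range(config.n_genes):
        gene_id = f"g{g + 1:03d}"
        rng = np.random.default_rng((config.seed, 1, g))
        length = int(rng.integers(lo, hi + 1))
        tree = _simulate_compiled(compiled, samples, rng)
        seqs = _evolve_sequences(
            tree, length, config.rate_per_unit, config.kappa, rng
        )
        allocation = _allele_allocation(roster, gene_id)
        clade_of_pool = {pool: clade for pool, _, clade in allocation}
        diag = _diagnostic_sites(
            {p: seqs[p] for p, _, _ in allocation}, clade_of_pool
        )
        alleles = Alignment(
            Sequence(allele_id, "".join(_BASES[b] for b in seqs[pool]))
            for pool, allele_id, _ in allocation
        )
        allele_clades = {aid: clade for _, aid, clade in allocation}
        flank_len = config.insert_size
        flanks = rng.integers(0, 4, size=2 * flank_len)
        genes[gene_id] = GeneData(
            gene_id=gene_id,
            exon_length=length,
            gene_tree=tree,
            alleles=alleles,
            allele_clades=allele_clades,
            diagnostic_sites=diag,
            flank_left="".join(_BASES[b] for b in flanks[:flank_len]),
            flank_right="".join(_BASES[b] for b in flanks[flank_len:]),
        )
    return genes


def make_individuals(
    genes: dict[str, GeneData], roster: dict[str, IndividualInfo]
) -> dict[str, str]:
    """Clade map over panel sequences (diploid/F1 alleles and congeners).

    Diploid alleles carry their individual's clade; the F1 hybrid's alleles are
    labelled "F1" (they belong to no single clade); congeners map to their
    outgroup labels. Polyploid alleles are not panel members — they exist only
    to be shredded into reads.
    """
    clade_map: dict[str, str] = {}
    for gene_id, gd in genes.items():
        for allele_id, clade in gd.allele_clades.items():
            ind = allele_id.split("_")[0]
            info = roster[ind]
            if info.kind == "diploid":
                clade_map[allele_id] = clade
            elif info.kind == "f1":
                clade_map[allele_id] = "F1"
            elif info.kind == "congener":
                clade_map[allele_id] = clade  # outgroup1 / outgroup2
    return clade_map


# ---------------------------------------------------------------------------
# Read shredding
# ---------------------------------------------------------------------------

def shred_reads(
    bundle_genes: dict[str, GeneData],
    roster: dict[str, IndividualInfo],
    config: SimulationConfig,
    individuals: Iterable[str] | None = None,
    tile: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shred each individual's alleles into paired 250 bp reads.

    Fragments of ``insert_size`` are drawn per allele at ``config.depth`` mean
    per-copy coverage; starts are uniform over the exon including flanking
    overhang (so mapped coverage is uniform along the exon, and only a subset
    of pairs is fully contained in it), or evenly tiled when ``tile`` is set.
    Mate 1 is the left fragment end; mate 2 is the right end and is stored in
    reference orientation here (FASTQ export reverse-complements it). Per-base
    errors are iid at ``error_rate``; quality strings encode that rate.

    Returns the aligned-read table and the pair truth table.
    """
    rl, ins = config.read_length, config.insert_size
    qual_char = chr(config.base_quality + 33)
    rows = []
    truth_rows = []
    chosen = set(individuals) if individuals is not None else None
    for gene_id in sorted(bundle_genes):
        gd = bundle_genes[gene_id]
        L = gd.exon_length
        if L < ins:  # exon shorter than insert: skipped, no pairs possible
            continue
        span = L + ins - 1  # number of admissible fragment starts
        for ind in sorted(roster):
            info = roster[ind]
            if info.kind == "congener":
                continue
            if chosen is not None and ind not in chosen:
                continue
            allele_ids = sorted(
                aid for aid, _ in gd.allele_clades.items()
                if aid.startswith(f"{ind}_")
            )
            rng = np.random.default_rng(
                (config.seed, 2, _stable_index(gene_id), _stable_index(ind))
            )
            for aid in allele_ids:
                scaffold = gd.scaffold(aid)
                off = gd.scaffold_offset
                n_frags = int(round(config.depth * span / (2 * rl)))
                if tile:
                    starts = np.linspace(-(ins - 1), L - 1, max(n_frags, 1))
                    starts = np.unique(np.round(starts).astype(int))
                else:
                    starts = rng.integers(-(ins - 1), L, size=n_frags)
                clade = gd.allele_clades[aid]
                for i, s in enumerate(starts):
                    pair_id = f"{ind}|{gene_id}|{aid.split('_')[-1]}|p{i:04d}"
                    frag_start = off + int(s)
                    m1 = scaffold[frag_start : frag_start + rl]
                    m2_start = frag_start + ins - rl
                    m2 = scaffold[m2_start : m2_start + rl]
                    m1, m2 = _apply_errors(m1, rng, config.error_rate), \
                        _apply_errors(m2, rng, config.error_rate)
                    for mate, seq, start in ((1, m1, frag_start), (2, m2, m2_start)):
                        rows.append(
                            {
                                "individual_id": ind,
                                "gene_id": gene_id,
                                "pair_id": pair_id,
                                "mate": mate,
                                "start": start,
                                "residues": seq,
                                "qualities": qual_char * len(seq),
                                "truth_clade": clade,
                                "source_allele": aid,
                            }
                        )
                    truth_rows.append(
                        {
                            "individual_id": ind,
                            "pair_id": pair_id,
                            "gene_id": gene_id,
                            "truth_clade": clade,
                            "source_allele": aid,
                        }
                    )
    reads = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def _stable_index(label: str) -> int:
    """Small deterministic integer from a label (for seed derivation)."""
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASE_ARR, arr[hits])
        arr[hits] = _BASE_ARR[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Bundle generation and serialization
# ---------------------------------------------------------------------------

def generate_dataset(
    config: SimulationConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> SyntheticBundle:
    """One call producing everything the pipeline consumes end to end."""
    config = config or SimulationConfig()
    roster = plan_individuals(config)
    genes = simulate_alleles(config, roster)
    clade_map = make_individuals(genes, roster)
    reads, truth = shred_reads(genes, roster, config)
    bundle = SyntheticBundle(
        config=config,
        individuals=roster,
        genes=genes,
        clade_map=clade_map,
        reads=reads,
        truth_pairs=truth,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SyntheticBundle, out_dir: str | os.PathLike) -> None:
    """Write the bundle atomically (temp directory, then rename)."""
    out_dir = str(out_dir)
    parent = os.path.dirname(os.path.abspath(out_dir)) or "."
    os.makedirs(parent, exist_ok=True)
    tmp = tempfile.mkdtemp(prefix=".bundle_", dir=parent)
    try:
        os.makedirs(os.path.join(tmp, "alleles"))
        os.makedirs(os.path.join(tmp, "trees"))
        os.makedirs(os.path.join(tmp, "reads"))
        cfg = dataclasses.asdict(bundle.config)
        cfg["polyploids"] = [
            {"individual_id": p["individual_id"], "composition": p["composition"]}
            for p in cfg["polyploids"]
        ]
        with open(os.path.join(tmp, "config.yaml"), "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        rows = []
        for gene_id in sorted(bundle.genes):
            gd = bundle.genes[gene_id]
            write_fasta(
                gd.alleles, os.path.join(tmp, "alleles", f"{gene_id}.fasta")
            )
            with open(os.path.join(tmp, "trees", f"{gene_id}.nwk"), "w") as fh:
                fh.write(gd.gene_tree.newick() + "\n")
            rows.append(
                {
                    "gene_id": gene_id,
                    "exon_length": gd.exon_length,
                    **{
                        f"n_diagnostic_{c}": len(gd.diagnostic_sites[c])
                        for c in NUCLEAR_CLADES
                    },
                }
            )
        pd.DataFrame(rows).to_csv(
            os.path.join(tmp, "genes.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            [
                {"sequence_id": k, "individual_id": k.split("_")[0], "clade": v}
                for k, v in sorted(bundle.clade_map.items())
            ]
        ).to_csv(os.path.join(tmp, "clade_map.tsv"), sep="\t", index=False)
        bundle.reads.to_csv(
            os.path.join(tmp, "reads", "reads.tsv"), sep="\t", index=False
        )
        bundle.truth_pairs.to_csv(
            os.path.join(tmp, "truth_pairs.tsv"), sep="\t", index=False
        )
        for ind in sorted(bundle.reads["individual_id"].unique()):
            sub = bundle.reads[bundle.reads["individual_id"] == ind]
            for mate, suffix in ((1, "R1"), (2, "R2")):
                msub = sub[sub["mate"] == mate]
                seqs = []
                for row in msub.itertuples(index=False):
                    seq = Sequence(
                        f"{row.pair_id}/{mate}",
                        row.residues,
                        [ord(c) - 33 for c in row.qualities],
                    )
                    if mate == 2:
                        seq = Sequence(seq.id, seq.reverse_complement().residues,
                                       seq.qualities[::-1])
                    seqs.append(seq)
                write_fastq(
                    seqs, os.path.join(tmp, "reads", f"{ind}_{suffix}.fastq")
                )
        if os.path.exists(out_dir):
            raise FileExistsError(f"refusing to overwrite {out_dir}")
        os.replace(tmp, out_dir)
    except Exception:
        import shutil

        shutil.rmtree(tmp, ignore_errors=True)
        raise
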
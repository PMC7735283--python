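"""End-to-end orchestration: phase diploids, build the panel, place reads.

The drivers in ``analysis/`` and the acceptance machinery are thin wrappers
around these functions, which connect the synthetic bundle (or equivalently
structured real inputs) to the phasing, reference-building and placement
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_core import Alignment, Sequence
from .allele_reference import (
    GeneModel,
    ReferenceConfig,
    ReferencePanel,
    build_reference,
    select_candidate_exons,
)
from .phasing import AlignedRead, DepthPolicy, phase_individual_gene
from .placement import (
    CompositionProfile,
    PlacementConfig,
    PlacementResult,
    compose_profile,
    leave_one_out_panel,
    pairs_from_frame,
    place_pairs_for_gene,
    select_overlapping_pairs,
)
from .synthetic_data import SyntheticBundle


def candidate_genes(bundle: SyntheticBundle) -> list[str]:
    """Genes whose (single) exon is longer than the sequencing insert size.

    Only such exons can fully contain a read pair, so all downstream stages
    are restricted to them.
    """
    models = [
        GeneModel(gene_id, [(0, gd.exon_length)])
        for gene_id, gd in bundle.genes.items()
    ]
    return sorted(select_candidate_exons(models, bundle.config.insert_size))


def exon_local_reads(
    bundle: SyntheticBundle, individual: str, gene_id: str
) -> list[AlignedRead]:
    """The individual's reads for one gene, clipped to exon coordinates.

    Emulates what a mapper reports against an exon reference: read portions
    overhanging the exon are soft-clipped away; reads entirely outside are
    dropped.
    """
    gd = bundle.genes[gene_id]
    off, end = gd.exon_interval
    df = bundle.reads
    sub = df[(df["individual_id"] == individual) & (df["gene_id"] == gene_id)]
    reads = []
    for row in sub.itertuples(index=False):
        start, residues = int(row.start), row.residues
        quals = [ord(c) - 33 for c in row.qualities]
        lo = max(start, off)
        hi = min(start + len(residues), end)
        if hi <= lo:
            continue
        reads.append(
            AlignedRead(
                read_id=f"{row.pair_id}/{row.mate}",
                mate=int(row.mate),
                start=lo - off,
                residues=residues[lo - start : hi - start],
                qualities=quals[lo - start : hi - start],
                pair_id=row.pair_id,
            )
        )
    return reads


def phase_panel_individuals(
    bundle: SyntheticBundle,
    policy: DepthPolicy | None = None,
    min_base_quality: int = 20,
) -> tuple[dict[str, Alignment], pd.DataFrame]:
    """Phase every diploid (and the F1) from reads, per gene; add congeners.

    Returns per-gene alignments of phased alleles plus the true congener
    sequences (congeners are externally provided reference sequences, not
    phased here), and a per-(individual, gene) phasing report.
    """
    if policy is None:
        # both haplotypes contribute, so expected per-site depth is twice the
        # per-copy coverage
        policy = DepthPolicy.for_depth(2 * bundle.config.depth)
    rows = []
    genes = candidate_genes(bundle)
    per_gene: dict[str, list[Sequence]] = {g: [] for g in genes}
    for gene_id in genes:
        gd = bundle.genes[gene_id]
        for ind in bundle.panel_individuals:
            reads = exon_local_reads(bundle, ind, gene_id)
            alleles, result = phase_individual_gene(
                reads, ind, gene_id, policy, min_base_quality,
                ref_length=gd.exon_length,
            )
            for allele in alleles:
                per_gene[gene_id].append(
                    Sequence(allele.fasta_id, allele.residues)
                )
            rows.append(
                {
                    "individual_id": ind,
                    "gene_id": gene_id,
                    "n_het_sites": len(result.het_sites),
                    "n_masked_sites": len(result.masked_sites),
                    "n_alleles_kept": len(alleles),
                    **{
                        k: v
                        for k, v in result.stats.items()
                        if isinstance(v, int)
                    },
                }
            )
        for seq in gd.alleles:
            if bundle.clade_map.get(seq.id) in ("outgroup1", "outgroup2"):
                per_gene[gene_id].append(seq)
    alignments = {g: Alignment(seqs) for g, seqs in per_gene.items() if seqs}
    return alignments, pd.DataFrame(rows)


def phased_clade_map(
    bundle: SyntheticBundle, alignments: dict[str, Alignment]
) -> dict[str, str]:
    """Clade labels for phased allele ids (haplotype order may differ from
    truth, but both haplotypes of an individual share its clade)."""
    out: dict[str, str] = {}
    for gene_id, aln in alignments.items():
        for seq_id in aln.ids:
            ind = seq_id.split("_")[0]
            info = bundle.individuals[ind]
            if info.kind == "diploid":
                out[seq_id] = info.clades[0][0]
            elif info.kind == "f1":
                out[seq_id] = "F1"
            else:
                out[seq_id] = info.clades[0][0]  # congener outgroup label
    return out


def build_panel_from_bundle(
    bundle: SyntheticBundle,
    use_true_alleles: bool = False,
    reference_config: ReferenceConfig | None = None,
) -> tuple[ReferencePanel, dict[str, str]]:
    """Build the reference panel, from phased reads or from the true alleles."""
    if use_true_alleles:
        keep = set(candidate_genes(bundle))
        alignments = {
            g: a for g, a in bundle.panel_alignments().items() if g in keep
        }
        clade_map = dict(bundle.clade_map)
    else:
        alignments, _ = phase_panel_individuals(bundle)
        clade_map = phased_clade_map(bundle, alignments)
    panel = build_reference(alignments, clade_map, reference_config)
    return panel, clade_map


@dataclass
class IndividualPlacement:
    individual_id: str
    placements: list[PlacementResult]
    profile: CompositionProfile
    skipped_genes: list[str] = field(default_factory=list)


def place_individual(
    bundle: SyntheticBundle,
    panel: ReferencePanel,
    individual: str,
    leave_out: bool = False,
    config: PlacementConfig | None = None,
) -> IndividualPlacement:
    """Select contained pairs and place them gene by gene for one individual.

    With ``leave_out`` the individual's own alleles are removed from every
    gene alignment first and genes failing re-screening are skipped — the
    calibration mode used for diploids and the F1 hybrid.
    """
    config = config or PlacementConfig()
    skipped: list[str] = []
    if leave_out:
        gene_entries, skipped = leave_one_out_panel(panel, individual)
    else:
        gene_entries = panel.genes
    df = bundle.reads
    sub = df[df["individual_id"] == individual]
    placements: list[PlacementResult] = []
    for gene_id in sorted(gene_entries):
        entry = gene_entries[gene_id]
        gdf = sub[sub["gene_id"] == gene_id]
        if gdf.empty:
            continue
        pairs = pairs_from_frame(gdf)
        selected = select_overlapping_pairs(
            pairs, bundle.genes[gene_id].exon_interval, config.containment
        )
        f1_ids = [
            i for i in entry.alignment.ids
            if panel.clade_map.get(i) == "F1"
        ]
        placements.extend(
            place_pairs_for_gene(
                entry, selected, panel.clade_map, f1_ids, config
            )
        )
    profile = compose_profile(placements, individual)
    return IndividualPlacement(individual, placements, profile, skipped)


def placements_table(results: list[IndividualPlacement]) -> pd.DataFrame:
    rows = []
    for res in results:
        for p in res.placements:
            rows.append(
                {
                    "individual": res.individual_id,
                    "pair_id": p.pair_id,
                    "gene_id": p.gene_id,
                    "assigned_clade": p.assigned_clade or "",
                    "status": p.status or "assigned",
                    "truth_clade": p.truth_clade or "",
                }
            )
    return pd.DataFrame(rows)
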
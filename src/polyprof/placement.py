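"""Phylogenetic placement of read pairs into clade-labelled gene alignments.

Polyploids cannot be phased read-by-read, so each read pair is placed
independently: pairs fully contained in a panel exon are merged into a single
partial sequence, profile-aligned onto the gene alignment (panel columns are
never altered; read bases inserted relative to the panel are dropped and
counted), the alignment is trimmed to the read span (at most 500 columns), a
tree is re-inferred and rooted, and the pair is assigned to the nuclear clade
its sister group belongs to. Assignments are discarded when the F1-hybrid
control alleles are no longer correctly placed after trimming, or when the
sister group mixes lineages from several clades. Per-individual tallies of
assigned reads give the genome-composition profile; running diploids with
their own alleles left out of the panel provides the calibration.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align

from .io_core import Alignment, Sequence
from .allele_reference import (
    CONGENER_CLADES,
    NUCLEAR_CLADES,
    ReferencePanel,
    ReferenceConfig,
    GeneEntry,
    infer_gene_tree,
    nested_clade,
    root_on_outgroup,
    screen_gene,
    sister_group,
    f1_filter,
)

DISCARD_STATUSES = (
    "discarded_f1_check",
    "discarded_mixed_sister",
    "discarded_short",
    "unplaced",
)


@dataclass
class ReadPair:
    """A paired-end fragment with per-mate coordinates on the gene scaffold."""

    pair_id: str
    individual_id: str
    mate1: Sequence
    mate2: Sequence
    gene_id: str | None = None
    interval1: tuple[int, int] | None = None  # 0-based half-open
    interval2: tuple[int, int] | None = None
    truth_clade: str | None = None


@dataclass
class PlacementResult:
    pair_id: str
    gene_id: str
    assigned_clade: str | None = None
    status: str | None = None
    truth_clade: str | None = None

    def __post_init__(self) -> None:
        if (self.assigned_clade is None) == (self.status is None):
            raise ValueError("exactly one of assigned_clade / status must be set")


@dataclass
class PlacementConfig:
    max_len: int = 500
    min_len: int = 250
    #: a mate is placed only if its local alignment score reaches this fraction
    #: of its length (match +1), which shuts out random sequence
    min_score_frac: float = 0.4
    containment: str = "mates"  # or "fragment"
    engine: str = "nj"


# ---------------------------------------------------------------------------
# Pair selection
# ---------------------------------------------------------------------------

def select_overlapping_pairs(
    read_pairs: Iterable[ReadPair],
    exon_interval: tuple[int, int],
    mode: str = "mates",
) -> list[ReadPair]:
    """Pairs whose reads are fully contained in the exon interval.

    ``mode="mates"`` requires each mate's interval inside the exon;
    ``mode="fragment"`` requires the full fragment span (including the
    unsequenced inter-mate region) inside. For end-pair mates the two
    coincide; both are exposed so either reading of full containment can be
    enforced explicitly.
    """
    s, e = exon_interval
    selected = []
    for pair in read_pairs:
        if pair.interval1 is None or pair.interval2 is None:
            raise ValueError(f"{pair.pair_id}: pair has no coordinates")
        if mode == "mates":
            ok = all(
                s <= a and b <= e for a, b in (pair.interval1, pair.interval2)
            )
        elif mode == "fragment":
            span = (
                min(pair.interval1[0], pair.interval2[0]),
                max(pair.interval1[1], pair.interval2[1]),
            )
            ok = s <= span[0] and span[1] <= e
        else:
            raise ValueError(f"unknown containment mode {mode!r}")
        if ok:
            selected.append(pair)
    return selected


# ---------------------------------------------------------------------------
# Profile addition of a merged pair
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner


def _panel_consensus(alignment: Alignment) -> str:
    mat = alignment.to_matrix()
    cols = []
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        counts = [(col == c).sum() for c in codes]
        best = int(np.argmax(counts))
        cols.append("ACGT"[best] if counts[best] > 0 else "N")
    return "".join(cols)


@dataclass
class AddResult:
    alignment: Alignment
    merged_id: str
    dropped_insertions: int
    mate_scores: tuple[float | None, float | None]


def add_pair_to_alignment(
    gene_alignment: Alignment,
    pair: ReadPair,
    config: PlacementConfig | None = None,
    consensus: str | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> AddResult | None:
    """Merge a read pair into one row aligned against the panel columns.

    Each mate (in its better-scoring orientation) is locally aligned to the
    panel consensus; aligned bases are written into a row of panel width, read
    bases inserted relative to the panel are dropped and counted, and the
    unsequenced inter-mate region and flanks stay as missing data (N). A mate
    whose score falls below the floor contributes nothing; if neither mate
    clears the floor the pair is unplaceable and None is returned.
    """
    config = config or PlacementConfig()
    if consensus is None:
        consensus = _panel_consensus(gene_alignment)
    if aligner is None:
        aligner = _make_aligner()
    width = gene_alignment.column_count
    merged = np.full(width, ord("N"), dtype=np.uint8)
    merged_qual = np.full(width, -1, dtype=np.int64)
    dropped = 0
    scores: list[float | None] = []
    for mate in (pair.mate1, pair.mate2):
        floor = config.min_score_frac * len(mate)
        # forward orientation first; only fall back to the reverse complement
        # when the forward placement is not already decisive
        alns = aligner.align(consensus, mate.residues)
        best_alns, seq = alns, mate
        if alns.score < 0.8 * len(mate):
            rc = mate.reverse_complement()
            rc_alns = aligner.align(consensus, rc.residues)
            if rc_alns.score > alns.score:
                best_alns, seq = rc_alns, rc
        if best_alns.score < floor:
            scores.append(None)
            continue
        scores.append(float(best_alns.score))
        aln = best_alns[0]
        res = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
        quals = np.asarray(
            seq.qualities if seq.qualities is not None else [40] * len(seq)
        )
        ref_blocks, read_blocks = aln.aligned
        prev_r = prev_q = None
        for (rs, re), (qs, qe) in zip(ref_blocks, read_blocks):
            if prev_q is not None and rs == prev_r and qs > prev_q:
                dropped += qs - prev_q  # insertion relative to the panel
            better = quals[qs:qe] > merged_qual[rs:re]
            merged[rs:re][better] = res[qs:qe][better]
            merged_qual[rs:re][better] = quals[qs:qe][better]
            prev_r, prev_q = re, qe
    if all(s is None for s in scores):
        return None
    merged_seq = Sequence(pair.pair_id, merged.tobytes().decode("ascii"))
    return AddResult(
        alignment=gene_alignment.add(merged_seq),
        merged_id=pair.pair_id,
        dropped_insertions=dropped,
        mate_scores=(scores[0], scores[1]),
    )


def trim_to_pair_span(
    extended_alignment: Alignment,
    merged_id: str,
    max_len: int = 500,
    min_len: int = 250,
) -> tuple[Alignment | None, str]:
    """Trim to the merged read's span, cap at ``max_len`` columns, length-check.

    Columns outside the first/last non-missing position of the merged read are
    removed; spans beyond the cap are trimmed equally from both ends. If the
    merged read retains fewer than ``min_len`` non-missing positions the pair
    is discarded as too short.
    """
    merged = extended_alignment.get(merged_id)
    arr = np.frombuffer(merged.residues.encode("ascii"), dtype=np.uint8)
    informative = ~((arr == ord("N")) | (arr == ord("-")))
    idx = np.flatnonzero(informative)
    if idx.size == 0:
        return None, "discarded_short"
    first, last = int(idx[0]), int(idx[-1])
    span = last - first + 1
    if span > max_len:
        excess = span - max_len
        first += excess // 2
        last -= excess - excess // 2
    keep = np.zeros(len(arr), dtype=bool)
    keep[first : last + 1] = True
    if int((informative & keep).sum()) < min_len:
        return None, "discarded_short"
    return extended_alignment.select_columns(keep), "ok"


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------

def assign_clade(
    trimmed_alignment: Alignment,
    clade_map: Mapping[str, str],
    f1_allele_ids: Iterable[str],
    merged_id: str,
    gene_id: str,
    outgroup_labels: Iterable[str],
    engine: str = "nj",
    truth_clade: str | None = None,
) -> PlacementResult:
    """Re-infer the gene tree with the merged read and apply the nesting rules.

    The tree is rooted on the first congener. Sanity check: both F1 alleles
    must still be nested in clades I and IV (the read leaf is ignored when
    evaluating their sister groups); failures discard the pair. Once verified,
    each F1 allele counts as a member of the clade it is nested in — it is a
    bona fide haplotype of that parental clade — so its presence in a sister
    group does not make the group mixed. The read's own sister group must then
    consist of leaves of exactly one nuclear clade, which is the assignment.
    Reads sister to outgroup-only groups are unplaced; mixed sister groups are
    discarded.
    """
    tree = root_on_outgroup(
        infer_gene_tree(trimmed_alignment, engine=engine),
        list(outgroup_labels),
        inplace=True,  # the freshly inferred tree is ours to mutate
    )
    effective_map = dict(clade_map)
    f1_ids = [i for i in f1_allele_ids if i in trimmed_alignment]
    if len(f1_ids) == 2:
        nested = {
            fid: nested_clade(
                sister_group(tree, fid, ignore=[merged_id]), clade_map
            )
            for fid in f1_ids
        }
        if sorted(filter(None, nested.values())) != ["I", "IV"]:
            return PlacementResult(
                merged_id, gene_id, status="discarded_f1_check",
                truth_clade=truth_clade,
            )
        effective_map.update(nested)
    sisters = sister_group(tree, merged_id)
    clades = {effective_map.get(lbl, "?") for lbl in sisters}
    if clades and clades <= set(CONGENER_CLADES):
        return PlacementResult(
            merged_id, gene_id, status="unplaced", truth_clade=truth_clade
        )
    clade = nested_clade(sisters, effective_map)
    if clade is None:
        return PlacementResult(
            merged_id, gene_id, status="discarded_mixed_sister",
            truth_clade=truth_clade,
        )
    return PlacementResult(
        merged_id, gene_id, assigned_clade=clade, truth_clade=truth_clade
    )


def place_pairs_for_gene(
    entry: GeneEntry,
    pairs: Iterable[ReadPair],
    clade_map: Mapping[str, str],
    f1_allele_ids: Iterable[str],
    config: PlacementConfig | None = None,
) -> list[PlacementResult]:
    """Place every selected pair of one gene independently."""
    config = config or PlacementConfig()
    consensus = _panel_consensus(entry.alignment)
    aligner = _make_aligner()
    outgroups = [
        i for i in entry.alignment.ids if clade_map.get(i) == "outgroup1"
    ]
    results = []
    for pair in pairs:
        added = add_pair_to_alignment(
            entry.alignment, pair, config, consensus=consensus, aligner=aligner
        )
        if added is None:
            results.append(
                PlacementResult(
                    pair.pair_id, entry.gene_id, status="unplaced",
                    truth_clade=pair.truth_clade,
                )
            )
            continue
        trimmed, status = trim_to_pair_span(
            added.alignment, added.merged_id, config.max_len, config.min_len
        )
        if trimmed is None:
            results.append(
                PlacementResult(
                    pair.pair_id, entry.gene_id, status=status,
                    truth_clade=pair.truth_clade,
                )
            )
            continue
        results.append(
            assign_clade(
                trimmed, clade_map, f1_allele_ids, added.merged_id,
                entry.gene_id, outgroups, config.engine, pair.truth_clade,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Composition profiles
# ---------------------------------------------------------------------------

@dataclass
class CompositionProfile:
    """Per-individual counts/proportions of reads assigned to each clade."""

    individual_id: str
    counts: dict[str, int]
    n_discarded: dict[str, int] = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float] | None:
        total = self.n_assigned
        if total == 0:
            return None
        return {c: self.counts.get(c, 0) / total for c in NUCLEAR_CLADES}

    def to_row(self) -> dict:
        props = self.proportions or {c: float("nan") for c in NUCLEAR_CLADES}
        row = {"individual": self.individual_id}
        row.update({f"pct_{c}": 100.0 * props[c] for c in NUCLEAR_CLADES})
        row["n_assigned"] = self.n_assigned
        row["n_discarded"] = sum(self.n_discarded.values())
        for status in DISCARD_STATUSES:
            row[f"n_{status}"] = self.n_discarded.get(status, 0)
        return row


def compose_profile(
    placements: Iterable[PlacementResult], individual_id: str
) -> CompositionProfile:
    """Tally assignments and discard reasons for one individual."""
    counts: Counter = Counter()
    discarded: Counter = Counter()
    for p in placements:
        if p.assigned_clade is not None:
            counts[p.assigned_clade] += 1
        else:
            discarded[p.status] += 1
    return CompositionProfile(individual_id, dict(counts), dict(discarded))


def profiles_table(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.to_row() for p in profiles])


# ---------------------------------------------------------------------------
# Leave-one-out for diploids
# ---------------------------------------------------------------------------

def leave_one_out_panel(
    panel: ReferencePanel, focal_individual: str
) -> tuple[dict[str, GeneEntry], list[str]]:
    """Panel copies with the focal individual's alleles removed per gene.

    Genes that no longer satisfy the screening criteria after removal are
    skipped for this individual and reported.
    """
    prefix = f"{focal_individual}_"
    reduced: dict[str, GeneEntry] = {}
    skipped: list[str] = []
    cfg: ReferenceConfig = panel.config
    for gene_id, entry in panel.genes.items():
        drop = [i for i in entry.alignment.ids if i.startswith(prefix)]
        aln = entry.alignment.drop(drop) if drop else entry.alignment
        screen = screen_gene(
            aln, panel.clade_map, cfg.min_per_clade, cfg.min_total
        )
        if not screen.passed:
            skipped.append(gene_id)
            continue
        reduced[gene_id] = GeneEntry(
            gene_id, aln, None, entry.informative, None, screen.counts
        )
    return reduced, skipped


def misassignment_rate(placements: Iterable[PlacementResult]) -> float | None:
    """Fraction of assigned reads whose clade differs from the truth label."""
    assigned = [
        p for p in placements
        if p.assigned_clade is not None and p.truth_clade in NUCLEAR_CLADES
    ]
    if not assigned:
        return None
    wrong = sum(1 for p in assigned if p.assigned_clade != p.truth_clade)
    return wrong / len(assigned)


def pairs_from_frame(
    df: pd.DataFrame, truth: Mapping[str, str] | None = None
) -> list[ReadPair]:
    """Build ReadPair objects from the generator's aligned-read table."""
    grouped: dict[tuple, dict] = defaultdict(dict)
    for row in df.itertuples(index=False):
        key = (row.individual_id, row.gene_id, row.pair_id)
        grouped[key][int(row.mate)] = row
    pairs = []
    for (ind, gene, pair_id), mates in sorted(grouped.items()):
        if set(mates) != {1, 2}:
            continue
        r1, r2 = mates[1], mates[2]
        pairs.append(
            ReadPair(
                pair_id=pair_id,
                individual_id=ind,
                mate1=Sequence(
                    f"{pair_id}/1", r1.residues,
                    [ord(c) - 33 for c in r1.qualities],
                ),
                mate2=Sequence(
                    f"{pair_id}/2", r2.residues,
                    [ord(c) - 33 for c in r2.qualities],
                ),
                gene_id=gene,
                interval1=(int(r1.start), int(r1.start) + len(r1.residues)),
                interval2=(int(r2.start), int(r2.start) + len(r2.residues)),
                truth_clade=getattr(r1, "truth_clade", None) or None,
            )
        )
    return pairs
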
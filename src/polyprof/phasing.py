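"""Read-backed phasing of heterozygous sites within single exons.

Diploid individuals carry two alleles of each single-copy exon; reads mapped to
the exon reveal heterozygous sites, and read pairs that co-observe several such
sites link the alleles into two haplotypes. This module calls heterozygous
sites under base-quality and two-tier depth filters, assembles the two
haplotypes with a greedy position-ordered algorithm that discards reads whose
allele pattern conflicts with both haplotypes, and emits per-haplotype
sequences with masked (N) positions wherever depth support fails. It also
provides the majority-consensus caller used for organelle genomes, where only
sites covered well above the expected nuclear depth are called.

Phasing here is deliberately simple: the exons are chosen to be longer than the
read-pair insert, so nearly every fragment spans multiple heterozygous sites
and switch errors are negligible; when linkage does break, the longest phase
block is kept and the remaining heterozygous sites are masked.
"""

from __future__ import annotations

import math
import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .io_core import Sequence

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"

#: phased sequences with fewer usable (non-N) positions than this are discarded
MIN_PHASED_LENGTH = 200


@dataclass
class AlignedRead:
    """An ungapped read aligned to a single reference exon (0-based start)."""

    read_id: str
    mate: int
    start: int
    residues: str
    qualities: list[int]
    pair_id: str

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"{self.read_id}: mate must be 1 or 2")
        if len(self.qualities) != len(self.residues):
            raise ValueError(f"{self.read_id}: quality/residue length mismatch")
        if self.start < 0:
            raise ValueError(f"{self.read_id}: negative start")

    @property
    def end(self) -> int:
        return self.start + len(self.residues)


@dataclass(frozen=True)
class DepthPolicy:
    """Two-tier depth thresholds for calling and masking.

    Resequencing data requires at least 3 reads per position and 2 per variant
    allele; high-coverage data (expected depth 20x or above) requires 10 and 3.
    """

    mode: str
    min_depth_per_position: int
    min_depth_per_variant: int

    @classmethod
    def resequencing(cls) -> "DepthPolicy":
        return cls("resequencing", 3, 2)

    @classmethod
    def high_coverage(cls) -> "DepthPolicy":
        return cls("high_coverage", 10, 3)

    @classmethod
    def for_depth(cls, expected_depth: float) -> "DepthPolicy":
        return cls.high_coverage() if expected_depth >= 20 else cls.resequencing()


@dataclass
class HetSite:
    position: int
    allele_a: str
    allele_b: str
    support_a: int
    support_b: int

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("heterozygous site alleles must differ")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)


@dataclass
class PhasedAllele:
    individual_id: str
    gene_id: str
    haplotype: int
    residues: str

    @property
    def usable_length(self) -> int:
        return len(self.residues) - self.residues.count("N")

    @property
    def fasta_id(self) -> str:
        return f"{self.individual_id}_{self.gene_id}_h{self.haplotype}"


@dataclass
class PhaseResult:
    haplotype1: str
    haplotype2: str
    het_sites: list[HetSite]
    kept_sites: list[int]  # positions of het sites in the retained phase block
    masked_sites: list[int]  # het sites outside the retained block (masked N)
    discarded: dict[str, str]  # read_id -> reason code
    stats: dict[str, int] = field(default_factory=dict)


def _pileup(
    reads: Iterable[AlignedRead],
    ref_length: int | None,
    min_base_quality: int,
    with_errors: bool = False,
):
    """Per-position base counts (and optionally summed error probabilities
    from the Phred qualities of the counted bases)."""
    reads = list(reads)
    if ref_length is None:
        ref_length = max((r.end for r in reads), default=0)
    counts = np.zeros((ref_length, 4), dtype=np.int64)
    perr = np.zeros((ref_length, 4)) if with_errors else None
    for r in reads:
        res = np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8)
        quals = np.asarray(r.qualities)
        for bi, base in enumerate(_BASES):
            sel = (res == ord(base)) & (quals >= min_base_quality)
            idx = np.flatnonzero(sel)
            pos = r.start + idx
            keep = pos < ref_length
            np.add.at(counts[:, bi], pos[keep], 1)
            if with_errors:
                np.add.at(
                    perr[:, bi], pos[keep],
                    10.0 ** (-0.1 * quals[idx[keep]]),
                )
    if with_errors:
        return counts, perr
    return counts


def call_het_sites(
    reads: Iterable[AlignedRead],
    policy: DepthPolicy,
    min_base_quality: int = 20,
    ref_length: int | None = None,
) -> list[HetSite]:
    """Call heterozygous positions from quality-filtered pileup counts.

    Bases with quality below ``min_base_quality`` are removed before counting.
    A position is a heterozygous candidate iff exactly two alleles each reach
    ``policy.min_depth_per_variant`` supporting reads and the (quality-passing)
    depth reaches ``policy.min_depth_per_position``; positions where three or
    more alleles pass the variant threshold are ambiguous and excluded.
    Candidates are then genotyped by a quality-aware likelihood ratio (the
    standard pileup caller's test): the site is called only if a balanced
    heterozygote explains the two allele counts better than a homozygote whose
    minor bases are sequencing errors at the observed quality.
    """
    counts, perr = _pileup(reads, ref_length, min_base_quality, with_errors=True)
    sites: list[HetSite] = []
    passing = counts >= policy.min_depth_per_variant
    n_passing = passing.sum(axis=1)
    depth = counts.sum(axis=1)
    for pos in np.flatnonzero(n_passing == 2):
        if depth[pos] < policy.min_depth_per_position:
            continue
        bi, bj = np.flatnonzero(passing[pos])
        # allele_a is the better-supported allele; ties break alphabetically
        if counts[pos, bj] > counts[pos, bi]:
            bi, bj = bj, bi
        n1, n2 = int(counts[pos, bi]), int(counts[pos, bj])
        e = (perr[pos, bi] + perr[pos, bj]) / max(n1 + n2, 1)
        e = min(max(e, 1e-6), 0.5)
        ll_hom = n1 * math.log(1 - e) + n2 * math.log(e / 3)
        ll_het = (n1 + n2) * math.log(0.5 * (1 - e) + 0.5 * e / 3)
        if ll_het <= ll_hom:
            continue
        sites.append(HetSite(int(pos), _BASES[bi], _BASES[bj], n1, n2))
    return sites


def _fragment_observations(
    fragments: Mapping[str, list[AlignedRead]],
    site_positions: list[int],
    min_base_quality: int,
) -> dict[str, dict[int, str]]:
    """Per fragment, the observed base at each het site (quality-passing only)."""
    pos_index = {p: i for i, p in enumerate(site_positions)}
    obs: dict[str, dict[int, str]] = {}
    for pair_id, reads in fragments.items():
        frag_obs: dict[int, str] = {}
        for r in reads:
            for p, i in pos_index.items():
                if r.start <= p < r.end:
                    base = r.residues[p - r.start]
                    if base in _BASE_INDEX and r.qualities[p - r.start] >= min_base_quality:
                        if i in frag_obs and frag_obs[i] != base:
                            frag_obs[i] = "*"  # mate disagreement: uninformative
                        else:
                            frag_obs.setdefault(i, base)
        obs[pair_id] = {i: b for i, b in frag_obs.items() if b != "*"}
    return obs


def phase_exon(
    reads: Iterable[AlignedRead],
    het_sites: list[HetSite],
    policy: DepthPolicy,
    min_base_quality: int = 20,
    ref_length: int | None = None,
) -> PhaseResult:
    """Partition reads into two haplotypes and build both allele sequences.

    Reads are sorted by (start, read_id) and mates are linked through their
    pair id so a fragment contributes joint evidence. Heterozygous sites are
    phased greedily in position order: each new site's orientation is set by
    majority vote over fragments that link it to already-phased sites. Sites
    with no linking fragment start a new phase block; only the largest block is
    retained and the het sites of other blocks are masked. Fragments whose
    observed alleles conflict with both assembled haplotypes (e.g. chimeras)
    are discarded. Haplotype sequences are per-haplotype majority bases, with N
    wherever the haplotype's depth falls below ``policy.min_depth_per_position``.
    """
    reads = sorted(reads, key=lambda r: (r.start, r.read_id))
    if ref_length is None:
        ref_length = max((r.end for r in reads), default=0)
    sites = sorted(het_sites, key=lambda s: s.position)
    positions = [s.position for s in sites]

    fragments: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in reads:
        fragments[r.pair_id].append(r)
    obs = _fragment_observations(fragments, positions, min_base_quality)

    # --- greedy position-ordered phasing into blocks -----------------------
    phi: dict[int, int] = {}  # site index -> orientation (hap1 = alleles[phi])
    blocks: list[list[int]] = []
    frag_covering: dict[int, list[str]] = defaultdict(list)
    for pair_id, fo in obs.items():
        for i in fo:
            frag_covering[i].append(pair_id)
    ties = 0
    vote_stats: dict[int, tuple[int, int]] = {}  # site -> (winning, losing) votes
    for i in range(len(sites)):
        if not blocks:
            blocks.append([i])
            phi[i] = 0
            continue
        current = blocks[-1]
        votes = [0, 0]
        for pair_id in frag_covering[i]:
            fo = obs[pair_id]
            base_i = fo[i]
            if base_i not in sites[i].alleles:
                continue
            oi = sites[i].alleles.index(base_i)
            for j in current:
                if j in fo and fo[j] in sites[j].alleles:
                    side_j = sites[j].alleles.index(fo[j]) ^ phi[j]
                    # fragment sits on haplotype `side_j`; orientation that puts
                    # base_i on that same haplotype:
                    votes[oi ^ side_j] += 1
        if votes[0] == 0 and votes[1] == 0:
            blocks.append([i])
            phi[i] = 0
        else:
            if votes[0] == votes[1]:
                ties += 1
            phi[i] = 0 if votes[0] >= votes[1] else 1
            current.append(i)
            vote_stats[i] = (votes[phi[i]], votes[1 - phi[i]])

    if blocks:
        kept = max(blocks, key=lambda b: (len(b), -b[0]))
    else:
        kept = []
    kept_set = set(kept)
    masked_positions = [sites[i].position for i in range(len(sites)) if i not in kept_set]

    # --- assign fragments to haplotypes ------------------------------------
    # Two passes: the first uses the phased allele pairs as-is; haplotype
    # alleles are then re-derived as per-haplotype majorities, which silences
    # spuriously called sites (where both haplotypes agree on the major base,
    # e.g. coincident sequencing errors), and fragments are reassigned on the
    # remaining informative sites only.
    # a genuinely heterozygous site links to the rest of the phase almost
    # unanimously; a site whose orientation votes are close to a coin flip is
    # a spurious call (coincident errors at a homozygous position) and is not
    # used as phase evidence — the position still gets its majority base
    consistent = {
        i for i in kept_set
        if i not in vote_stats
        or vote_stats[i][0] >= 0.8 * sum(vote_stats[i])
    }
    hap_allele = {
        i: (sites[i].alleles[phi[i]], sites[i].alleles[1 - phi[i]]) for i in kept_set
    }
    frag_counts = {
        pair_id: _pileup(frag_reads, ref_length, min_base_quality)
        for pair_id, frag_reads in fragments.items()
    }

    def assign_fragments(informative, alleles):
        assignment: dict[str, int] = {}
        discarded: dict[str, str] = {}
        for pair_id, fo in obs.items():
            covered = [i for i in fo if i in informative]
            if not covered:
                continue
            m = [0, 0]
            for i in covered:
                base = fo[i]
                for h in (0, 1):
                    if base != alleles[i][h]:
                        m[h] += 1
            # a fragment belongs to the haplotype it mismatches least; equal
            # mismatch counts (chimeras, heavily erroneous reads) conflict
            # with both assembled haplotypes and are discarded
            if m[0] < m[1]:
                assignment[pair_id] = 0
            elif m[1] < m[0]:
                assignment[pair_id] = 1
            else:
                for r in fragments[pair_id]:
                    discarded[r.read_id] = "ambiguous_phase"
        return assignment, discarded

    def accumulate(assignment, discarded):
        hap_counts = [
            np.zeros((ref_length, 4), dtype=np.int64) for _ in range(2)
        ]
        n_assigned = n_unassigned = 0
        for pair_id, frag_reads in fragments.items():
            if frag_reads and frag_reads[0].read_id in discarded:
                continue
            target = assignment.get(pair_id)
            counts = frag_counts[pair_id]
            if target is None:
                n_unassigned += 1
                hap_counts[0] += counts
                hap_counts[1] += counts
            else:
                n_assigned += 1
                hap_counts[target] += counts
        return hap_counts, n_assigned, n_unassigned

    assignment, discarded = assign_fragments(consistent, hap_allele)
    hap_counts, n_assigned, n_unassigned = accumulate(assignment, discarded)
    refined = {}
    informative = set()
    for i in consistent:
        pos = sites[i].position
        maj = tuple(
            _BASES[int(np.argmax(hap_counts[h][pos]))]
            if hap_counts[h][pos].sum() > 0
            else hap_allele[i][h]
            for h in (0, 1)
        )
        refined[i] = maj
        if maj[0] != maj[1]:
            informative.add(i)
    assignment, discarded = assign_fragments(informative, refined)
    hap_counts, n_assigned, n_unassigned = accumulate(assignment, discarded)

    haplotypes = []
    for h in range(2):
        counts = hap_counts[h]
        depth = counts.sum(axis=1)
        best = np.argmax(counts, axis=1)  # ties break alphabetically (first index)
        seq = np.array(list(_BASES))[best]
        seq[depth < policy.min_depth_per_position] = "N"
        for p in masked_positions:
            seq[p] = "N"
        haplotypes.append("".join(seq))

    n_discarded_frags = sum(
        1 for pid, fr in fragments.items() if fr and fr[0].read_id in discarded
    )
    stats = {
        "informative_positions": sorted(sites[i].position for i in informative),
        "vote_stats": {sites[i].position: v for i, v in vote_stats.items()},
        "fragments_total": len(fragments),
        "fragments_assigned": n_assigned,
        "fragments_unassigned": n_unassigned,
        "fragments_discarded": n_discarded_frags,
        "phase_blocks": len(blocks),
        "orientation_ties": ties,
    }
    return PhaseResult(
        haplotype1=haplotypes[0],
        haplotype2=haplotypes[1],
        het_sites=sites,
        kept_sites=[sites[i].position for i in kept],
        masked_sites=masked_positions,
        discarded=discarded,
        stats=stats,
    )


def phase_individual_gene(
    reads: Iterable[AlignedRead],
    individual_id: str,
    gene_id: str,
    policy: DepthPolicy,
    min_base_quality: int = 20,
    ref_length: int | None = None,
    min_phased_length: int = MIN_PHASED_LENGTH,
) -> tuple[list[PhasedAllele], PhaseResult]:
    """Phase one individual's reads for one exon into PhasedAllele records.

    Phased sequences with fewer than ``min_phased_length`` usable (non-N)
    positions are discarded, mirroring the pipeline's 200 bp rule.
    """
    reads = list(reads)
    sites = call_het_sites(reads, policy, min_base_quality, ref_length)
    result = phase_exon(reads, sites, policy, min_base_quality, ref_length)
    alleles = []
    for h, seq in ((1, result.haplotype1), (2, result.haplotype2)):
        allele = PhasedAllele(individual_id, gene_id, h, seq)
        if allele.usable_length >= min_phased_length:
            alleles.append(allele)
    return alleles, result


# ---------------------------------------------------------------------------
# Organelle majority consensus
# ---------------------------------------------------------------------------

def majority_consensus(
    reads: Iterable[AlignedRead],
    depth_floor: float,
    reference: str | None = None,
    ref_length: int | None = None,
    min_base_quality: int = 0,
) -> tuple[Sequence, list[int]]:
    """Per-position majority base where depth strictly exceeds ``depth_floor``.

    For organelle work the caller sets the floor to five times the expected
    nuclear sequencing depth, discarding organelle-to-nucleus transfers whose
    coverage tracks the nuclear genome. Positions at or below the floor are N;
    ties resolve to the reference base when one is supplied (and the position
    is reported), otherwise N.
    """
    if depth_floor < 0:
        raise ValueError("depth_floor must be >= 0")
    if ref_length is None and reference is not None:
        ref_length = len(reference)
    counts = _pileup(reads, ref_length, min_base_quality)
    depth = counts.sum(axis=1)
    best = counts.max(axis=1)
    seq = []
    tie_positions: list[int] = []
    for pos in range(counts.shape[0]):
        if depth[pos] <= depth_floor:
            seq.append("N")
            continue
        winners = np.flatnonzero(counts[pos] == best[pos])
        if len(winners) == 1:
            seq.append(_BASES[winners[0]])
        else:
            tie_positions.append(pos)
            if reference is not None and pos < len(reference):
                seq.append(reference[pos])
            else:
                seq.append("N")
    return Sequence("consensus", "".join(seq)), tie_positions


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------

def read_sam(path: str | os.PathLike) -> tuple[dict[str, list[AlignedRead]], int]:
    """Minimal SAM reader: mapped, ungapped reads (CIGAR a single M run).

    Returns reads grouped by reference name plus the count of reads rejected
    for carrying indels or clipping in their CIGAR.
    """
    by_ref: dict[str, list[AlignedRead]] = defaultdict(list)
    rejected = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped:
                continue
            cigar = rec.cigartuples
            if cigar is None or len(cigar) != 1 or cigar[0][0] != 0:
                rejected += 1
                continue
            quals = (
                list(rec.query_qualities)
                if rec.query_qualities is not None
                else [40] * len(rec.query_sequence)
            )
            mate = 2 if rec.is_read2 else 1
            by_ref[rec.reference_name].append(
                AlignedRead(
                    read_id=f"{rec.query_name}/{mate}",
                    mate=mate,
                    start=rec.reference_start,
                    residues=rec.query_sequence.upper(),
                    qualities=quals,
                    pair_id=rec.query_name,
                )
            )
    return dict(by_ref), rejected


READS_TSV_COLUMNS = [
    "individual_id", "gene_id", "pair_id", "mate", "start",
    "residues", "qualities", "truth_clade", "source_allele",
]


def read_reads_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Load the aligned-read TSV emitted by the synthetic-data generator."""
    df = pd.read_csv(
        path, sep="\t", dtype={"mate": int, "start": int},
        keep_default_na=False, na_values=[],
    )
    missing = [c for c in READS_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def aligned_reads_from_frame(df: pd.DataFrame) -> list[AlignedRead]:
    return [
        AlignedRead(
            read_id=f"{row.pair_id}/{row.mate}",
            mate=int(row.mate),
            start=int(row.start),
            residues=row.residues,
            qualities=[ord(c) - 33 for c in row.qualities],
            pair_id=row.pair_id,
        )
        for row in df.itertuples(index=False)
    ]
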
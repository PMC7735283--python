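"""Sequence and alignment containers, standard-format I/O, and sample-metadata rules.

This module holds the plumbing shared by the whole pipeline: FASTA/FASTQ/Newick/TSV
readers and writers, occupancy-based alignment trimming and length/occupancy
filters, and the two small classification rules applied to sample metadata
(photosynthetic type from the carbon isotope ratio, ploidy level from 2C genome
size).

Coordinate convention: all internal coordinates are 0-based, half-open. Any
interval surfaced to users in reports is 1-based closed and labelled as such.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TSequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACGTN-")
NUCLEOTIDES = ("A", "C", "G", "T")
#: residues treated as absent when computing column coverage: both the alignment
#: gap and the consensus/phasing mask character.
MISSING_RESIDUES = frozenset("N-")


class ParseError(ValueError):
    """Raised when an input file violates its format."""


@dataclass
class Sequence:
    """A named nucleotide sequence, optionally with per-base Phred qualities."""

    id: str
    residues: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValueError(
                f"{self.id}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "Sequence":
        rc = str(Seq(self.residues).reverse_complement())
        quals = None if self.qualities is None else self.qualities[::-1]
        return Sequence(self.id, rc, quals)


class Alignment:
    """An ordered collection of equal-length sequences with unique ids."""

    def __init__(self, sequences: Iterable[Sequence]):
        seqs = list(sequences)
        if seqs:
            ncol = len(seqs[0])
            for s in seqs:
                if len(s) != ncol:
                    raise ValueError(
                        f"unequal sequence lengths: {s.id} has {len(s)}, expected {ncol}"
                    )
        ids = [s.id for s in seqs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        self.sequences: list[Sequence] = seqs
        self._index = {s.id: s for s in seqs}

    @property
    def column_count(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def get(self, seq_id: str) -> Sequence:
        return self._index[seq_id]

    def to_matrix(self) -> np.ndarray:
        """Residues as a (n_sequences, n_columns) uint8 array of ASCII codes."""
        if not self.sequences:
            return np.zeros((0, 0), dtype=np.uint8)
        return np.frombuffer(
            "".join(s.residues for s in self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.sequences), self.column_count)

    def select_columns(self, keep: np.ndarray) -> "Alignment":
        """New alignment from a boolean/index column selector, order preserved."""
        sub = self.to_matrix()[:, keep]
        out = []
        for i, s in enumerate(self.sequences):
            quals = (
                None
                if s.qualities is None
                else list(np.asarray(s.qualities)[keep])
            )
            out.append(Sequence(s.id, sub[i].tobytes().decode("ascii"), quals))
        return Alignment(out)

    def drop(self, ids: Iterable[str]) -> "Alignment":
        dropset = set(ids)
        return Alignment(s for s in self.sequences if s.id not in dropset)

    def add(self, seq: Sequence) -> "Alignment":
        return Alignment([*self.sequences, seq])


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[Sequence]:
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate id {rec.id!r} (record {i + 1})")
        seen.add(rec.id)
        seqs.append(Sequence(rec.id, str(rec.seq).upper()))
    return seqs


def read_fasta_alignment(path: str | os.PathLike) -> Alignment:
    return Alignment(read_fasta(path))


def write_fasta(seqs: Iterable[Sequence], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta-2line")


def read_fastq(path: str | os.PathLike) -> list[Sequence]:
    """Read Phred+33 FASTQ; every returned Sequence carries qualities."""
    seqs: list[Sequence] = []
    seen: set[str] = set()
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate id {rec.id!r} (record {i + 1})")
            seen.add(rec.id)
            seqs.append(
                Sequence(
                    rec.id,
                    str(rec.seq).upper(),
                    list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:  # biopython flags malformed records
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: record {len(seqs) + 1}: {exc}") from exc
    return seqs


def write_fastq(seqs: Iterable[Sequence], path: str | os.PathLike) -> None:
    records = []
    for s in seqs:
        if s.qualities is None:
            raise ValueError(f"{s.id}: FASTQ output requires qualities")
        rec = SeqRecord(Seq(s.residues), id=s.id, description="")
        rec.letter_annotations["phred_quality"] = list(s.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Newick / TSV
# ---------------------------------------------------------------------------

def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_tsv_map(
    path: str | os.PathLike, key: str, value: str
) -> dict[str, str]:
    """Load two columns of a headered TSV as a mapping; duplicate keys error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (key, value):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df[key].duplicated().any():
        dups = sorted(df.loc[df[key].duplicated(), key].unique())
        raise ParseError(f"{path}: duplicate keys {dups}")
    return dict(zip(df[key], df[value]))


def read_clade_map(path: str | os.PathLike) -> dict[str, str]:
    """Clade map TSV (sequence_id, individual_id, clade) -> {sequence_id: clade}."""
    return read_tsv_map(path, "sequence_id", "clade")


# ---------------------------------------------------------------------------
# Alignment filters
# ---------------------------------------------------------------------------

def column_occupancy(alignment: Alignment) -> np.ndarray:
    """Per-column fraction of sequences with a non-missing residue."""
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    mat = alignment.to_matrix()
    missing = (mat == ord("N")) | (mat == ord("-"))
    return 1.0 - missing.mean(axis=0)


def trim_by_occupancy(alignment: Alignment, min_fraction: float) -> Alignment:
    """Remove columns covered by fewer than ``min_fraction`` of the sequences.

    Gap ('-') and mask ('N') residues both count as non-coverage. A column is
    retained iff its coverage is >= ``min_fraction``; column order is preserved.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    keep = column_occupancy(alignment) >= min_fraction - 1e-12
    return alignment.select_columns(keep)


def taxon_occupancy(alignment: Alignment, expected_taxa: Iterable[str]) -> float:
    """Fraction of expected taxa that contribute a sequence to the alignment."""
    expected = list(expected_taxa)
    if not expected:
        raise ValueError("expected_taxa must be non-empty")
    present = set(alignment.ids)
    return sum(t in present for t in expected) / len(expected)


def filter_alignments(
    alignments: Mapping[str, Alignment] | TSequence[Alignment],
    min_length: int = 500,
    min_taxon_occupancy: float = 0.95,
    expected_taxa: Iterable[str] | None = None,
) -> list:
    """Keep alignments with column_count > min_length AND occupancy > threshold.

    Both inequalities are strict. ``expected_taxa`` defaults to the union of
    sequence ids across all input alignments.
    """
    items = (
        list(alignments.items())
        if isinstance(alignments, Mapping)
        else list(enumerate(alignments))
    )
    if expected_taxa is None:
        expected = sorted({i for _, a in items for i in a.ids})
    else:
        expected = list(expected_taxa)
    kept = [
        key
        for key, aln in items
        if aln.column_count > min_length
        and taxon_occupancy(aln, expected) > min_taxon_occupancy
    ]
    if isinstance(alignments, Mapping):
        return kept
    return [alignments[k] for k in kept]


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

#: 2C genome-size range of confirmed diploids, in pg/2C.
DIPLOID_RANGE_PG = (1.78, 2.77)
#: candidate ploidy levels considered when assigning from genome size.
PLOIDY_CANDIDATES = (2, 4, 6, 8, 10, 12)


@dataclass
class SampleMetadata:
    sample_id: str
    genome_size_2C: float | None = None
    delta13C: float | None = None
    ploidy: int | None = None
    photosynthetic_type: str = "unknown"

    def __post_init__(self) -> None:
        if self.ploidy is not None and (self.ploidy <= 0 or self.ploidy % 2):
            raise ValueError(f"{self.sample_id}: ploidy must be a positive even integer")


def classify_photosynthetic_type(delta13C: float | None) -> str:
    """Classify the photosynthetic type from the carbon isotope ratio (per mil).

    Values strictly below -17 per mil indicate non-C4 carbon fixation; the
    boundary itself classifies as C4. A missing value returns "unknown".
    """
    if delta13C is None or (isinstance(delta13C, float) and math.isnan(delta13C)):
        return "unknown"
    if not math.isfinite(delta13C):
        raise ValueError(f"delta13C must be finite, got {delta13C}")
    return "non-C4" if delta13C < -17.0 else "C4"


@dataclass
class PloidyCall:
    """A ploidy assignment from 2C genome size.

    flag is "confident" only for a unique match to the measured diploid range;
    polyploid matches are "possible" (single) or "ambiguous" (the scaled ranges
    of high ploidy levels overlap, in which case the largest matching level is
    reported); "possible" with no match means nearest scaled midpoint.
    """

    ploidy: int
    flag: str
    matches: tuple[int, ...] = field(default_factory=tuple)

    @property
    def flagged(self) -> bool:
        return self.flag != "confident"


def assign_ploidy(
    genome_size_2C: float,
    diploid_range: tuple[float, float] = DIPLOID_RANGE_PG,
    tolerance: float = 0.25,
    candidates: TSequence[int] = PLOIDY_CANDIDATES,
) -> PloidyCall:
    """Assign a ploidy level from a 2C genome size in picograms.

    A size matches ploidy p when it lies in the diploid range scaled by p/2.
    If no strict match exists, the ranges are widened by the multiplicative
    ``tolerance`` at both endpoints; failing that, the nearest scaled midpoint
    wins. Ties (overlapping scaled ranges at p >= 6) resolve to the largest
    matching level.
    """
    if genome_size_2C <= 0:
        raise ValueError(f"genome size must be positive, got {genome_size_2C}")
    lo, hi = diploid_range
    strict = tuple(
        p for p in candidates if lo * p / 2 <= genome_size_2C <= hi * p / 2
    )
    if strict:
        p = max(strict)
        if strict == (2,):
            return PloidyCall(2, "confident", strict)
        flag = "ambiguous" if len(strict) > 1 else "possible"
        return PloidyCall(p, flag, strict)
    widened = tuple(
        p
        for p in candidates
        if lo * p / 2 * (1 - tolerance)
        <= genome_size_2C
        <= hi * p / 2 * (1 + tolerance)
    )
    if widened:
        return PloidyCall(max(widened), "possible", widened)
    mid = (lo + hi) / 2
    nearest = min(candidates, key=lambda p: (abs(genome_size_2C - mid * p / 2), p))
    return PloidyCall(nearest, "possible", ())


def read_metadata(path: str | os.PathLike) -> list[SampleMetadata]:
    """Load sample metadata TSV (sample_id, genome_size_2C, delta13C)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing column 'sample_id'")
    out = []
    for row in df.itertuples(index=False):
        size = getattr(row, "genome_size_2C", None)
        d13c = getattr(row, "delta13C", None)
        size = None if size is None or pd.isna(size) else float(size)
        d13c = None if d13c is None or pd.isna(d13c) else float(d13c)
        out.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                genome_size_2C=size,
                delta13C=d13c,
                photosynthetic_type=classify_photosynthetic_type(d13c),
            )
        )
    return out
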
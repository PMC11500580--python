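"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions are strict and uniform: every genomic interval in
this package is **0-based, half-open** (the BED convention). FASTA headers
carry the gene_id only. Tab-separated tables use a header row and ``NA``
for missing values.

Pileups are computed per gene in gene-local coordinates (offset 0 is the
gene's 5'-most reference position on the plus strand of the reference);
reads overlapping a gene boundary are clipped to the gene interval. Bases
are counted regardless of mapping strand, in reference orientation, and
without any base-quality filter. Insertions contribute no counts and
deleted reference positions contribute no counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical base order used for all count arrays in the package.
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# byte -> base code lookup (A=0, C=1, G=2, T=3, everything else -1)
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as base codes (A=0, C=1, G=2, T=3, other=-1)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    lookup = np.frombuffer(b"ACGTN", dtype=np.uint8)
    codes = np.where(codes < 0, 4, codes)
    return np.asarray(lookup)[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class GeneModel:
    """A gene's reference coordinates; ``length_bp`` is the per-kb normalizer."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CpGIsland:
    """A CpG-island interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"island on {self.chrom}: end ({self.end}) must exceed start ({self.start})")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneStatRecord:
    """Per-gene differential statistics consumed by the gene-set module.

    At least one of (adjusted_p, log2_fold_change) or splicing_changed must
    be present; missing values are ``None``.
    """

    gene_id: str
    adjusted_p: float | None = None
    log2_fold_change: float | None = None
    splicing_changed: bool | None = None

    def __post_init__(self) -> None:
        if self.adjusted_p is None and self.log2_fold_change is None and self.splicing_changed is None:
            raise ValueError(f"record {self.gene_id!r}: all statistics missing")
        if self.adjusted_p is not None and not (0.0 <= self.adjusted_p <= 1.0):
            raise ValueError(f"record {self.gene_id!r}: adjusted_p {self.adjusted_p} outside [0, 1]")


@dataclass(frozen=True)
class PileupColumn:
    """Base counts at one gene-local reference position.

    Counts cover aligned match/mismatch bases only; insertions and deletions
    never contribute. ``depth`` is always the sum of the four counts.
    """

    position: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for b, n in self.counts.items():
            if b not in BASE_INDEX:
                raise ValueError(f"position {self.position}: unknown base {b!r}")
            if n < 0:
                raise ValueError(f"position {self.position}: negative count for {b}")

    @property
    def depth(self) -> int:
        return int(sum(self.counts.values()))

    def count(self, base: str) -> int:
        return int(self.counts.get(base, 0))


class Pileup(Sequence):
    """Per-gene pileup: an (L, 4) count matrix in ``BASES`` order.

    Behaves as an immutable sequence of :class:`PileupColumn`; the raw
    matrix is exposed as ``.counts`` for vectorised consumers.
    """

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"pileup counts must be (L, 4), got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("pileup counts must be non-negative")
        self.counts = counts

    @classmethod
    def zeros(cls, length: int) -> "Pileup":
        return cls(np.zeros((length, 4), dtype=np.int64))

    @classmethod
    def from_columns(cls, columns: Iterable[PileupColumn], length: int | None = None) -> "Pileup":
        cols = list(columns)
        if length is None:
            length = len(cols)
        seen = np.zeros(length, dtype=bool)
        counts = np.zeros((length, 4), dtype=np.int64)
        for col in cols:
            if not (0 <= col.position < length):
                raise ValueError(f"pileup position {col.position} outside [0, {length})")
            if seen[col.position]:
                raise ValueError(f"duplicated pileup position {col.position}")
            seen[col.position] = True
            for b, n in col.counts.items():
                counts[col.position, BASE_INDEX[b]] = n
        if not seen.all():
            missing = int(np.flatnonzero(~seen)[0])
            raise ValueError(f"missing pileup position {missing}")
        return cls(counts)

    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __len__(self) -> int:
        return self.counts.shape[0]

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        if i < 0:
            i += len(self)
        row = self.counts[i]
        return PileupColumn(position=int(i), counts={b: int(row[j]) for j, b in enumerate(BASES)})

    def __iter__(self) -> Iterator[PileupColumn]:
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pileup):
            return NotImplemented
        return self.counts.shape == other.counts.shape and bool((self.counts == other.counts).all())


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _bed_fields(path: Union[str, os.PathLike], min_fields: int):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < min_fields:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= {min_fields} BED fields, got {len(fields)}"
                )
            yield lineno, fields


def read_gene_models(path: Union[str, os.PathLike]) -> list[GeneModel]:
    """Read gene models from a BED6 file, preserving file order.

    Raises ``ValueError`` (naming the offending line) on malformed lines,
    invalid coordinates, or duplicated gene_ids.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, fields in _bed_fields(path, 6):
        chrom, start, end, name, _score, strand = fields[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
        if name in seen:
            raise ValueError(f"{path}: line {lineno}: duplicate gene_id {name!r}")
        seen.add(name)
        try:
            genes.append(GeneModel(name, chrom, start_i, end_i, strand))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_intervals(path: Union[str, os.PathLike]) -> list[CpGIsland]:
    """Read plain intervals (e.g. the UCSC CpG-island track) from BED3+."""
    islands: list[CpGIsland] = []
    for lineno, fields in _bed_fields(path, 3):
        chrom, start, end = fields[:3]
        try:
            islands.append(CpGIsland(chrom, int(start), int(end)))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return islands


def write_intervals(islands: Iterable[CpGIsland], path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, os.PathLike]) -> dict[str, str]:
    """Read a FASTA file into {record id: upper-case sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: Union[str, os.PathLike]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_consensus_fasta(consensus, path: Union[str, os.PathLike]) -> None:
    """Write consensus sequences to FASTA; headers carry gene_id only.

    Accepts a {gene_id: seq} mapping or any iterable of objects with
    ``gene_id`` and ``seq`` attributes (e.g. ConsensusSequence).
    """
    if isinstance(consensus, Mapping):
        seqs = dict(consensus)
    else:
        seqs = {c.gene_id: c.seq for c in consensus}
    write_fasta(seqs, path)


def gene_sequence(reference: Mapping[str, str], gene: GeneModel) -> str:
    """Extract a gene's reference sequence (reference orientation)."""
    chrom_seq = reference[gene.chrom]
    if gene.end > len(chrom_seq):
        raise ValueError(f"gene {gene.gene_id!r} extends past end of {gene.chrom}")
    return chrom_seq[gene.start:gene.end]


# ---------------------------------------------------------------------------
# Tables (TSV, header row, NA for missing)
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: Union[str, os.PathLike], index: bool = False) -> None:
    frame.to_csv(path, sep="\t", na_rep="NA", index=index)


def read_table(path: Union[str, os.PathLike], index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, index_col=index_col)


def gene_stat_records(frame: pd.DataFrame) -> list[GeneStatRecord]:
    """Convert a stats table (gene_id, adjusted_p, log2_fold_change and/or
    splicing_changed columns) into GeneStatRecord objects."""

    def _opt(row, col, cast):
        if col not in row or pd.isna(row[col]):
            return None
        return cast(row[col])

    records = []
    for _, row in frame.iterrows():
        records.append(
            GeneStatRecord(
                gene_id=str(row["gene_id"]),
                adjusted_p=_opt(row, "adjusted_p", float),
                log2_fold_change=_opt(row, "log2_fold_change", float),
                splicing_changed=_opt(row, "splicing_changed", bool),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

PILEUP_TSV_COLUMNS = ("gene_id", "position", "nA", "nC", "nG", "nT")


def write_pileup_tsv(pileups: Mapping[str, Pileup], path: Union[str, os.PathLike]) -> None:
    """Write per-gene pileups to a TSV with columns gene_id, position, nA..nT."""
    chunks = []
    for gene_id, pile in pileups.items():
        frame = pd.DataFrame(pile.counts, columns=["nA", "nC", "nG", "nT"])
        frame.insert(0, "position", np.arange(len(pile)))
        frame.insert(0, "gene_id", gene_id)
        chunks.append(frame)
    out = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame(columns=PILEUP_TSV_COLUMNS)
    write_table(out, path)


def pileup_from_tsv(source, gene: GeneModel) -> Pileup:
    """Build a gene's pileup from a pileup TSV (path or pre-loaded DataFrame).

    Positions are gene-local; absent positions get zero counts; a position
    outside [0, length_bp) is an error. A gene_id absent from the table
    yields an all-zero pileup.
    """
    frame = source if isinstance(source, pd.DataFrame) else read_table(source)
    missing = [c for c in PILEUP_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"pileup TSV missing columns {missing}")
    sub = frame[frame["gene_id"] == gene.gene_id]
    counts = np.zeros((gene.length_bp, 4), dtype=np.int64)
    if len(sub):
        pos = sub["position"].to_numpy(dtype=np.int64)
        if (pos < 0).any() or (pos >= gene.length_bp).any():
            bad = pos[(pos < 0) | (pos >= gene.length_bp)][0]
            raise ValueError(
                f"gene {gene.gene_id!r}: pileup position {bad} outside [0, {gene.length_bp})"
            )
        vals = sub[["nA", "nC", "nG", "nT"]].to_numpy(dtype=np.int64)
        np.add.at(counts, pos, vals)
    return Pileup(counts)


def pileup_from_alignments(path: Union[str, os.PathLike], gene: GeneModel) -> Pileup:
    """Build a gene's pileup from a SAM/BAM file by streaming all reads.

    Standard CIGAR semantics via pysam aligned pairs: only match/mismatch
    bases are counted, insertions and soft-clips have no reference position
    and are skipped, deleted reference positions receive no count. Reads are
    clipped to the gene interval; mapping strand is ignored (counts are in
    reference orientation). No index is required.
    """
    counts = np.zeros((gene.length_bp, 4), dtype=np.int64)
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name != gene.chrom:
                continue
            if read.reference_end is None or read.reference_end <= gene.start:
                continue
            if read.reference_start >= gene.end:
                continue
            seq = read.query_sequence
            if seq is None:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if gene.start <= rpos < gene.end:
                    code = _BASE_CODE[ord(seq[qpos])]
                    if code >= 0:
                        counts[rpos - gene.start, code] += 1
    return Pileup(counts)


def read_pileup(path: Union[str, os.PathLike], gene: GeneModel) -> Pileup:
    """Read a gene's pileup from SAM/BAM or a pileup TSV (by file extension)."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".sam", ".bam", ".cram"):
        return pileup_from_alignments(path, gene)
    return pileup_from_tsv(path, gene)
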
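"""Substitution spectra, the AT>CG / CG>AT ratio, and dinucleotide densities.

The spectrum compares a gene's called consensus against its reference
sequence position by position, counting the 12 ordered base-substitution
classes (ref -> consensus, ref != consensus) plus reference -> N. Class
sums follow the weak/strong grouping used for transposon-derived genes:

* ``AT>CG`` = A>C + A>G + T>C + T>G
* ``CG>AT`` = C>A + C>T + G>A + G>T

Both class sets are closed under complementation, so the ratio statistic
is invariant to which strand the reads mapped to. Total substitutions per
gene (the 12 classes plus ref->N) are normalised to gene length per
1000 bp. Dinucleotide (CpG / GpC) densities are overlapping sliding-window
counts normalised the same way; windows containing N are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .io_formats import BASES, encode_sequence

#: The 12 ordered substitution classes, "ref>cons".
SUBSTITUTION_CLASSES = tuple(f"{r}>{c}" for r in BASES for c in BASES if r != c)
AT_TO_CG_CLASSES = ("A>C", "A>G", "T>C", "T>G")
CG_TO_AT_CLASSES = ("C>A", "C>T", "G>A", "G>T")


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Counts of the 12 ref->consensus substitution classes for one gene."""

    gene_id: str
    length_bp: int
    class_counts: Mapping[str, int]
    n_to_N: int

    def __post_init__(self) -> None:
        unknown = set(self.class_counts) - set(SUBSTITUTION_CLASSES)
        if unknown:
            raise ValueError(f"unknown substitution classes {sorted(unknown)}")
        if self.n_to_N < 0 or any(v < 0 for v in self.class_counts.values()):
            raise ValueError("substitution counts must be non-negative")

    def count(self, cls: str) -> int:
        return int(self.class_counts.get(cls, 0))

    @property
    def at_to_cg(self) -> int:
        return sum(self.count(c) for c in AT_TO_CG_CLASSES)

    @property
    def cg_to_at(self) -> int:
        return sum(self.count(c) for c in CG_TO_AT_CLASSES)

    @property
    def total_substitutions(self) -> int:
        """All positions where consensus differs from reference (N included)."""
        return sum(self.class_counts.values()) + self.n_to_N

    @property
    def total_per_kb(self) -> float:
        return self.total_substitutions / (self.length_bp / 1000.0)

    @property
    def ratio(self) -> float | None:
        return substitution_ratio(self)


@dataclass(frozen=True)
class DinucleotideDensity:
    """Sliding-window dinucleotide count for one gene, per-kb normalised."""

    gene_id: str
    pattern: str
    count: int
    length_bp: int
    n_valid_windows: int

    @property
    def per_kb(self) -> float:
        if self.length_bp == 0:
            return 0.0
        return self.count / (self.length_bp / 1000.0)


def count_substitutions(reference: str, consensus: str, gene_id: str = "") -> SubstitutionSpectrum:
    """Count per-class substitutions between a reference gene sequence
    (over ACGT) and its consensus (over ACGTN).

    Positions where the consensus is N increment ``n_to_N`` only; they count
    toward the total (and per-kb) but toward neither class sum.
    """
    if len(reference) != len(consensus):
        raise ValueError(
            f"gene {gene_id!r}: reference length {len(reference)} != consensus length {len(consensus)}"
        )
    ref = encode_sequence(reference)
    if (ref < 0).any():
        bad = int(np.flatnonzero(ref < 0)[0])
        raise ValueError(f"gene {gene_id!r}: non-ACGT reference base {reference[bad]!r} at {bad}")
    cons_bytes = np.frombuffer(consensus.encode("ascii"), dtype=np.uint8)
    cons = encode_sequence(consensus)
    is_n = cons_bytes == ord("N")
    if ((cons < 0) & ~is_n).any():
        bad = int(np.flatnonzero((cons < 0) & ~is_n)[0])
        raise ValueError(f"gene {gene_id!r}: non-ACGTN consensus base {consensus[bad]!r} at {bad}")

    mismatch = (cons != ref) & ~is_n
    pair = np.bincount(ref[mismatch] * 4 + cons[mismatch], minlength=16)
    class_counts = {
        f"{r}>{c}": int(pair[i * 4 + j])
        for i, r in enumerate(BASES)
        for j, c in enumerate(BASES)
        if r != c
    }
    return SubstitutionSpectrum(
        gene_id=gene_id,
        length_bp=len(reference),
        class_counts=class_counts,
        n_to_N=int(is_n.sum()),
    )


def substitution_ratio(spec: SubstitutionSpectrum, pseudocount: float = 0.0) -> float | None:
    """The AT>CG / CG>AT ratio; ``None`` (undefined) when the denominator is
    zero and no pseudocount is given."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    num = spec.at_to_cg + pseudocount
    den = spec.cg_to_at + pseudocount
    if den == 0:
        return None
    return num / den


def dinucleotide_density(
    seq: str, pattern: str, length_bp: int | None = None, gene_id: str = ""
) -> DinucleotideDensity:
    """Count a 2-mer in overlapping windows (step 1); windows containing N
    are skipped and excluded from ``n_valid_windows``."""
    if len(pattern) != 2 or any(b not in BASES for b in pattern):
        raise ValueError(f"pattern must be a 2-mer over ACGT, got {pattern!r}")
    if length_bp is not None and length_bp != len(seq):
        raise ValueError(f"length_bp {length_bp} != sequence length {len(seq)}")
    length = len(seq)
    if length < 2:
        return DinucleotideDensity(gene_id, pattern, 0, length, 0)
    codes = encode_sequence(seq)
    first, second = codes[:-1], codes[1:]
    valid = (first >= 0) & (second >= 0)
    p0, p1 = encode_sequence(pattern)
    count = int(((first == p0) & (second == p1)).sum())
    return DinucleotideDensity(gene_id, pattern, count, length, int(valid.sum()))


# ---------------------------------------------------------------------------
# Group x sample aggregation and the z-score view
# ---------------------------------------------------------------------------

AGGREGATION_SCHEMES = ("mean_of_gene_ratios", "ratio_of_summed_counts")


@dataclass
class GroupSampleMatrix:
    """Gene-group x sample matrix of aggregated ratios (or densities)."""

    values: pd.DataFrame

    @property
    def z_view(self) -> pd.DataFrame:
        return row_zscore(self.values)


def row_zscore(matrix: Union[pd.DataFrame, "GroupSampleMatrix"]) -> pd.DataFrame:
    """Row-wise (x - mean) / sample SD (ddof 1); rows with fewer than two
    non-missing cells or zero SD become all-missing."""
    frame = matrix.values if isinstance(matrix, GroupSampleMatrix) else matrix
    out = frame.astype(float).copy()
    for label, row in out.iterrows():
        vals = row.dropna()
        sd = vals.std(ddof=1) if len(vals) >= 2 else 0.0
        if len(vals) < 2 or sd == 0 or not math.isfinite(sd):
            out.loc[label] = np.nan
        else:
            out.loc[label] = (row - vals.mean()) / sd
    return out


def aggregate_group_matrix(
    per_gene_values: pd.DataFrame,
    groups,
    scheme: str = "mean_of_gene_ratios",
) -> GroupSampleMatrix:
    """Collapse a long per-gene table to a group x sample matrix.

    ``per_gene_values`` carries one row per (gene_id, sample, replicate)
    with either a ``value`` column (per-gene ratio; NaN = undefined) for the
    ``mean_of_gene_ratios`` scheme, or ``at_to_cg``/``cg_to_at`` count
    columns for ``ratio_of_summed_counts``. The replicate dimension is
    collapsed first by arithmetic mean; undefined values are excluded from
    means, and a cell with no defined value left is missing.

    ``groups`` is a {label: set of gene_id} mapping or a GeneGroupPartition.
    """
    if scheme not in AGGREGATION_SCHEMES:
        raise ValueError(f"unknown aggregation scheme {scheme!r}; choose from {AGGREGATION_SCHEMES}")
    cells = groups.cells if hasattr(groups, "cells") else dict(groups)
    for col in ("gene_id", "sample", "replicate"):
        if col not in per_gene_values.columns:
            raise ValueError(f"per-gene table missing column {col!r}")

    samples = list(pd.unique(per_gene_values["sample"]))
    if scheme == "mean_of_gene_ratios":
        if "value" not in per_gene_values.columns:
            raise ValueError("scheme mean_of_gene_ratios requires a 'value' column")
        # replicate collapse: mean of defined per-replicate values
        rep = (
            per_gene_values.groupby(["gene_id", "sample"], sort=False)["value"]
            .mean()  # skipna: undefined replicate ratios are excluded
            .unstack("sample")
        )
        data = {}
        for label, members in cells.items():
            present = rep.reindex(sorted(members))
            data[label] = present.mean(axis=0, skipna=True)
        values = pd.DataFrame(data).T.reindex(columns=samples)
    else:
        for col in ("at_to_cg", "cg_to_at"):
            if col not in per_gene_values.columns:
                raise ValueError(f"scheme ratio_of_summed_counts requires a {col!r} column")
        rep = (
            per_gene_values.groupby(["gene_id", "sample"], sort=False)[["at_to_cg", "cg_to_at"]]
            .mean()  # "averaged sum": replicate counts averaged before summation
            .reset_index()
        )
        values = pd.DataFrame(index=list(cells), columns=samples, dtype=float)
        for label, members in cells.items():
            sub = rep[rep["gene_id"].isin(members)]
            for sample in samples:
                cell = sub[sub["sample"] == sample]
                num = cell["at_to_cg"].sum()
                den = cell["cg_to_at"].sum()
                values.loc[label, sample] = (num / den) if den > 0 else np.nan
    values.index.name = "group"
    values.columns.name = "sample"
    return GroupSampleMatrix(values=values.astype(float))
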
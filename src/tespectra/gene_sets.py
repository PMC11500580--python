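"""Gene-set construction and the disjoint Venn partition of TE-derived genes.

Builds the three kinds of gene sets the composition heatmaps are grouped
by — TE-derived genes per condition (merged across samples within each
condition), expression-changed genes (adjusted p < 0.05 and at least a
two-fold change), and splicing-changed genes — and intersects them into a
disjoint partition whose cells label every TE-derived gene by where it was
detected (condition A only / condition B only / both) and whether its
expression, splicing, or neither changed.

Upstream model fitting (edgeR-style dispersion/GLM, rMATS) is out of scope:
this module consumes their per-gene output tables and implements the
thresholding, CPM prefilter, BH adjustment, merging, and partition logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .io_formats import GeneStatRecord

CHANGE_STATES = ("de", "splicing", "neither")


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset[str]

    def __init__(self, label: str, members: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members


@dataclass(frozen=True)
class GeneGroupPartition:
    """A disjoint partition of a gene universe into labelled cells."""

    universe: frozenset[str]
    cells: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.cells.items():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"cell {label!r} overlaps earlier cells on {sorted(overlap)[:3]}")
            seen |= set(members)
        if seen != set(self.universe):
            raise ValueError("partition cells do not exactly cover the universe")

    def cell_sizes(self) -> dict[str, int]:
        return {label: len(m) for label, m in self.cells.items()}

    def cell_of(self, gene_id: str) -> str | None:
        for label, members in self.cells.items():
            if gene_id in members:
                return label
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "cell": label}
            for label, members in self.cells.items()
            for g in sorted(members)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "cell"])


def de_gene_set(
    stats: Iterable[GeneStatRecord],
    adj_p_max: float = 0.05,
    min_fold_change: float = 2.0,
    fc_strict: bool = False,
    label: str = "de",
) -> GeneSet:
    """Genes with adjusted p below ``adj_p_max`` (strict) and an absolute
    fold change of at least ``min_fold_change``.

    The fold-change threshold is applied on the log2 scale:
    |log2FC| >= log2(min_fold_change), inclusive by default (``fc_strict``
    switches to a strict inequality). Records with a missing p-value or
    fold change are excluded.
    """
    if adj_p_max <= 0 or min_fold_change <= 0:
        raise ValueError("thresholds must be positive")
    lfc_min = math.log2(min_fold_change)
    members = []
    for rec in stats:
        if rec.adjusted_p is None or rec.log2_fold_change is None:
            continue
        if rec.adjusted_p >= adj_p_max:
            continue
        magnitude = abs(rec.log2_fold_change)
        if (magnitude > lfc_min) if fc_strict else (magnitude >= lfc_min):
            members.append(rec.gene_id)
    return GeneSet(label, members)


def splicing_gene_set(stats: Iterable[GeneStatRecord], label: str = "splicing") -> GeneSet:
    """Genes flagged as splicing-changed."""
    return GeneSet(label, [rec.gene_id for rec in stats if rec.splicing_changed])


def cpm_prefilter(
    counts: pd.DataFrame, cpm_min: float = 0.5, min_libraries: int = 1, label: str = "expressed"
) -> GeneSet:
    """Low-expression prefilter: keep genes whose CPM (count * 1e6 / library
    total) reaches ``cpm_min`` in at least ``min_libraries`` libraries.

    ``counts`` is a gene x library matrix of non-negative counts (gene_id
    index).
    """
    if cpm_min <= 0 or min_libraries <= 0:
        raise ValueError("thresholds must be positive")
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        bad = counts.columns[int(np.flatnonzero(totals <= 0)[0])]
        raise ValueError(f"library {bad!r} has zero total count")
    cpm = mat * 1e6 / totals
    keep = (cpm >= cpm_min).sum(axis=1) >= min_libraries
    return GeneSet(label, [str(g) for g, k in zip(counts.index, keep) if k])


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if np.isnan(ps).any() or (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return _scipy_stats.false_discovery_control(ps, method="bh").tolist()


def merge_te_lists(
    per_sample_lists: Mapping[str, GeneSet], condition_of: Mapping[str, str]
) -> dict[str, GeneSet]:
    """Union each condition's per-sample TE-derived gene lists."""
    merged: dict[str, set[str]] = {}
    for sample, gene_set in per_sample_lists.items():
        if sample not in condition_of:
            raise ValueError(f"sample {sample!r} has no assigned condition")
        merged.setdefault(condition_of[sample], set()).update(gene_set.members)
    return {cond: GeneSet(cond, members) for cond, members in merged.items()}


def venn_partition(
    te_condition_a: GeneSet,
    te_condition_b: GeneSet,
    de: GeneSet,
    splicing: GeneSet,
    overlap_cell: bool = False,
    label_a: str | None = None,
    label_b: str | None = None,
) -> GeneGroupPartition:
    """Partition the TE-derived universe (te_A union te_B) into disjoint
    cells by detection signature (A only / B only / both) crossed with
    change status (de / splicing / neither).

    A gene in both the de and splicing sets is assigned to the de cell by
    default; with ``overlap_cell`` it lands in its own ``de+splicing`` cell
    instead. Only non-empty cells are materialised. Cell labels look like
    ``"A_only:de"``.
    """
    label_a = label_a or te_condition_a.label or "A"
    label_b = label_b or te_condition_b.label or "B"
    universe = te_condition_a.members | te_condition_b.members
    cells: dict[str, set[str]] = {}
    for gene in universe:
        in_a, in_b = gene in te_condition_a, gene in te_condition_b
        te_part = "both" if (in_a and in_b) else (f"{label_a}_only" if in_a else f"{label_b}_only")
        in_de, in_sp = gene in de, gene in splicing
        if in_de and in_sp and overlap_cell:
            change = "de+splicing"
        elif in_de:
            change = "de"
        elif in_sp:
            change = "splicing"
        else:
            change = "neither"
        cells.setdefault(f"{te_part}:{change}", set()).add(gene)
    return GeneGroupPartition(
        universe=frozenset(universe),
        cells={label: frozenset(members) for label, members in sorted(cells.items())},
    )
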
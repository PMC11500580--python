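"""End-to-end plumbing: pileups -> consensus -> spectra -> group matrices.

Thin orchestration over the core modules, shared by the CLI, the test
suite and the acceptance script.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import (
    SUBSTITUTION_CLASSES,
    GroupSampleMatrix,
    aggregate_group_matrix,
    count_substitutions,
    dinucleotide_density,
    substitution_ratio,
)
from .consensus_caller import ConsensusSequence, call_consensus
from .io_formats import GeneModel, Pileup, gene_sequence
from .synthetic_data import SyntheticExperiment


def consensus_for_sample(
    genes: Sequence[GeneModel],
    pileups: Mapping[str, Pileup],
    min_fraction=0.51,
    min_depth: int = 1,
) -> dict[str, ConsensusSequence]:
    """Call every gene's consensus from its pileup (missing gene -> all-N)."""
    out = {}
    for gene in genes:
        pile = pileups.get(gene.gene_id, Pileup.zeros(gene.length_bp))
        out[gene.gene_id] = call_consensus(
            pile, gene_id=gene.gene_id, min_fraction=min_fraction, min_depth=min_depth
        )
    return out


def spectrum_table(
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
    consensus: Mapping[str, ConsensusSequence],
) -> pd.DataFrame:
    """One row per gene: the 12 class counts, n_to_N, class sums, total/kb,
    the AT>CG / CG>AT ratio, and consensus CG / GC densities per kb."""
    rows = []
    for gene in genes:
        ref_seq = gene_sequence(reference, gene)
        cons = consensus[gene.gene_id]
        spec = count_substitutions(ref_seq, cons.seq, gene_id=gene.gene_id)
        row = {"gene_id": gene.gene_id, "length_bp": gene.length_bp}
        for cls in SUBSTITUTION_CLASSES:
            row[cls] = spec.count(cls)
        row["n_to_N"] = spec.n_to_N
        row["at_to_cg"] = spec.at_to_cg
        row["cg_to_at"] = spec.cg_to_at
        row["total_per_kb"] = spec.total_per_kb
        ratio = substitution_ratio(spec)
        row["ratio"] = np.nan if ratio is None else ratio
        row["cg_per_kb"] = dinucleotide_density(cons.seq, "CG", gene_id=gene.gene_id).per_kb
        row["gc_per_kb"] = dinucleotide_density(cons.seq, "GC", gene_id=gene.gene_id).per_kb
        rows.append(row)
    return pd.DataFrame(rows)


def experiment_spectra(
    experiment: SyntheticExperiment, min_fraction=0.51, min_depth: int = 1
) -> pd.DataFrame:
    """Run consensus + spectrum for every simulated (sample, replicate);
    returns a long table with gene_id, condition, sample, replicate, the
    spectrum columns, and ``value`` = the per-gene ratio (NaN = undefined)."""
    ref = experiment.reference
    chunks = []
    for run in experiment.runs:
        cons = consensus_for_sample(ref.genes, run.pileups, min_fraction, min_depth)
        table = spectrum_table(ref.genes, ref.reference, cons)
        table.insert(1, "condition", run.condition)
        table.insert(2, "sample", run.sample)
        table.insert(3, "replicate", run.replicate)
        chunks.append(table)
    long = pd.concat(chunks, ignore_index=True)
    long["value"] = long["ratio"]
    return long


def condition_ratio_matrix(
    experiment: SyntheticExperiment,
    groups: Mapping[str, set] | None = None,
    scheme: str = "mean_of_gene_ratios",
    min_fraction=0.51,
) -> GroupSampleMatrix:
    """Group x sample ratio matrix from a simulated experiment; default
    grouping is a single cell holding every gene."""
    long = experiment_spectra(experiment, min_fraction=min_fraction)
    if groups is None:
        groups = {"all": {g.gene_id for g in experiment.reference.genes}}
    return aggregate_group_matrix(long, groups, scheme=scheme)
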
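"""Synthetic reference genes, reads/pileups, islands and statistics tables.

Emulates the study design every pipeline stage is tested against: genes of
varying length and CG density laid on one synthetic chromosome, two
conditions (e.g. FXD vs healthy donors) with a small number of samples and
n = 3 sequencing replicates each, 100-bp single-end reads at a configured
mean coverage, and per-gene statistics tables with controlled fractions of
"changed" genes.

Substitutions are planted at the *haplotype* level (clonal): each sample
derives, once per gene, a haplotype from the reference in which every A/T
position flips to C or G with ``rate_at_to_cg`` and every C/G position
flips to A or T with ``rate_cg_to_at``; replicates of a sample share that
haplotype and differ only in read sampling and i.i.d. sequencing errors.
This matches a cell line sequenced against the reference genome, and is
what makes the 0.51 consensus rule able to recover the planted signal at
moderate coverage.

Randomness: a single run seed; every stream (per gene, sample, replicate)
is derived by stable hashing of its labels, so outputs are reproducible
and independent of iteration order.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from . import io_formats
from .composition import dinucleotide_density
from .gene_sets import GeneSet
from .io_formats import CpGIsland, GeneModel, Pileup, encode_sequence

#: Maximum attainable CG-dinucleotide density: CGCGCG... has one CG per 2 bp.
MAX_CG_PER_KB = 500.0

_A, _C, _G, _T = 0, 1, 2, 3
_BASE_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)


def derived_rng(seed: int, *tokens) -> np.random.Generator:
    """A generator derived from (seed, tokens) by stable hashing; the same
    labels always give the same stream regardless of call order."""
    key = "|".join([str(seed)] + [str(t) for t in tokens])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "big") & 0x7FFFFFFF)


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Rates may be a single float (shared by all conditions) or a
    {condition: rate} mapping. ``planted_cells`` optionally fixes the gene
    group structure exactly, as {"<te>:<change>": size} with te in
    {"<condA>_only", "<condB>_only", "both"} and change in
    {"de", "splicing", "neither"}; it overrides ``n_genes`` for group
    assignment.
    """

    seed: int = 0
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (5000, 8000)
    cg_density_targets: Mapping[str, float] = field(
        default_factory=lambda: {"cg_poor": 10.0, "cg_rich": 50.0}
    )
    conditions: tuple[str, str] = ("FXD", "healthy")
    samples_per_condition: int = 2
    replicates: int = 3
    coverage: float = 30.0
    read_length: int = 100
    rate_at_to_cg: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: {"FXD": 0.02, "healthy": 0.01}
    )
    rate_cg_to_at: Union[float, Mapping[str, float]] = 0.01
    error_rate: float = 0.001
    frac_de: float = 0.1
    frac_splicing: float = 0.2
    planted_cells: Mapping[str, int] | None = None
    chrom: str = "chr_sim"
    gap_bp: int = 5000

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.gene_length_range[0] < 2 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("invalid gene_length_range")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for name in ("error_rate", "frac_de", "frac_splicing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for cond in self.conditions:
            for r in (self.rate_for(cond, "at_to_cg"), self.rate_for(cond, "cg_to_at")):
                if not (0.0 <= r <= 1.0):
                    raise ValueError("substitution rates must lie in [0, 1]")

    def rate_for(self, condition: str, which: str) -> float:
        rate = self.rate_at_to_cg if which == "at_to_cg" else self.rate_cg_to_at
        if isinstance(rate, Mapping):
            return float(rate[condition])
        return float(rate)

    def sample_labels(self) -> list[tuple[str, str]]:
        """All (condition, sample_label) pairs of the design."""
        return [
            (cond, f"{cond}_s{i + 1}")
            for cond in self.conditions
            for i in range(self.samples_per_condition)
        ]


@dataclass
class GroundTruth:
    """Everything the simulator planted, for verification against pipeline output."""

    #: gene_id -> (te_status, change_status)
    gene_groups: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: gene_id -> CG density group label
    density_group: dict[str, str] = field(default_factory=dict)
    #: gene_id -> true CG dinucleotide count of the reference gene sequence
    cg_counts: dict[str, int] = field(default_factory=dict)
    #: sample_label -> gene_id -> dict(positions, ref, alt, at_to_cg, cg_to_at)
    substitutions: dict[str, dict[str, dict]] = field(default_factory=dict)
    #: sample_label -> condition
    condition_of: dict[str, str] = field(default_factory=dict)

    def planted_counts(self, sample: str, gene_id: str) -> tuple[int, int]:
        rec = self.substitutions[sample][gene_id]
        return rec["at_to_cg"], rec["cg_to_at"]

    def planted_ratio_mean(self, sample: str, genes: Sequence[str] | None = None) -> float:
        """Mean over genes of the per-gene planted AT>CG / CG>AT ratio
        (genes with zero planted CG>AT excluded), mirroring the pipeline's
        mean_of_gene_ratios scheme."""
        pool = genes if genes is not None else sorted(self.substitutions[sample])
        ratios = []
        for g in pool:
            at, cg = self.planted_counts(sample, g)
            if cg > 0:
                ratios.append(at / cg)
        return float(np.mean(ratios)) if ratios else float("nan")


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def _random_sequence_with_cg_target(
    rng: np.random.Generator, length: int, target_per_kb: float, max_attempts: int = 500
) -> str:
    """Draw a sequence whose CG-dinucleotide density lands within 10% of the
    target (accept/reject around an exact-expectation block construction).

    Construction: emit a "CG" block with probability q = d/(1-d) (d = target
    density per bp), else a single base; a single G is never emitted directly
    after a single C, so every CG dinucleotide is a block and the expected
    density is exactly q/(1+q) = d. Target 0 therefore yields exactly zero
    CG dinucleotides.
    """
    if target_per_kb < 0:
        raise ValueError("CG density target must be non-negative")
    if target_per_kb > MAX_CG_PER_KB:
        raise ValueError(
            f"CG density target {target_per_kb}/kb unattainable; the maximum of any "
            f"sequence (CGCGCG...) is {MAX_CG_PER_KB}/kb"
        )
    density = target_per_kb / 1000.0
    q = 1.0 if density >= 0.5 else density / (1.0 - density)
    # 10% relative band, but never narrower than half a count step (short
    # genes may have no integer CG count inside a bare 10% band)
    target_count = target_per_kb * length / 1000.0
    tol_counts = max(0.10 * target_count, 0.5 if target_per_kb > 0 else 0.0)
    for _ in range(max_attempts):
        chars: list[str] = []
        while len(chars) < length:
            if rng.random() < q:
                chars.append("C")
                chars.append("G")
            else:
                prev_c = bool(chars) and chars[-1] == "C"
                pool = "ACT" if prev_c else "ACGT"
                chars.append(pool[rng.integers(len(pool))])
        seq = "".join(chars[:length])
        measured = dinucleotide_density(seq, "CG").count
        if abs(measured - target_count) <= tol_counts:
            return seq
    raise RuntimeError(
        f"could not reach CG target {target_per_kb}/kb within 10% in {max_attempts} attempts"
    )


def _assign_groups(config: SimulationConfig, rng: np.random.Generator) -> dict[str, tuple[str, str]]:
    cond_a, cond_b = config.conditions[0], config.conditions[1]
    if config.planted_cells is not None:
        groups: dict[str, tuple[str, str]] = {}
        i = 0
        for cell, size in config.planted_cells.items():
            te_part, change = cell.rsplit(":", 1)
            for _ in range(size):
                groups[f"g{i + 1:05d}"] = (te_part, change)
                i += 1
        return groups
    groups = {}
    for i in range(config.n_genes):
        u = rng.random()
        te = f"{cond_a}_only" if u < 0.4 else (f"{cond_b}_only" if u < 0.8 else "both")
        v = rng.random()
        if v < config.frac_de:
            change = "de"
        elif v < config.frac_de + config.frac_splicing:
            change = "splicing"
        else:
            change = "neither"
        groups[f"g{i + 1:05d}"] = (te, change)
    return groups


def plant_gene_groups(config: SimulationConfig) -> GroundTruth:
    """Assign every gene a (te_status, change_status) signature without
    simulating sequences — enough input for simulate_stats_tables."""
    rng = derived_rng(config.seed, "groups")
    truth = GroundTruth()
    truth.gene_groups = _assign_groups(config, rng)
    return truth


@dataclass
class SyntheticReference:
    reference: dict[str, str]
    genes: list[GeneModel]
    islands: list[CpGIsland]
    truth: GroundTruth

    def gene_sequences(self) -> dict[str, str]:
        return {g.gene_id: io_formats.gene_sequence(self.reference, g) for g in self.genes}


def simulate_reference(config: SimulationConfig) -> SyntheticReference:
    """Generate the reference: gene sequences with per-group CG density
    targets (within 10%), laid on one chromosome with random-sequence gaps,
    plus CpG islands dropped into about half the gene bodies."""
    truth = plant_gene_groups(config)
    gene_ids = sorted(truth.gene_groups)
    density_labels = list(config.cg_density_targets)
    chrom_parts: list[str] = []
    genes: list[GeneModel] = []
    islands: list[CpGIsland] = []
    cursor = 0
    for idx, gene_id in enumerate(gene_ids):
        rng = derived_rng(config.seed, "gene", gene_id)
        gap = _random_sequence_with_cg_target(rng, config.gap_bp, 60.0)
        chrom_parts.append(gap)
        cursor += len(gap)
        length = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        group = density_labels[idx % len(density_labels)]
        seq = _random_sequence_with_cg_target(rng, length, config.cg_density_targets[group])
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(gene_id, config.chrom, cursor, cursor + length, strand)
        genes.append(gene)
        truth.density_group[gene_id] = group
        truth.cg_counts[gene_id] = dinucleotide_density(seq, "CG").count
        chrom_parts.append(seq)
        cursor += length
        if rng.random() < 0.5:
            isl_len = int(rng.integers(200, min(1001, length)))
            isl_start = gene.start + int(rng.integers(0, length - isl_len + 1))
            islands.append(CpGIsland(config.chrom, isl_start, isl_start + isl_len))
    tail = _random_sequence_with_cg_target(derived_rng(config.seed, "tail"), config.gap_bp, 60.0)
    chrom_parts.append(tail)
    reference = {config.chrom: "".join(chrom_parts)}
    return SyntheticReference(reference=reference, genes=genes, islands=islands, truth=truth)


# ---------------------------------------------------------------------------
# Sample simulation (haplotype + reads -> pileups, optional SAM)
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRead:
    gene_id: str
    start: int  # gene-local, after clipping
    seq: str


@dataclass
class SampleRun:
    condition: str
    sample: str
    replicate: int
    pileups: dict[str, Pileup]
    reads: list[SimulatedRead] | None = None


def _haplotype(
    config: SimulationConfig, condition: str, sample: str, gene_id: str, ref_codes: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Derive the sample's clonal haplotype for one gene and record the
    planted substitutions. Shared across replicates by construction."""
    rng = derived_rng(config.seed, "hap", condition, sample, gene_id)
    hap = ref_codes.copy()
    rate_at = config.rate_for(condition, "at_to_cg")
    rate_cg = config.rate_for(condition, "cg_to_at")
    u = rng.random(len(hap))
    is_at = (hap == _A) | (hap == _T)
    is_cg = (hap == _C) | (hap == _G)
    flip_at = is_at & (u < rate_at)
    flip_cg = is_cg & (u < rate_cg)
    # uniform choice of target within each class
    hap[flip_at] = np.where(rng.random(int(flip_at.sum())) < 0.5, _C, _G)
    hap[flip_cg] = np.where(rng.random(int(flip_cg.sum())) < 0.5, _A, _T)
    positions = np.flatnonzero(flip_at | flip_cg)
    record = {
        "positions": positions,
        "ref": ref_codes[positions].copy(),
        "alt": hap[positions].copy(),
        "at_to_cg": int(flip_at.sum()),
        "cg_to_at": int(flip_cg.sum()),
    }
    return hap, record


def _simulate_gene_reads(
    rng: np.random.Generator,
    hap: np.ndarray,
    coverage: float,
    read_length: int,
    error_rate: float,
    want_reads: bool,
) -> tuple[np.ndarray, list[tuple[int, np.ndarray]]]:
    """Sample clipped single-end reads from the haplotype and pile them up.

    Read starts are uniform over [-(read_length - 1), L - 1] and clipped to
    the gene, so depth is approximately Poisson(coverage) across the whole
    gene, edges included.
    """
    length = len(hap)
    n_reads = rng.poisson(coverage * (length + read_length - 1) / read_length)
    starts = rng.integers(-(read_length - 1), length, size=n_reads)
    lo = np.clip(starts, 0, None)
    hi = np.clip(starts + read_length, None, length)
    spans = hi - lo
    keep = spans > 0
    lo, spans = lo[keep], spans[keep]
    total = int(spans.sum())
    # flat positions of every read base (repeat/cumsum trick)
    offsets = np.repeat(np.concatenate([[0], np.cumsum(spans)[:-1]]), spans)
    flat_pos = np.repeat(lo, spans) + (np.arange(total) - offsets)
    bases = hap[flat_pos].copy()
    if error_rate > 0:
        err = rng.random(total) < error_rate
        n_err = int(err.sum())
        if n_err:
            bases[err] = (bases[err] + rng.integers(1, 4, size=n_err)) % 4
    counts = np.bincount(flat_pos * 4 + bases, minlength=length * 4).reshape(length, 4)
    reads: list[tuple[int, np.ndarray]] = []
    if want_reads:
        bounds = np.concatenate([[0], np.cumsum(spans)])
        for i in range(len(spans)):
            reads.append((int(lo[i]), bases[bounds[i]:bounds[i + 1]]))
    return counts.astype(np.int64), reads


def simulate_sample(
    reference: SyntheticReference,
    config: SimulationConfig,
    condition: str,
    sample: str,
    replicate: int,
    want_reads: bool = False,
) -> tuple[SampleRun, dict[str, dict]]:
    """Simulate one sequencing replicate of one sample: per-gene pileups
    (and, optionally, the underlying reads for SAM output), plus the
    planted-substitution ground truth of the sample's haplotype."""
    gene_seqs = reference.gene_sequences()
    pileups: dict[str, Pileup] = {}
    reads: list[SimulatedRead] = []
    truth_records: dict[str, dict] = {}
    for gene in reference.genes:
        ref_codes = encode_sequence(gene_seqs[gene.gene_id])
        hap, record = _haplotype(config, condition, sample, gene.gene_id, ref_codes)
        truth_records[gene.gene_id] = record
        rng = derived_rng(config.seed, "reads", condition, sample, replicate, gene.gene_id)
        counts, gene_reads = _simulate_gene_reads(
            rng, hap, config.coverage, config.read_length, config.error_rate, want_reads
        )
        pileups[gene.gene_id] = Pileup(counts)
        if want_reads:
            for start, codes in gene_reads:
                reads.append(
                    SimulatedRead(gene.gene_id, start, _BASE_CHARS[codes].tobytes().decode())
                )
    run = SampleRun(condition, sample, replicate, pileups, reads if want_reads else None)
    return run, truth_records


def write_sam(
    run: SampleRun, reference: SyntheticReference, path: Union[str, os.PathLike]
) -> None:
    """Write a replicate's simulated reads as plain SAM (chromosome coords)."""
    if run.reads is None:
        raise ValueError("sample was simulated without reads; pass want_reads=True")
    genes = {g.gene_id: g for g in reference.genes}
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": len(seq)} for chrom, seq in reference.reference.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, read in enumerate(run.reads):
            gene = genes[read.gene_id]
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = f"{run.sample}_r{run.replicate}_{i}"
            aln.query_sequence = read.seq
            aln.flag = 0
            aln.reference_id = list(reference.reference).index(gene.chrom)
            aln.reference_start = gene.start + read.start
            aln.mapping_quality = 60
            aln.cigarstring = f"{len(read.seq)}M"
            aln.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            out.write(aln)


# ---------------------------------------------------------------------------
# Statistics tables
# ---------------------------------------------------------------------------

@dataclass
class StatsTables:
    de: pd.DataFrame  # gene_id, adjusted_p, log2_fold_change
    splicing: pd.DataFrame  # gene_id, splicing_changed
    te_lists: dict[str, GeneSet]  # sample label -> TE-derived gene set
    condition_of: dict[str, str]


def simulate_stats_tables(config: SimulationConfig, truth: GroundTruth) -> StatsTables:
    """Emit DE and splicing tables plus per-sample TE lists that reproduce
    the planted group structure exactly.

    Genes planted as "de" get adjusted_p < 0.05 and |log2FC| >= 1; all
    others get adjusted_p >= 0.05, so thresholding recovers the planted de
    set whatever their fold changes. TE-list membership is split across each
    condition's samples so the within-condition union equals the planted
    per-condition set.
    """
    if not truth.gene_groups:
        raise ValueError("GroundTruth carries no gene group assignments")
    rng = derived_rng(config.seed, "stats")
    cond_a, cond_b = config.conditions[0], config.conditions[1]
    gene_ids = sorted(truth.gene_groups)

    de_rows, sp_rows = [], []
    for gene_id in gene_ids:
        _, change = truth.gene_groups[gene_id]
        if change == "de":
            p = rng.uniform(1e-4, 0.049)
            lfc = rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 4.0)
        else:
            p = rng.uniform(0.05, 1.0)
            lfc = rng.uniform(-0.9, 0.9)
        de_rows.append({"gene_id": gene_id, "adjusted_p": p, "log2_fold_change": lfc})
        sp_rows.append({"gene_id": gene_id, "splicing_changed": change == "splicing"})

    samples = config.sample_labels()
    condition_of = {label: cond for cond, label in samples}
    per_sample: dict[str, set[str]] = {label: set() for _, label in samples}
    for gene_id in gene_ids:
        te, _ = truth.gene_groups[gene_id]
        for cond in config.conditions:
            if te != "both" and te != f"{cond}_only":
                continue
            cond_samples = [label for c, label in samples if c == cond]
            chosen = [label for label in cond_samples if rng.random() < 0.6]
            if not chosen:
                chosen = [cond_samples[int(rng.integers(len(cond_samples)))]]
            for label in chosen:
                per_sample[label].add(gene_id)
    te_lists = {label: GeneSet(label, members) for label, members in per_sample.items()}
    return StatsTables(
        de=pd.DataFrame(de_rows),
        splicing=pd.DataFrame(sp_rows),
        te_lists=te_lists,
        condition_of=condition_of,
    )


# ---------------------------------------------------------------------------
# Whole-experiment orchestration and file emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    config: SimulationConfig
    reference: SyntheticReference
    runs: list[SampleRun]
    stats: StatsTables

    @property
    def truth(self) -> GroundTruth:
        return self.reference.truth


def simulate_experiment(config: SimulationConfig, want_reads: bool = False) -> SyntheticExperiment:
    """Simulate the full design: reference, every (sample, replicate) run,
    and the statistics tables; ground truth accumulates on the reference."""
    reference = simulate_reference(config)
    runs: list[SampleRun] = []
    for condition, sample in config.sample_labels():
        reference.truth.condition_of[sample] = condition
        for replicate in range(1, config.replicates + 1):
            run, records = simulate_sample(
                reference, config, condition, sample, replicate, want_reads=want_reads
            )
            reference.truth.substitutions[sample] = records
            runs.append(run)
    stats = simulate_stats_tables(config, reference.truth)
    return SyntheticExperiment(config=config, reference=reference, runs=runs, stats=stats)


def write_experiment(experiment: SyntheticExperiment, outdir: Union[str, os.PathLike]) -> None:
    """Emit the experiment as plain-text files: reference.fasta, genes.bed,
    islands.bed, per-run pileup TSVs (and SAM when reads were kept), de.tsv,
    splicing.tsv, te_lists/, conditions.tsv and truth.json."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    ref = experiment.reference
    io_formats.write_fasta(ref.reference, os.path.join(outdir, "reference.fasta"))
    io_formats.write_gene_models(ref.genes, os.path.join(outdir, "genes.bed"))
    io_formats.write_intervals(ref.islands, os.path.join(outdir, "islands.bed"))
    for run in experiment.runs:
        stem = f"{run.sample}_rep{run.replicate}"
        io_formats.write_pileup_tsv(run.pileups, os.path.join(outdir, f"pileup_{stem}.tsv"))
        if run.reads is not None:
            write_sam(run, ref, os.path.join(outdir, f"reads_{stem}.sam"))
    io_formats.write_table(experiment.stats.de, os.path.join(outdir, "de.tsv"))
    io_formats.write_table(experiment.stats.splicing, os.path.join(outdir, "splicing.tsv"))
    te_dir = os.path.join(outdir, "te_lists")
    os.makedirs(te_dir, exist_ok=True)
    for label, gene_set in experiment.stats.te_lists.items():
        frame = pd.DataFrame({"gene_id": sorted(gene_set.members)})
        io_formats.write_table(frame, os.path.join(te_dir, f"{label}.tsv"))
    cond = pd.DataFrame(
        [{"sample": s, "condition": c} for s, c in experiment.stats.condition_of.items()]
    )
    io_formats.write_table(cond, os.path.join(outdir, "conditions.tsv"))
    truth = experiment.truth
    payload = {
        "gene_groups": {g: list(v) for g, v in truth.gene_groups.items()},
        "density_group": truth.density_group,
        "cg_counts": truth.cg_counts,
        "condition_of": truth.condition_of,
        "planted_counts": {
            sample: {g: [rec["at_to_cg"], rec["cg_to_at"]] for g, rec in records.items()}
            for sample, records in truth.substitutions.items()
        },
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(payload, fh, indent=1)
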
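# tespectra

Consensus-based nucleotide-composition analysis of transposon-derived
genes from RNA-seq.

Some disease states leave a compositional fingerprint on the genes that
derive from transposable elements (TEs): an excess of weak-to-strong base
substitutions (A/T → C/G) and elevated CpG-dinucleotide content, a pattern
reminiscent of latent RNA-virus genomes that evade CG-suppression-based
antiviral surveillance. `tespectra` implements the complete analysis needed
to measure that fingerprint from aligned short-read RNA-seq data, for
anyone comparing nucleotide composition between conditions (patient vs
healthy donor cell lines, infected vs naive cells, and so on):

1. **Per-gene pileups** from SAM/BAM (or a simplified pileup TSV), with
   strict 0-based half-open coordinates; insertions and deletions never
   contribute counts.
2. **Consensus calling** with a minimum-fraction rule: a base is emitted
   when its count reaches fraction ≥ 0.51 of the column depth, else `N`.
3. **The 12-class substitution spectrum** of consensus vs reference, with
   class sums

   AT>CG = (A>C) + (A>G) + (T>C) + (T>G),
   CG>AT = (C>A) + (C>T) + (G>A) + (G>T),

   the per-gene statistic *r* = AT>CG / CG>AT, and totals normalised per
   1000 bp of gene length. Both class sets are closed under complementation,
   so *r* is invariant to mapping strand.
4. **CG / GC dinucleotide densities** (overlapping windows, per-kb
   normalised, N-containing windows skipped).
5. **Gene-set construction and Venn partitioning**: differential-expression
   thresholding (adjusted *p* < 0.05 and |log2FC| ≥ 1), CPM ≥ 0.5
   prefiltering, Benjamini–Hochberg adjustment, per-condition merging of
   TE gene lists, and the disjoint partition of TE-derived genes by
   detection condition × change status that defines the row groups of the
   ratio heatmaps (group × sample matrices with a row z-score view).
6. **CpG-island metagene profiles** over gene bodies ± 2 kb, smoothed with
   a univariate spline (smoothing factor 5).
7. **A synthetic-data generator** that plants clonal substitutions at known
   class-specific rates and emits reference FASTA, BED, reads (SAM or
   pileup TSV) and statistics tables with full ground truth, so every stage
   of the pipeline is verifiable end to end.

## Worked example

Simulate a two-condition study (12 genes, 2 samples × 3 replicates per
condition, coverage 30×) in which the FXD condition carries A/T → C/G
substitutions at rate 0.02 per base and healthy at 0.01, both over a
C/G → A/T rate of 0.01; then run the full pipeline and compare with the
planted truth:

```python
from tespectra import SimulationConfig, simulate_experiment
from tespectra.workflow import condition_ratio_matrix
from tespectra.composition import row_zscore

cfg = SimulationConfig(seed=1, n_genes=12, gene_length_range=(2000, 3000),
                       samples_per_condition=2, replicates=3, coverage=30.0)
exp = simulate_experiment(cfg)
matrix = condition_ratio_matrix(exp)
print(matrix.values.round(3))
print(row_zscore(matrix.values).round(3))
for sample in sorted(exp.truth.condition_of):
    print(f"truth {sample}: {exp.truth.planted_ratio_mean(sample):.3f}")
```

Output:

```
sample  FXD_s1  FXD_s2  healthy_s1  healthy_s2
group
all      2.023   2.054       1.205       1.164

sample  FXD_s1  FXD_s2  healthy_s1  healthy_s2
group
all      0.834   0.896      -0.824      -0.907

truth FXD_s1: 2.023
truth FXD_s2: 2.054
truth healthy_s1: 1.205
truth healthy_s2: 1.164
```

The first matrix holds the group-mean AT>CG/CG>AT ratio per sample
(replicates averaged first, then genes): ≈ 2 in the high-rate condition and
≈ 1.2 in the low-rate condition, matching the ratio of the planted rates.
The z-score view standardises each row, separating the conditions. At 30×
coverage the pipeline estimates equal the planted truth to three decimals —
the 0.51-fraction consensus reconstructs each sample's clonal haplotype
essentially exactly.

A command-line interface mirrors the library
(`tespectra simulate|consensus|spectrum|dinuc|ratio-matrix|groups|cpg-profile`);
run `tespectra --help` for options.

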
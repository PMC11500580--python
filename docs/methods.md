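# Methods

## The measurement

Given reads aligned to a reference genome and a set of gene models, the
pipeline asks, per gene: *at how many positions does the sample's
expressed sequence differ from the reference, and in which direction?*

The expressed sequence is summarised by a consensus call. For each
gene-local position the pileup counts of A, C, G, T are collected from
aligned match/mismatch bases only — insertions are skipped, deleted
reference positions receive no count, soft-clipped bases are ignored, and
no base-quality filter is applied. A base *b* is called when

    count(b) / depth >= min_fraction        (default 0.51, inclusive)

and `N` is called otherwise (including depth 0). Because the threshold
exceeds 1/2, at most one base can qualify, so the call is deterministic
and unambiguous. The comparison is evaluated in exact integer arithmetic
(`count * denominator >= depth * numerator` with the threshold held as a
rational number), so a column at exactly 51/100 is called and one at
50/100 is not, with no floating-point edge behaviour. The only depth
requirement is depth ≥ 1; a stricter `min_depth` is available but off by
default.

Comparing consensus to reference position-wise yields counts of the 12
ordered substitution classes ref→cons. Class sums are

    AT>CG = A>C + A>G + T>C + T>G
    CG>AT = C>A + C>T + G>A + G>T

and the per-gene statistic is the ratio AT>CG / CG>AT. Positions whose
consensus is `N` are tallied separately (`n_to_N`): they count toward the
total substitution load (and the per-kb normalisation, total / (length /
1000)) but toward neither class sum, which keeps the conservation identity

    #\{i : cons[i] != ref[i]\} = sum of 12 classes + n_to_N

exactly testable. Both class sets are closed under complementation
(e.g. the complement of A>C is T>G, also in AT>CG), so reverse-
complementing both sequences — equivalently, counting reads in either
orientation — leaves both sums and the ratio unchanged. This is why the
pileup deliberately ignores mapping strand.

A gene with CG>AT = 0 has an undefined ratio; it is recorded as missing
and excluded from group means rather than patched with a pseudocount
(a pseudocount argument exists but defaults to 0).

## Aggregation to group × sample matrices

The replicate dimension is always collapsed first by arithmetic mean
(undefined per-replicate ratios excluded). The gene dimension is then
collapsed by one of two schemes, both first-class because they answer
subtly different questions:

* `mean_of_gene_ratios` (default): the mean of per-gene ratios — every
  gene contributes equally.
* `ratio_of_summed_counts`: AT>CG and CG>AT counts are summed over the
  group first and then divided — long or highly-substituted genes dominate,
  but genes with CG>AT = 0 still contribute their numerator.

A cell with no defined value left is missing. The z-score view
standardises each row with the sample standard deviation (ddof 1 — the
conventional small-n choice); rows with fewer than two non-missing cells
or zero SD become all-missing rather than producing infinities.

## Dinucleotide densities

CG (CpG) and GC densities are overlapping sliding-window counts (step 1)
normalised per kb of gene length. Windows containing `N` are skipped and
excluded from the count of valid windows. CG and GC are
reverse-complement palindromes, so their counts are strand-invariant —
property-tested, and the reason no strand handling appears in this code
path.

## Gene sets and the Venn partition

A gene is expression-changed when adjusted *p* < 0.05 (strict) and
|log2 fold change| ≥ 1 (inclusive). The fold-change boundary is stated
ambiguously in common usage ("at least two-fold" vs a strict inequality
on the log scale); the default is the inclusive reading, and `fc_strict`
switches to the exclusive one. The CPM prefilter keeps genes with
count·10⁶ / library-total ≥ 0.5 in at least one library. BH adjustment
delegates to `scipy.stats.false_discovery_control` and is verified in the
test suite against a brute-force implementation of the step-up
definition.

Per-sample TE-derived gene lists are merged by union within each
condition. The partition universe is te(A) ∪ te(B); each gene is labelled
by detection signature (A only / B only / both) crossed with change
status (expression-changed / splicing-changed / neither). A gene in both
the expression and splicing sets is assigned to the expression cell —
the two sets rarely overlap in practice — unless `overlap_cell` requests
a dedicated `de+splicing` cell. Cells are non-empty, pairwise disjoint,
and cover the universe by construction (validated at construction time).

Upstream model fitting (edgeR-style GLMs, splicing callers) is out of
scope; this module consumes their per-gene output tables.

## CpG-island metagene profiles

Islands overlapping a gene's window — gene body ± 2 kb flanks, half-open
arithmetic, ≥ 1 bp overlap — are clipped to the window. Coverage (bp of
island per bin) is accumulated into 20 fixed 100-bp bins per flank and
100 scaled gene-body bins; genes shorter than the bin count are binned by
fractional overlap. Minus-strand genes are flipped so upstream is always
5′. The profile is the per-bin mean across genes; genes without islands
stay in the denominator so group sizes remain comparable. Bin sums
therefore equal total clipped island coverage divided by gene count — an
exact conservation law the tests exploit. Coverage, not midpoint
counting, is the default (robust to island length); `mode="midpoint"` is
available. Overlapping islands are accumulated independently (coverage
may exceed bin width if the input islands themselves overlap).

Smoothing fits `scipy.interpolate.UnivariateSpline` (cubic, smoothing
factor *s* = 5 by default) over bin index. A constant profile is a fixed
point; *s* = 0 interpolates the raw values; profiles with fewer than 4
bins cannot support a cubic spline and are returned raw with a warning
flag. Raw values are never altered by smoothing.

## The synthetic-data generator

The generator defines the study conditions every stage is tested under.
Defaults, chosen once to mirror a small two-condition cell-line study:

| parameter | default | rationale |
|---|---|---|
| n_genes | 50 | enough genes for stable group means at desk scale |
| gene length | 5–8 kb | typical mature transcript scale; ≥ 5 kb gives per-gene class counts large enough for meaningful per-gene ratios |
| conditions × samples × replicates | 2 × 2 × 3 | two-arm design with n = 3 sequencing replicates per sample |
| coverage | 30× | moderate RNA-seq depth at which the 0.51 rule is near-deterministic |
| read length | 100 bp single-end | standard short-read configuration |
| rate_at_to_cg | FXD 0.02, healthy 0.01 | condition-specific weak→strong rate, the signal under study |
| rate_cg_to_at | 0.01 | shared strong→weak background |
| error_rate | 0.001 | Illumina-scale per-base error |
| CG targets | 10 and 50 per kb | a CG-suppressed and a CG-rich gene class |

Substitutions are planted at the **haplotype** level: each (sample, gene)
derives one mutated copy of the reference — every A/T position flips to C
or G with `rate_at_to_cg`, every C/G position to A or T with
`rate_cg_to_at` — and all of that sample's replicates sequence the same
haplotype. This clonal model (a cell line vs the reference genome) is
what the consensus rule is designed to detect; per-read noise enters only
through the sequencing error rate. Read start positions are uniform over
[−(read_length−1), L−1] and clipped to the gene, so depth is approximately
Poisson(coverage) across the entire gene including its edges; with zero
rates this makes consensus == reference an exact, testable identity.

Reference sequences hit a per-gene CG-density target by a block
construction with exact expectation: a CG block is emitted with
probability q = d/(1−d) (d = target density per bp), single bases
otherwise, and a lone G is never emitted directly after a lone C — so
every CG dinucleotide is a planted block. An accept/reject loop then
enforces a 10% relative band around the target count, widened to at least
half a count so that short genes (where no integer count may fall inside
a bare 10% band) remain feasible. The maximum CG density of any sequence
is 500/kb (CGCGCG…); targets above that are rejected as unattainable.

Statistics tables reproduce the planted group structure exactly: planted
expression-changed genes receive adjusted *p* < 0.05 and |log2FC| ≥ 1,
all others *p* ≥ 0.05; TE-list membership is split randomly across each
condition's samples with the within-condition union equal to the planted
set, so merging + thresholding + partitioning recovers the planted cells
identically.

All randomness derives from one run seed; every stream (per gene, sample,
replicate) is a hash-derived substream, so outputs are byte-reproducible
and independent of iteration order, and replicates share their sample's
haplotype by construction rather than by state-passing.

### What the simulation does not emulate

No splice junctions, no transcript-level expression variation, no indels,
no strand-specific library artefacts, no mapping ambiguity (reads are
placed at their true positions), and no correlated error profiles. Passing
tests therefore demonstrate the correctness of the statistics and their
estimators under the stated clonal-substitution model — not robustness to
alignment error or splicing complexity in real data, which upstream
aligners and annotation handle.

## Numerical choices and degenerate inputs

* Consensus threshold comparisons are exact rational arithmetic; all other
  statistics are integer counts until the final division.
* Undefined ratios are missing values throughout, never infinities.
* Zero-depth pileup columns call `N`; an alignment file without a gene's
  reads yields an all-zero pileup (not an error).
* A gene shorter than the body-bin count is profiled by fractional
  overlap; empty gene lists are an error for metagene profiling.
* Problem sizes in the test suite and acceptance script (50 genes of
  5–8 kb at 30×, 708 genes for the partition recovery) were chosen as the
  smallest designs at which each property is informative.
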
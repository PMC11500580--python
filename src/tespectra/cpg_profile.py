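"""CpG-island metagene profiles over gene bodies with +/- 2 kb flanks.

Islands overlapping a gene's window (body plus flanks) by at least 1 bp
are kept and clipped to the window. Coverage is accumulated into fixed
100-bp flank bins and 100 scaled gene-body bins, flipped for minus-strand
genes so that upstream is always 5', and averaged over genes. The raw
profile is optionally smoothed with a univariate smoothing spline
(default smoothing factor 5); the raw values are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .io_formats import CpGIsland, GeneModel

PROFILE_MODES = ("coverage", "midpoint")


@dataclass(frozen=True)
class MetageneProfile:
    """A positional island profile for one gene group.

    ``raw`` holds, per bin, mean island coverage in bp across genes (or the
    mean number of island midpoints in midpoint mode). ``regions`` labels
    each bin as upstream / body / downstream; upstream and downstream each
    span ``flank_bp`` of fixed-width bins, body bins are in scaled
    (fractional) gene coordinates.
    """

    group_label: str
    regions: tuple[str, ...]
    raw: np.ndarray
    smoothed: np.ndarray | None
    n_genes: int
    n_genes_with_island: int
    body_bins: int
    flank_bin_bp: int
    flank_bp: int
    smoothing_warning: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.raw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group_label,
                "region": list(self.regions),
                "bin": np.arange(self.n_bins),
                "raw": self.raw,
                "smoothed": self.smoothed if self.smoothed is not None else np.nan,
            }
        )


def islands_overlapping_gene(
    islands: Iterable[CpGIsland], gene: GeneModel, flank_bp: int = 2000
) -> list[CpGIsland]:
    """Islands overlapping the gene window [start - flank, end + flank) by at
    least 1 bp, clipped to that window (half-open arithmetic)."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    lo, hi = gene.start - flank_bp, gene.end + flank_bp
    kept = []
    for isl in islands:
        if isl.chrom != gene.chrom:
            continue
        clipped_lo, clipped_hi = max(isl.start, lo), min(isl.end, hi)
        if clipped_hi - clipped_lo >= 1:
            kept.append(CpGIsland(isl.chrom, clipped_lo, clipped_hi))
    return kept


def _bin_edges(gene: GeneModel, body_bins: int, flank_bin_bp: int, flank_bp: int) -> np.ndarray:
    if flank_bp % flank_bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of flank_bin_bp")
    n_flank = flank_bp // flank_bin_bp
    up = gene.start - flank_bp + flank_bin_bp * np.arange(n_flank + 1, dtype=float)
    body = gene.start + gene.length_bp * np.arange(body_bins + 1, dtype=float) / body_bins
    down = gene.end + flank_bin_bp * np.arange(n_flank + 1, dtype=float)
    return np.concatenate([up, body[1:], down[1:]])


def _gene_vector(
    gene: GeneModel,
    islands: Sequence[CpGIsland],
    body_bins: int,
    flank_bin_bp: int,
    flank_bp: int,
    mode: str,
) -> np.ndarray:
    edges = _bin_edges(gene, body_bins, flank_bin_bp, flank_bp)
    vec = np.zeros(len(edges) - 1)
    for isl in islands_overlapping_gene(islands, gene, flank_bp):
        if mode == "coverage":
            overlap = np.minimum(isl.end, edges[1:]) - np.maximum(isl.start, edges[:-1])
            vec += np.clip(overlap, 0.0, None)
        else:  # midpoint
            mid = (isl.start + isl.end) / 2.0
            idx = int(np.clip(np.searchsorted(edges, mid, side="right") - 1, 0, len(vec) - 1))
            vec[idx] += 1.0
    if gene.strand == "-":
        vec = vec[::-1]
    return vec


def metagene_bin(
    islands_per_gene: Mapping[str, Sequence[CpGIsland]],
    genes: Sequence[GeneModel],
    body_bins: int = 100,
    flank_bin_bp: int = 100,
    flank_bp: int = 2000,
    group_label: str = "",
    mode: str = "coverage",
) -> MetageneProfile:
    """Accumulate per-gene island coverage into a raw metagene profile.

    ``islands_per_gene`` maps gene_id to the islands overlapping that gene's
    window (clipping is re-applied internally, so raw islands are fine).
    Genes absent from the mapping contribute zero coverage but stay in the
    denominator. Minus-strand genes are flipped so upstream is always 5'.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    if mode not in PROFILE_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {PROFILE_MODES}")
    n_flank = flank_bp // flank_bin_bp
    total = np.zeros(2 * n_flank + body_bins)
    n_with = 0
    for gene in genes:
        islands = islands_per_gene.get(gene.gene_id, ())
        vec = _gene_vector(gene, islands, body_bins, flank_bin_bp, flank_bp, mode)
        if vec.sum() > 0:
            n_with += 1
        total += vec
    regions = (
        ("upstream",) * n_flank + ("body",) * body_bins + ("downstream",) * n_flank
    )
    return MetageneProfile(
        group_label=group_label,
        regions=regions,
        raw=total / len(genes),
        smoothed=None,
        n_genes=len(genes),
        n_genes_with_island=n_with,
        body_bins=body_bins,
        flank_bin_bp=flank_bin_bp,
        flank_bp=flank_bp,
    )


def smooth_profile(profile: MetageneProfile, smoothing_factor: float = 5.0) -> MetageneProfile:
    """Fit a cubic smoothing spline over bin index (smoothing factor = the
    spline's residual budget); the raw profile is stored unchanged.

    Profiles with fewer than 4 bins cannot support a cubic spline; they get
    ``smoothed == raw`` with ``smoothing_warning`` set.
    """
    if smoothing_factor < 0:
        raise ValueError("smoothing_factor must be >= 0")
    n = profile.n_bins
    if n < 4:
        return replace(profile, smoothed=profile.raw.copy(), smoothing_warning=True)
    x = np.arange(n, dtype=float)
    spline = UnivariateSpline(x, profile.raw, k=3, s=smoothing_factor)
    return replace(profile, smoothed=spline(x), smoothing_warning=False)


def group_profiles(
    islands: Sequence[CpGIsland],
    genes: Sequence[GeneModel],
    groups: Mapping[str, set],
    body_bins: int = 100,
    flank_bin_bp: int = 100,
    flank_bp: int = 2000,
    smoothing_factor: float = 5.0,
    mode: str = "coverage",
) -> dict[str, MetageneProfile]:
    """Smoothed metagene profile per gene group (convenience wrapper)."""
    by_id = {g.gene_id: g for g in genes}
    out = {}
    for label, members in groups.items():
        group_genes = [by_id[g] for g in sorted(members) if g in by_id]
        if not group_genes:
            continue
        per_gene = {
            g.gene_id: islands_overlapping_gene(islands, g, flank_bp) for g in group_genes
        }
        prof = metagene_bin(
            per_gene, group_genes, body_bins, flank_bin_bp, flank_bp, label, mode
        )
        out[label] = smooth_profile(prof, smoothing_factor)
    return out
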
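"""Per-gene consensus calling from pileup columns.

A base is emitted at a position when its count reaches a minimum fraction
of the depth (default 0.51, inclusive); otherwise the position is called
``N``. Because the threshold exceeds 1/2, at most one base can qualify, so
the call is unambiguous. Fractions are compared in exact integer arithmetic
(``count * denominator >= depth * numerator``) so the 51/100 boundary is
never subject to floating-point rounding. No insertions or deletions are
ever emitted; zero-depth positions call ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Union

import numpy as np

from .io_formats import BASES, Pileup, PileupColumn

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N_BYTE = ord("N")


@dataclass(frozen=True)
class ConsensusSequence:
    """A called per-gene consensus over {A, C, G, T, N}."""

    gene_id: str
    seq: str
    n_called: int
    n_failed: int

    def __post_init__(self) -> None:
        if self.n_called + self.n_failed != len(self.seq):
            raise ValueError(
                f"consensus {self.gene_id!r}: n_called + n_failed != sequence length"
            )


def _threshold_parts(min_fraction) -> tuple[int, int]:
    frac = min_fraction if isinstance(min_fraction, Fraction) else Fraction(str(min_fraction))
    if not (Fraction(1, 2) < frac <= 1):
        raise ValueError(
            f"min_fraction must satisfy 0.5 < f <= 1 (got {min_fraction}); "
            "a threshold at or below 1/2 would make ties ambiguous"
        )
    return frac.numerator, frac.denominator


def call_base(column: PileupColumn, min_fraction=0.51, min_depth: int = 1) -> str:
    """Call one position: the base whose fraction of depth reaches
    ``min_fraction`` (inclusive), else ``N``. Zero depth calls ``N``."""
    num, den = _threshold_parts(min_fraction)
    depth = column.depth
    if depth < max(min_depth, 1):
        return "N"
    for base in BASES:
        if column.count(base) * den >= depth * num:
            return base
    return "N"


def call_consensus_counts(counts: np.ndarray, min_fraction=0.51, min_depth: int = 1) -> np.ndarray:
    """Vectorised consensus over an (L, 4) count matrix; returns byte codes
    of the called sequence (``A C G T N`` as uint8)."""
    num, den = _threshold_parts(min_fraction)
    counts = np.asarray(counts, dtype=np.int64)
    depth = counts.sum(axis=1)
    qualifies = counts * den >= depth[:, None] * num
    qualifies &= (depth >= max(min_depth, 1))[:, None]
    called = qualifies.any(axis=1)
    out = np.full(counts.shape[0], _N_BYTE, dtype=np.uint8)
    out[called] = _BASE_BYTES[qualifies.argmax(axis=1)[called]]
    return out


def call_consensus(
    columns: Union[Pileup, Iterable[PileupColumn]],
    gene_id: str = "",
    min_fraction=0.51,
    min_depth: int = 1,
) -> ConsensusSequence:
    """Call a gene's consensus from its pileup.

    ``columns`` must cover positions 0..L-1 exactly once (a ``Pileup`` does
    so by construction; a raw column list is validated).
    """
    pile = columns if isinstance(columns, Pileup) else Pileup.from_columns(list(columns))
    codes = call_consensus_counts(pile.counts, min_fraction=min_fraction, min_depth=min_depth)
    n_failed = int((codes == _N_BYTE).sum())
    return ConsensusSequence(
        gene_id=gene_id,
        seq=codes.tobytes().decode("ascii"),
        n_called=len(codes) - n_failed,
        n_failed=n_failed,
    )
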
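"""Replicate concordance: standardized-window overlap percentages and
intensity correlation between two breakpoint peak sets.

Peaks are first standardized to center +/- flank windows; an overlap needs at
least 1 shared bp.  Overlap counts are asymmetric (fraction of A peaks hitting
any B window, and vice versa), matching how replicate Venn diagrams are read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomeIndex, GenomicInterval, IntervalIndex, standardize_window
from .peaks import Peak

__all__ = ["OverlapReport", "overlap_fraction", "intensity_correlation", "rounded_pct"]


def rounded_pct(count: int, total: int) -> int:
    """Percentage rounded to the nearest integer, the reporting convention."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round(100.0 * count / total))


@dataclass(frozen=True)
class OverlapReport:
    n_A: int
    n_B: int
    n_A_in_B: int
    n_B_in_A: int

    @property
    def pct_A_in_B(self) -> int:
        return rounded_pct(self.n_A_in_B, self.n_A)

    @property
    def pct_B_in_A(self) -> int:
        return rounded_pct(self.n_B_in_A, self.n_B)

    def as_dict(self) -> dict:
        return {
            "n_A": self.n_A,
            "n_B": self.n_B,
            "n_A_in_B": self.n_A_in_B,
            "n_B_in_A": self.n_B_in_A,
            "pct_A_in_B": self.pct_A_in_B,
            "pct_B_in_A": self.pct_B_in_A,
        }


def _windows(peaks: list[Peak], flank: int, genome: GenomeIndex) -> list[GenomicInterval]:
    return [standardize_window(p.interval, flank, genome) for p in peaks]


def overlap_fraction(
    A: list[Peak], B: list[Peak], genome: GenomeIndex, flank: int = 200
) -> OverlapReport:
    """Asymmetric overlap counts between two peak sets after standardizing
    every peak to its center +/- flank window."""
    wA = _windows(A, flank, genome)
    wB = _windows(B, flank, genome)
    idx_B = IntervalIndex(wB)
    idx_A = IntervalIndex(wA)
    n_A_in_B = sum(1 for w in wA if idx_B.any_overlap(w))
    n_B_in_A = sum(1 for w in wB if idx_A.any_overlap(w))
    return OverlapReport(len(A), len(B), n_A_in_B, n_B_in_A)


def intensity_correlation(
    A: list[Peak],
    B: list[Peak],
    genome: GenomeIndex,
    flank: int = 200,
    log10: bool = False,
) -> float:
    """Pearson r of intensities over matched peak pairs.

    Each A peak overlapping >= 1 standardized B window is paired with its
    highest-intensity overlapping B peak (a deterministic choice robust to
    fragmented peaks).  Raw tag-count intensities by default; ``log10``
    switches to log10 counts.
    """
    pairs = paired_intensities(A, B, genome, flank)
    if len(pairs) < 2:
        raise ValueError(
            f"correlation undefined: only {len(pairs)} overlapping pair(s)"
        )
    x, y = np.asarray(pairs, dtype=float).T
    if log10:
        x, y = np.log10(x), np.log10(y)
    return float(np.corrcoef(x, y)[0, 1])


def paired_intensities(
    A: list[Peak], B: list[Peak], genome: GenomeIndex, flank: int = 200
) -> list[tuple[float, float]]:
    """(intensity_A, intensity_B) for every A peak with an overlapping B window;
    the B partner is the highest-intensity overlapping B peak."""
    wB = _windows(B, flank, genome)
    idx = IntervalIndex(
        GenomicInterval(w.chrom, w.start, w.end, name=str(i))
        for i, w in enumerate(wB)
    )
    pairs: list[tuple[float, float]] = []
    for a in A:
        wa = standardize_window(a.interval, flank, genome)
        hits = idx.query(wa)
        if not hits:
            continue
        partner = max((B[int(h.name)] for h in hits), key=lambda p: p.intensity)
        pairs.append((float(a.intensity), float(partner.intensity)))
    return pairs
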
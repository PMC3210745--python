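"""Breakpoint peak calling from deduplicated fragment-end tags.

A transparent local-Poisson sliding-window caller: windows of fixed width
slide along each chromosome; each window's tag count is tested against a
Poisson background whose rate is the maximum of the genome-wide tag rate and
rates estimated in larger spans centered on the window (the span rates
exclude the candidate window's own tags, so a sharp cluster cannot inflate
its own background).  Significant windows are merged into peaks.

Strands are pooled: fragment-end tags mark cut sites directly, so no
strand-shift model applies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .intervals import (
    GenomeIndex,
    GenomicInterval,
    IntervalIndex,
    Tag,
    TagSet,
    read_intervals,
)

__all__ = [
    "Peak",
    "PeakCallerParams",
    "deduplicate_tags",
    "call_peaks",
    "filter_peaks",
    "write_peaks",
    "read_peaks",
]


@dataclass(frozen=True)
class Peak:
    """A putative apoptotic breakpoint: a region of clustered fragment-end tags."""

    interval: GenomicInterval
    summit: int
    tag_count: int
    p_value: float
    name: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie inside the peak interval")

    @property
    def intensity(self) -> int:
        """Alias of tag_count, the quantity used for replicate correlations."""
        return self.tag_count

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def center(self) -> int:
        return self.interval.center


@dataclass(frozen=True)
class PeakCallerParams:
    """Sliding-window caller parameters, tuned for ~180 bp fragment tags.

    window 400 bp spans roughly two nucleosomal fragments; local background
    spans follow the MACS convention of 1/5/10 kb.
    """

    window: int = 400
    step: int = 50
    local_lambda_spans: tuple[int, ...] = (1_000, 5_000, 10_000)
    p_threshold: float = 1e-5
    merge_gap: int = 100
    min_tags: int = 5

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if any(s < self.window for s in self.local_lambda_spans):
            raise ValueError("local lambda spans must be >= window")
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0,1)")


def deduplicate_tags(tags: TagSet) -> TagSet:
    """Collapse identical (chrom, pos, strand) tags — clonal PCR duplicates.

    The result is sorted, hence independent of input order, and idempotent.
    """
    unique = sorted(set(tags.tags))
    return TagSet(unique, tags.genome)


def _positions_by_chrom(tags: TagSet) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for t in tags:
        by.setdefault(t.chrom, []).append(t.pos)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by.items()}


def call_peaks(tags: TagSet, params: PeakCallerParams | None = None) -> list[Peak]:
    """Call breakpoint peaks from (deduplicated) tags.

    Windows of ``params.window`` bp slide by ``params.step``; a window with
    k tags is significant when the Poisson upper tail P(X >= k) under the
    local background rate is <= ``p_threshold`` and k >= ``min_tags``.
    Significant windows at most ``merge_gap`` bp apart merge into one peak;
    the summit is the position of maximum local tag density (leftmost on
    ties); tag_count is the number of tags in the merged region.
    """
    params = params or PeakCallerParams()
    if not tags.genome:
        raise ValueError("empty genome index")
    genome_len = sum(tags.genome.values())
    n_total = len(tags)
    if n_total == 0:
        return []
    lambda_bg = n_total / genome_len  # genome-wide rate per bp

    by_chrom = _positions_by_chrom(tags)
    peaks: list[Peak] = []
    for chrom in tags.genome:  # genome order => output sorted by coordinate
        pos = by_chrom.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        L = tags.genome[chrom]
        w = params.window
        starts = np.arange(0, max(1, L - w + 1), params.step, dtype=np.int64)
        ends = starts + w
        k = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)

        # local background: max over genome rate and span rates, each span
        # rate excluding the candidate window's own tags
        lam = np.full(len(starts), lambda_bg)
        centers = starts + w // 2
        for span in params.local_lambda_spans:
            if span <= w:
                continue
            s_lo = np.clip(centers - span // 2, 0, L)
            s_hi = np.clip(centers + span // 2, 0, L)
            k_span = np.searchsorted(pos, s_hi) - np.searchsorted(pos, s_lo)
            rate = (k_span - k) / np.maximum(s_hi - s_lo - w, 1)
            lam = np.maximum(lam, rate)

        mu = lam * w
        pvals = stats.poisson.sf(k - 1, mu)
        sig = (pvals <= params.p_threshold) & (k >= params.min_tags)
        if not np.any(sig):
            continue

        # merge significant windows separated by <= merge_gap
        idx = np.flatnonzero(sig)
        groups: list[list[int]] = [[idx[0]]]
        for i in idx[1:]:
            if starts[i] - ends[groups[-1][-1]] <= params.merge_gap:
                groups[-1].append(i)
            else:
                groups.append([i])

        for g in groups:
            region_start = int(starts[g[0]])
            region_end = int(ends[g[-1]])
            in_region = pos[(pos >= region_start) & (pos < region_end)]
            tag_count = int(len(in_region))
            summit = _summit(in_region, region_start, params.window)
            p_min = float(np.min(pvals[g]))
            peaks.append(
                Peak(
                    GenomicInterval(chrom, region_start, region_end),
                    summit=summit,
                    tag_count=tag_count,
                    p_value=p_min,
                )
            )
    # name peaks in coordinate order
    return [
        Peak(p.interval, p.summit, p.tag_count, p.p_value, name=f"peak_{i + 1}", flags=p.flags)
        for i, p in enumerate(peaks)
    ]


def _summit(region_pos: np.ndarray, region_start: int, window: int) -> int:
    """Tag position with the most tags within +/- window/2; leftmost on ties."""
    if len(region_pos) == 0:
        return region_start
    half = window // 2
    lo = np.searchsorted(region_pos, region_pos - half)
    hi = np.searchsorted(region_pos, region_pos + half, side="right")
    density = hi - lo
    return int(region_pos[int(np.argmax(density))])


def filter_peaks(
    peaks: list[Peak],
    mask: list[GenomicInterval] | None = None,
    exclude_chroms: set[str] | frozenset[str] = frozenset(),
    flag_regions: list[GenomicInterval] | None = None,
) -> list[Peak]:
    """Apply exclusion and flagging filters.

    Peaks overlapping (>= 1 bp) any mask interval (satellite repeats) or lying
    on an excluded chromosome are removed.  Survivors overlapping any flag
    region (known copy-number changes) carry the "CNV" flag but are kept.
    Relative order is preserved.
    """
    mask_idx = IntervalIndex(mask or [])
    flag_idx = IntervalIndex(flag_regions or [])
    out: list[Peak] = []
    for p in peaks:
        if p.chrom in exclude_chroms:
            continue
        if mask_idx.any_overlap(p.interval):
            continue
        if flag_idx.any_overlap(p.interval):
            p = Peak(
                p.interval, p.summit, p.tag_count, p.p_value,
                name=p.name, flags=p.flags | {"CNV"},
            )
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Peak I/O (BED6+: name, score = -10*log10 p rounded, summit, tag_count, flags)


def write_peaks(peaks: list[Peak], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = 0
            if p.p_value > 0:
                score = int(round(-10.0 * np.log10(p.p_value)))
            name = p.name or f"peak_{i + 1}"
            flags = ",".join(sorted(p.flags)) if p.flags else "."
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{name}\t"
                f"{score}\t.\t{p.summit}\t{p.tag_count}\t{p.p_value:.6g}\t{flags}\n"
            )


def read_peaks(path: str | os.PathLike) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{lineno}: expected >= 8 columns for a peak record")
            flags = frozenset() if len(f) < 10 or f[9] == "." else frozenset(f[9].split(","))
            p_value = float(f[8]) if len(f) > 8 else 10 ** (-float(f[4]) / 10.0)
            peaks.append(
                Peak(
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    summit=int(f[6]),
                    tag_count=int(f[7]),
                    p_value=p_value,
                    name=f[3],
                    flags=flags,
                )
            )
    return peaks
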
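"""Random-region null models and enrichment statistics.

Covers: uniform random-peak simulation with the same exclusion filters as
real peaks; chromatin-mark association counting (marks standardized to 149 bp
around their centers, a peak associates when its center falls inside a
standardized mark window); Pearson chi-square on 2x2 tables (no continuity
correction by default); one-sided binomial upper tails carried in log10 space
so extreme significance never silently reports 0; and curated gene-list
enrichment against a gene universe.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .intervals import GenomeIndex, GenomicInterval, IntervalIndex
from .peaks import Peak, filter_peaks

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "simulate_random_peaks",
    "standardize_marks",
    "mark_association",
    "chi_square_2x2",
    "binomial_enrichment",
    "curated_list_enrichment",
    "read_gene_list",
]

MARK_WIDTH = 149


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = peak set vs reference, columns =
    associated vs not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b == 0 and self.c + self.d == 0:
            raise ValueError("degenerate table: both row totals are zero")


@dataclass(frozen=True)
class EnrichmentResult:
    observed_k: int
    n: int
    rate: float
    background_rate: float | None
    statistic: float | None
    p_value: float
    log10_p: float
    test: str

    def as_dict(self) -> dict:
        return {
            "observed_k": self.observed_k,
            "n": self.n,
            "rate": self.rate,
            "background_rate": self.background_rate,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "log10_p": self.log10_p,
            "test": self.test,
        }


# ---------------------------------------------------------------------------
# Random-region null


def simulate_random_peaks(
    n: int,
    genome: GenomeIndex,
    mask: list[GenomicInterval] | None = None,
    exclude_chroms: set[str] | frozenset[str] = frozenset(),
    width: int = 400,
    seed: int = 0,
) -> list[Peak]:
    """Place n width-``width`` intervals uniformly over the genome (chromosome
    chosen proportional to its length), then apply the same satellite-mask and
    chromosome exclusions as real peaks.  Survivors are returned."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if width < 1:
        raise ValueError("width must be >= 1")
    shortest = min(genome.values())
    if width > shortest:
        raise ValueError(
            f"width {width} exceeds the shortest chromosome ({shortest} bp)"
        )
    rng = np.random.default_rng(seed)
    chroms = list(genome.keys())
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    pick = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    peaks: list[Peak] = []
    for i, ci in enumerate(pick):
        chrom = chroms[int(ci)]
        start = int(rng.integers(0, genome[chrom] - width + 1))
        iv = GenomicInterval(chrom, start, start + width, name=f"rand_{i + 1}")
        peaks.append(Peak(iv, summit=iv.center, tag_count=0, p_value=1.0, name=iv.name))
    return filter_peaks(peaks, mask=mask, exclude_chroms=exclude_chroms)


# ---------------------------------------------------------------------------
# Mark association


def standardize_marks(marks: list[GenomicInterval]) -> list[GenomicInterval]:
    """Replace each mark by the width-149 window [center-74, center+75)."""
    half = MARK_WIDTH // 2  # 74
    out = []
    for m in marks:
        c = m.center
        start = max(0, c - half)
        out.append(GenomicInterval(m.chrom, start, start + MARK_WIDTH, m.strand, m.name))
    return out


def mark_association(peaks: list[Peak], marks: list[GenomicInterval]) -> EnrichmentResult:
    """Count peaks whose center lies inside >= 1 standardized mark window.

    Returns the counting stage only (rate, no test); feed ``observed_k``/``n``
    to :func:`binomial_enrichment` with a background rate from a matched
    random-peak run.
    """
    idx = IntervalIndex(standardize_marks(marks))
    k = sum(1 for p in peaks if idx.contains(p.chrom, p.center))
    n = len(peaks)
    return EnrichmentResult(
        observed_k=k,
        n=n,
        rate=k / n if n else 0.0,
        background_rate=None,
        statistic=None,
        p_value=1.0,
        log10_p=0.0,
        test="count",
    )


# ---------------------------------------------------------------------------
# Tests


def chi_square_2x2(
    t: ContingencyTable2x2, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square with 1 df on a 2x2 table.

    No continuity correction by default; ``continuity_correction`` enables
    Yates.  Requires all expected counts > 0.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        raise ValueError("degenerate table: a zero row or column total")
    observed = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer([row1, row2], [col1, col2]) / n
    diff = np.abs(observed - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float(np.sum(diff**2 / expected))
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def _binom_log10_sf(k: int, n: int, p0: float) -> float:
    """log10 P(X >= k) for X ~ Binomial(n, p0), stable in the far tail."""
    if k <= 0:
        return 0.0
    if k > n:
        return -math.inf
    # exact: logsumexp of log pmf over the tail
    j = np.arange(k, n + 1)
    logpmf = stats.binom.logpmf(j, n, p0)
    return float(special.logsumexp(logpmf) / math.log(10.0))


def binomial_enrichment(k: int, n: int, p0: float) -> EnrichmentResult:
    """One-sided binomial upper tail P(X >= k) under background rate p0.

    The tail is computed in log space; ``p_value`` underflows to 0.0 for
    extreme enrichment, but ``log10_p`` stays finite.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"background rate p0 must be in (0,1), got {p0}")
    log10_p = _binom_log10_sf(k, n, p0)
    p = 10.0**log10_p if log10_p > -300 else 0.0
    return EnrichmentResult(
        observed_k=k,
        n=n,
        rate=k / n if n else 0.0,
        background_rate=p0,
        statistic=None,
        p_value=min(p, 1.0),
        log10_p=min(log10_p, 0.0),
        test="binomial",
    )


def _normalize(symbols) -> dict[str, str]:
    """Map casefolded/stripped symbol -> original (first occurrence wins)."""
    out: dict[str, str] = {}
    for s in symbols:
        key = str(s).strip().casefold()
        if key and key not in out:
            out[key] = str(s).strip()
    return out


def curated_list_enrichment(
    hit_genes, curated, universe
) -> tuple[EnrichmentResult, ContingencyTable2x2]:
    """Chi-square enrichment of a curated gene list among hit genes.

    Table: hit genes vs the remaining universe genes (rows) x curated vs not
    (columns).  Symbols are compared case-insensitively after whitespace
    stripping.
    """
    uni = set(_normalize(universe))
    if not uni:
        raise ValueError("empty gene universe")
    hits = set(_normalize(hit_genes)) & uni
    cur = set(_normalize(curated)) & uni
    k = len(hits & cur)
    n = len(hits)
    rest = uni - hits
    c = len(cur & rest)
    table = ContingencyTable2x2(k, n - k, c, len(rest) - c)
    statistic, p = chi_square_2x2(table)
    result = EnrichmentResult(
        observed_k=k,
        n=n,
        rate=k / n if n else 0.0,
        background_rate=len(cur) / len(uni),
        statistic=statistic,
        p_value=p,
        log10_p=math.log10(p) if p > 0 else -math.inf,
        test="chi_square",
    )
    return result, table


def curated_list_enrichment_from_counts(
    k: int, n_hits: int, n_curated: int, n_universe: int
) -> tuple[EnrichmentResult, ContingencyTable2x2]:
    """Counts-only form of :func:`curated_list_enrichment` for use with
    published summary tables: k curated genes among n_hits hit genes, against
    n_curated curated genes in a universe of n_universe."""
    if n_universe <= 0:
        raise ValueError("empty gene universe")
    table = ContingencyTable2x2(
        k, n_hits - k, n_curated - k, (n_universe - n_hits) - (n_curated - k)
    )
    statistic, p = chi_square_2x2(table)
    result = EnrichmentResult(
        observed_k=k,
        n=n_hits,
        rate=k / n_hits if n_hits else 0.0,
        background_rate=n_curated / n_universe,
        statistic=statistic,
        p_value=p,
        log10_p=math.log10(p) if p > 0 else -math.inf,
        test="chi_square",
    )
    return result, table


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Plain-text gene list, one symbol per line; blanks and # comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(s)
    return out
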
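"""Synthetic apoptotic-fragmentation data generator.

Emulates the statistical structure the analysis assumes: internucleosomal
cleavage yielding ~180 bp double-stranded fragments, preferential cleavage at
gene promoters and open-chromatin (mark) regions, clonal PCR duplicates, and
a uniform background of non-specific breaks.  Everything is reproducible from
``SimConfig.seed``.

The generative model is deliberately minimal: a piecewise-constant cleavage
landscape over the genome (baseline 1, multiplied by an enrichment fold inside
promoter windows and inside mark peaks), fragment cut sites drawn per-base in
proportion to the landscape weight, Gaussian jitter on fragment length, and
both fragment ends emitting a strand-aware 5' tag.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np

from .intervals import GenomeIndex, GenomicInterval, Tag, TagSet

__all__ = [
    "SimConfig",
    "CleavageLandscape",
    "generate_genome",
    "write_genome",
    "generate_gene_models",
    "generate_mark_peaks",
    "build_cleavage_landscape",
    "simulate_tags",
    "PROMOTER_FLANK",
    "MARK_WIDTH",
]

PROMOTER_FLANK = 2500  # bp either side of the TSS
MARK_WIDTH = 149  # chromatin-mark peaks standardized to this width


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fragmentation experiment.

    Defaults encode the biology being emulated: 180 bp internucleosomal
    fragments, a genome-average GC of 41%, and ten-fold preferential cleavage
    of promoters and open chromatin (the enrichment fold is not quantified by
    the underlying biology; 10x is a fixed calibration choice, see
    docs/methods.md).
    """

    n_chroms: int = 2
    chrom_length: int = 500_000
    gc_fraction: float = 0.41
    n_genes: int = 40
    exons_per_gene: int = 4
    promoter_enrichment_fold: float = 10.0
    mark_enrichment_fold: float = 10.0
    fragment_size: int = 180
    fragment_jitter_sd: float = 10.0
    n_fragments: int = 20_000
    duplicate_rate: float = 0.1
    background_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("gc_fraction", "duplicate_rate", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.promoter_enrichment_fold < 1 or self.mark_enrichment_fold < 1:
            raise ValueError("enrichment folds must be >= 1")
        if self.fragment_size <= 0:
            raise ValueError("fragment_size must be > 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


# ---------------------------------------------------------------------------
# Genome


def generate_genome(config: SimConfig) -> tuple[dict[str, str], GenomeIndex]:
    """i.i.d. base sequences with P(G)+P(C) = gc_fraction.

    Returns (name -> sequence, GenomeIndex); chromosome names chr1, chr2, ...
    """
    rng = config.rng(stream=1)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, str] = {}
    for i in range(config.n_chroms):
        draws = rng.choice(alphabet, size=config.chrom_length, p=probs)
        seqs[f"chr{i + 1}"] = draws.tobytes().decode("ascii")
    genome = GenomeIndex({name: len(s) for name, s in seqs.items()})
    return seqs, genome


def write_genome(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    """Write FASTA plus a samtools-style .fai sidecar."""
    with open(path, "w") as fh:
        offsets = {}
        offset = 0
        for name, seq in seqs.items():
            header = f">{name}\n"
            fh.write(header)
            offset += len(header)
            offsets[name] = offset
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            offset += len(seq) + -(-len(seq) // width)  # bases + newlines
    with open(f"{path}.fai", "w") as fh:
        for name, seq in seqs.items():
            fh.write(f"{name}\t{len(seq)}\t{offsets[name]}\t{width}\t{width + 1}\n")


# ---------------------------------------------------------------------------
# Gene models


def generate_gene_models(config: SimConfig, genome: GenomeIndex):
    """Place non-overlapping transcripts with disjoint exons; random strand.

    Returns a pandas DataFrame in the UCSC-knownGene-like layout used by
    :mod:`apobreak.annotation` (name, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds, geneSymbol).
    """
    import pandas as pd

    rng = config.rng(stream=2)
    chroms = list(genome.keys())
    slot = 20_000  # transcript + flanking room so promoters rarely collide
    slots: list[tuple[str, int]] = []
    for c in chroms:
        # reserve one slot of margin at each chromosome end so promoter and
        # distal windows stay in bounds
        n_slots = genome[c] // slot - 2
        slots.extend((c, (j + 1) * slot) for j in range(max(0, n_slots)))
    if config.n_genes > len(slots):
        raise ValueError(
            f"cannot place {config.n_genes} non-overlapping genes: only "
            f"{len(slots)} slots of {slot} bp available in a genome of "
            f"{sum(genome.values())} bp"
        )
    chosen = rng.choice(len(slots), size=config.n_genes, replace=False)
    chosen.sort()

    rows = []
    for gi, si in enumerate(chosen):
        chrom, base = slots[si]
        span = int(rng.integers(8_000, 12_001))
        tx_start = base + int(rng.integers(0, slot - span - 1000))
        tx_end = tx_start + span
        strand = "+" if rng.random() < 0.5 else "-"
        # exon boundaries: 2k sorted cut points inside the span
        k = config.exons_per_gene
        cuts = np.sort(rng.choice(np.arange(1, span), size=2 * k, replace=False))
        exon_starts = [tx_start + int(cuts[2 * j]) for j in range(k)]
        exon_ends = [tx_start + int(cuts[2 * j + 1]) for j in range(k)]
        # first exon starts at the transcript start, last ends at its end
        exon_starts[0] = tx_start
        exon_ends[-1] = tx_end
        rows.append(
            {
                "name": f"TX{gi + 1:04d}",
                "chrom": chrom,
                "strand": strand,
                "txStart": tx_start,
                "txEnd": tx_end,
                "exonStarts": ",".join(str(x) for x in exon_starts) + ",",
                "exonEnds": ",".join(str(x) for x in exon_ends) + ",",
                "geneSymbol": f"GENE{gi + 1:04d}",
            }
        )
    return pd.DataFrame(rows)


def _tss_of_row(row) -> int:
    return int(row["txStart"]) if row["strand"] == "+" else int(row["txEnd"]) - 1


def promoter_windows(genes, genome: GenomeIndex) -> list[GenomicInterval]:
    """TSS +/- PROMOTER_FLANK windows, clamped to chromosome bounds."""
    out = []
    for _, row in genes.iterrows():
        tss = _tss_of_row(row)
        length = genome.length_of(row["chrom"])
        start = max(0, tss - PROMOTER_FLANK)
        end = min(length, tss + PROMOTER_FLANK)
        out.append(GenomicInterval(row["chrom"], start, end, row["strand"]))
    return out


def generate_mark_peaks(
    config: SimConfig,
    genes,
    genome: GenomeIndex,
    p_at_promoter: float = 0.8,
    n_background: int = 50,
) -> list[GenomicInterval]:
    """Chromatin-mark peak track: width-149 peaks at promoters plus background.

    Each gene's promoter carries a mark peak (centered on its TSS) with
    probability ``p_at_promoter``; ``n_background`` additional peaks are
    placed uniformly.
    """
    rng = config.rng(stream=3)
    half_lo = MARK_WIDTH // 2  # 74
    peaks: list[GenomicInterval] = []
    for _, row in genes.iterrows():
        if rng.random() < p_at_promoter:
            tss = _tss_of_row(row)
            length = genome.length_of(row["chrom"])
            center = min(max(tss, half_lo), length - (MARK_WIDTH - half_lo))
            peaks.append(
                GenomicInterval(row["chrom"], center - half_lo, center - half_lo + MARK_WIDTH)
            )
    chroms = list(genome.keys())
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    pick = rng.choice(len(chroms), size=n_background, p=lengths / lengths.sum())
    for ci in pick:
        chrom = chroms[ci]
        start = int(rng.integers(0, genome[chrom] - MARK_WIDTH))
        peaks.append(GenomicInterval(chrom, start, start + MARK_WIDTH))
    return peaks


# ---------------------------------------------------------------------------
# Cleavage landscape


@dataclass
class CleavageLandscape:
    """Piecewise-constant relative cleavage propensity over the genome.

    ``tiles[chrom]`` is (boundaries, weights): boundaries is a sorted int
    array starting at 0 and ending at the chromosome length; weights[i]
    applies on [boundaries[i], boundaries[i+1]).
    """

    genome: GenomeIndex
    tiles: dict[str, tuple[np.ndarray, np.ndarray]]

    def total_mass(self) -> float:
        return float(
            sum(
                float(np.sum(np.diff(b) * w))
                for b, w in self.tiles.values()
            )
        )

    def weight_at(self, chrom: str, pos: int) -> float:
        b, w = self.tiles[chrom]
        i = int(np.searchsorted(b, pos, side="right")) - 1
        return float(w[i])


def _coverage_union(intervals: list[GenomicInterval], chrom: str) -> list[tuple[int, int]]:
    segs = sorted((iv.start, iv.end) for iv in intervals if iv.chrom == chrom)
    merged: list[tuple[int, int]] = []
    for s, e in segs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_cleavage_landscape(
    genes,
    marks: list[GenomicInterval],
    config: SimConfig,
    genome: GenomeIndex,
) -> CleavageLandscape:
    """Baseline weight 1; x promoter fold inside promoter-window union;
    x mark fold inside mark-peak union (multiplicative where both apply)."""
    promoters = promoter_windows(genes, genome)
    tiles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in genome.items():
        prom_u = _coverage_union(promoters, chrom)
        mark_u = _coverage_union(marks, chrom)
        bounds = {0, length}
        for s, e in prom_u + mark_u:
            bounds.add(min(s, length))
            bounds.add(min(e, length))
        b = np.array(sorted(bounds), dtype=np.int64)
        w = np.ones(len(b) - 1, dtype=float)
        mids = (b[:-1] + b[1:]) / 2.0
        for s, e in prom_u:
            w[(mids >= s) & (mids < e)] *= config.promoter_enrichment_fold
        for s, e in mark_u:
            w[(mids >= s) & (mids < e)] *= config.mark_enrichment_fold
        tiles[chrom] = (b, w)
    return CleavageLandscape(genome, tiles)


# ---------------------------------------------------------------------------
# Fragment-end tags


def _sample_positions(
    landscape: CleavageLandscape, n: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Draw n genomic positions with per-base probability proportional to
    landscape weight (inverse-CDF over tiles, then uniform within a tile)."""
    chroms = list(landscape.tiles.keys())
    masses = np.array(
        [float(np.sum(np.diff(b) * w)) for b, w in landscape.tiles.values()]
    )
    chrom_pick = rng.choice(len(chroms), size=n, p=masses / masses.sum())
    out: list[tuple[str, int]] = []
    for ci in range(len(chroms)):
        m = int(np.sum(chrom_pick == ci))
        if m == 0:
            continue
        b, w = landscape.tiles[chroms[ci]]
        tile_mass = np.diff(b) * w
        tile_pick = rng.choice(len(tile_mass), size=m, p=tile_mass / tile_mass.sum())
        offsets = rng.random(m)
        starts = b[:-1][tile_pick]
        widths = np.diff(b)[tile_pick]
        pos = starts + np.floor(offsets * widths).astype(np.int64)
        out.extend((chroms[ci], int(p)) for p in pos)
    return out


def simulate_tags(
    landscape: CleavageLandscape,
    config: SimConfig,
    five_prime_only: bool = False,
) -> TagSet:
    """Simulate fragment-end tags from the cleavage landscape.

    Each fragment starts at a cut site drawn proportional to landscape weight
    (a ``background_fraction`` of fragments is drawn uniformly instead) and
    spans ``fragment_size`` bp plus Gaussian jitter (truncated at >= 50 bp).
    Blunt-end ligation sequences both ends, so each fragment emits a + strand
    tag at its 5' start and a - strand tag at its 3' end unless
    ``five_prime_only``.  Each tag is duplicated (an exact clonal copy) with
    probability ``duplicate_rate``.
    """
    genome = landscape.genome
    rng = config.rng(stream=4)
    n = config.n_fragments
    n_bg = int(rng.binomial(n, config.background_fraction))
    uniform = CleavageLandscape(
        genome,
        {
            c: (np.array([0, L], dtype=np.int64), np.array([1.0]))
            for c, L in genome.items()
        },
    )
    cuts = _sample_positions(landscape, n - n_bg, rng) + _sample_positions(
        uniform, n_bg, rng
    )
    jitter = rng.normal(0.0, config.fragment_jitter_sd, size=len(cuts))
    tags: list[Tag] = []
    for (chrom, cut), j in zip(cuts, jitter):
        length = max(50, int(round(config.fragment_size + j)))
        end = cut + length  # fragment occupies [cut, end)
        L = genome[chrom]
        if end > L:  # shift fragments hanging off the chromosome end
            cut = max(0, L - length)
            end = min(L, cut + length)
        tags.append(Tag(chrom, cut, "+"))
        if not five_prime_only:
            tags.append(Tag(chrom, end - 1, "-"))
    dup = rng.random(len(tags)) < config.duplicate_rate
    tags.extend(t for t, d in zip(list(tags), dup) if d)
    return TagSet(tags, genome)


def write_metadata(path: str | os.PathLike, config: SimConfig, **extra) -> None:
    """Sidecar metadata recording the seed and parameters of an artifact."""
    payload = dict(dataclasses.asdict(config), **extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")
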
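"""Hierarchical genomic annotation of breakpoint peaks and GC content.

Each peak is assigned exactly one of six categories by testing its center
point against gene-model regions in strict priority order:

    promoter > exon > intron > three_prime > distal_promoter > intergenic

where promoter = TSS +/- 2.5 kb (strand-aware TSS), three_prime = the 2.5 kb
immediately downstream of the transcript end, and distal_promoter = 2.5-20 kb
upstream of the TSS.  "Gene-associated" means any category but intergenic.
Genes encoding distinct isoforms of one gene product (same gene symbol) count
as one gene.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass

from .intervals import GenomeIndex, GenomicInterval, IntervalIndex, interval_overlaps
from .peaks import Peak

__all__ = [
    "GeneModel",
    "CATEGORIES",
    "GENIC_CATEGORIES",
    "read_gene_models",
    "write_gene_models",
    "GeneAnnotator",
    "classify_peak",
    "annotate_peakset",
    "gc_content",
]

CATEGORIES = (
    "promoter",
    "exon",
    "intron",
    "three_prime",
    "distal_promoter",
    "intergenic",
)
GENIC_CATEGORIES = frozenset(CATEGORIES[:-1])

PROMOTER_FLANK = 2500
DISTAL_PROMOTER_MAX = 20_000
THREE_PRIME_EXTENT = 2500


@dataclass(frozen=True)
class GeneModel:
    """A transcript with strand-aware TSS/TES, exons, and a gene symbol."""

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError("invalid transcript span")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(
                    f"exon {s}-{e} outside transcript span "
                    f"{self.tx_start}-{self.tx_end} of {self.transcript_id}"
                )

    @property
    def tss(self) -> int:
        """Transcription start site (base position, strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (base position, strand-aware)."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    # --- annotation geometry (all half-open, clamped at 0; upstream and
    # downstream follow the strand) -------------------------------------

    def promoter_region(self) -> tuple[int, int]:
        return max(0, self.tss - PROMOTER_FLANK), self.tss + PROMOTER_FLANK

    def three_prime_region(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.tx_end, self.tx_end + THREE_PRIME_EXTENT
        return max(0, self.tx_start - THREE_PRIME_EXTENT), self.tx_start

    def distal_promoter_region(self) -> tuple[int, int]:
        if self.strand == "+":
            return max(0, self.tss - DISTAL_PROMOTER_MAX), max(0, self.tss - PROMOTER_FLANK)
        return self.tss + PROMOTER_FLANK, self.tss + DISTAL_PROMOTER_MAX


# ---------------------------------------------------------------------------
# Gene-table I/O (UCSC-knownGene-like columns)

_GENE_COLUMNS = [
    "name", "chrom", "strand", "txStart", "txEnd",
    "exonStarts", "exonEnds", "geneSymbol",
]


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    return gene_models_from_table(df)


def gene_models_from_table(df) -> list[GeneModel]:
    models = []
    for _, row in df.iterrows():
        starts = [int(x) for x in str(row["exonStarts"]).rstrip(",").split(",") if x]
        ends = [int(x) for x in str(row["exonEnds"]).rstrip(",").split(",") if x]
        if len(starts) != len(ends):
            raise ValueError(f"exon start/end count mismatch for {row['name']}")
        models.append(
            GeneModel(
                transcript_id=str(row["name"]),
                gene_symbol=str(row["geneSymbol"]),
                chrom=str(row["chrom"]),
                strand=str(row["strand"]),
                tx_start=int(row["txStart"]),
                tx_end=int(row["txEnd"]),
                exons=tuple(zip(starts, ends)),
            )
        )
    return models


def write_gene_models(models: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for m in models:
            fh.write(
                "\t".join(
                    [
                        m.transcript_id, m.chrom, m.strand,
                        str(m.tx_start), str(m.tx_end),
                        ",".join(str(s) for s, _ in m.exons) + ",",
                        ",".join(str(e) for _, e in m.exons) + ",",
                        m.gene_symbol,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Classification


class GeneAnnotator:
    """Indexed gene-model regions for hierarchical peak classification.

    ``mode`` = "point" tests the peak's center point (default, yields a strict
    partition); "interval" tests the full peak interval for >= 1 bp overlap.
    """

    def __init__(self, genes: list[GeneModel], mode: str = "point"):
        if mode not in ("point", "interval"):
            raise ValueError("mode must be 'point' or 'interval'")
        self.mode = mode
        self.genes = list(genes)
        self._region_index: dict[str, IntervalIndex] = {
            cat: IntervalIndex() for cat in CATEGORIES[:-1]
        }
        for gi, g in enumerate(self.genes):
            tag = str(gi)
            for cat, (s, e) in (
                ("promoter", g.promoter_region()),
                ("three_prime", g.three_prime_region()),
                ("distal_promoter", g.distal_promoter_region()),
            ):
                if s < e:
                    self._region_index[cat].add(GenomicInterval(g.chrom, s, e, name=tag))
            for s, e in g.exons:
                self._region_index["exon"].add(GenomicInterval(g.chrom, s, e, name=tag))
            # intron region = transcript span; exon priority removes exonic hits
            self._region_index["intron"].add(
                GenomicInterval(g.chrom, g.tx_start, g.tx_end, name=tag)
            )

    def _hits(self, cat: str, peak: Peak) -> list[GeneModel]:
        idx = self._region_index[cat]
        if self.mode == "point":
            found = idx.contains(peak.chrom, peak.center)
        else:
            found = idx.query(peak.interval)
        return [self.genes[int(h.name)] for h in found]

    def classify(self, peak: Peak) -> tuple[str, list[tuple[str, str]]]:
        """Category plus (transcript_id, gene_symbol) pairs of the transcripts
        providing the winning (highest-priority) category."""
        for cat in CATEGORIES[:-1]:
            hits = self._hits(cat, peak)
            if hits:
                seen = []
                for g in sorted(hits, key=lambda g: g.transcript_id):
                    pair = (g.transcript_id, g.gene_symbol)
                    if pair not in seen:
                        seen.append(pair)
                return cat, seen
        return "intergenic", []


def classify_peak(
    peak: Peak, genes: list[GeneModel] | GeneAnnotator, mode: str = "point"
) -> tuple[str, list[tuple[str, str]]]:
    annot = genes if isinstance(genes, GeneAnnotator) else GeneAnnotator(genes, mode)
    return annot.classify(peak)


def annotate_peakset(
    peaks: list[Peak], genes: list[GeneModel] | GeneAnnotator, mode: str = "point"
) -> dict:
    """Per-category counts (a partition of the peaks), unique transcript and
    gene lists, and the rounded gene-association percentage."""
    annot = genes if isinstance(genes, GeneAnnotator) else GeneAnnotator(genes, mode)
    counts = Counter({cat: 0 for cat in CATEGORIES})
    transcripts: list[str] = []
    symbols: list[str] = []
    seen_tx: set[str] = set()
    seen_sym: set[str] = set()
    per_peak: list[dict] = []
    for p in peaks:
        cat, pairs = annot.classify(p)
        counts[cat] += 1
        for tx, sym in pairs:
            if tx not in seen_tx:
                seen_tx.add(tx)
                transcripts.append(tx)
            key = sym.strip().casefold()
            if key not in seen_sym:
                seen_sym.add(key)
                symbols.append(sym)
        per_peak.append(
            {
                "name": p.name,
                "chrom": p.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "category": cat,
                "transcripts": [tx for tx, _ in pairs],
                "genes": sorted({s for _, s in pairs}),
            }
        )
    n = len(peaks)
    n_genic = sum(counts[c] for c in CATEGORIES[:-1])
    return {
        "n_peaks": n,
        "category_counts": dict(counts),
        "n_gene_associated": n_genic,
        "pct_gene_associated": int(round(100.0 * n_genic / n)) if n else 0,
        "transcripts": transcripts,
        "genes": symbols,
        "per_peak": per_peak,
    }


# ---------------------------------------------------------------------------
# GC content


def gc_content(peaks: list[Peak], genome_fasta) -> float:
    """GC fraction over the union of peak intervals.

    ``genome_fasta`` is a pyfaidx.Fasta, a path to a FASTA, or a plain
    name -> sequence mapping.  Counting is case-insensitive; ambiguous bases
    (anything outside ACGT) are excluded from the denominator.
    """
    if isinstance(genome_fasta, (str, os.PathLike)):
        import pyfaidx

        genome_fasta = pyfaidx.Fasta(str(genome_fasta))

    # union of intervals per chromosome so shared bases count once
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.interval.start, p.interval.end))
    gc = at = 0
    for chrom, segs in by_chrom.items():
        segs.sort()
        merged: list[tuple[int, int]] = []
        for s, e in segs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            seq = str(genome_fasta[chrom][s:e]).upper()
            if len(seq) < e - s:
                raise ValueError(
                    f"sequence of {chrom} shorter than interval {s}-{e}"
                )
            gc += seq.count("G") + seq.count("C")
            at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases under the peak set")
    return gc / (gc + at)
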
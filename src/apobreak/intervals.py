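"""Genomic coordinate primitives: intervals, tags, overlap queries and BED I/O.

All coordinates are 0-based, half-open (BED convention).  Overlap between two
intervals requires at least 1 shared base; strand never enters an overlap
test (it is used only for gene geometry, in :mod:`apobreak.annotation`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Tag",
    "TagSet",
    "GenomeIndex",
    "IntervalIndex",
    "interval_overlaps",
    "standardize_window",
    "read_intervals",
    "write_intervals",
    "read_tags",
    "write_tags",
]


class GenomeIndex(dict):
    """Ordered mapping of chromosome name -> length in bp.

    Construct from pairs, from a FASTA ``.fai`` file
    (:meth:`from_fai`), or from a :class:`pyfaidx.Fasta`.
    """

    def __init__(self, items=()):
        super().__init__()
        for name, length in dict(items).items():
            self.add(name, length)

    def add(self, name: str, length: int) -> None:
        if name in self:
            raise ValueError(f"duplicate chromosome name: {name!r}")
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        super().__setitem__(name, int(length))

    @classmethod
    def from_fai(cls, path: str | os.PathLike) -> "GenomeIndex":
        idx = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                name, length = line.split("\t")[:2]
                idx.add(name, int(length))
        return idx

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeIndex":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: len(fa[name]) for name in fa.keys()})

    def length_of(self, chrom: str) -> int:
        try:
            return self[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region, optionally stranded.

    ``strand`` is '+', '-', or '.' (unstranded).  ``name`` and ``score`` are
    optional BED columns carried through I/O untouched.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floor of (start+end)/2 — deterministic for even widths."""
        return (self.start + self.end) // 2

    def validate_against(self, genome: GenomeIndex) -> None:
        length = genome.length_of(self.chrom)
        if self.end > length:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {length}"
            )


class Tag(NamedTuple):
    """The mapped 5'-end coordinate of one sequenced fragment end."""

    chrom: str
    pos: int
    strand: str


@dataclass
class TagSet:
    """A multiset of strand-aware single-base tags plus the genome they map to.

    Duplicates (identical chrom/pos/strand, the signature of clonal PCR
    amplification) are permitted; :func:`apobreak.peaks.deduplicate_tags`
    collapses them.
    """

    tags: list[Tag]
    genome: GenomeIndex

    def __post_init__(self):
        for t in self.tags:
            length = self.genome.length_of(t.chrom)
            if not (0 <= t.pos < length):
                raise ValueError(
                    f"tag {t.chrom}:{t.pos} out of bounds (length {length})"
                )
            if t.strand not in ("+", "-"):
                raise ValueError(f"tag strand must be + or -, got {t.strand!r}")

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self) -> Iterator[Tag]:
        return iter(self.tags)


def interval_overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least 1 bp.  Strand is ignored."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def standardize_window(
    a: GenomicInterval, flank: int, genome: GenomeIndex
) -> GenomicInterval:
    """Replace an interval by the window [center - flank, center + flank).

    The window is clamped to [0, chromosome length], so its width is at most
    2*flank.  This is the peak-standardization step used before replicate
    overlap comparisons.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    length = genome.length_of(a.chrom)
    c = a.center
    start = max(0, c - flank)
    end = min(length, c + flank)
    if flank == 0:
        end = min(length, start + 1)  # degenerate: keep a 1 bp point interval
    return GenomicInterval(a.chrom, start, end, a.strand, a.name, a.score)


# ---------------------------------------------------------------------------
# BED I/O

_SKIP_PREFIXES = ("track", "browser", "#")


def read_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals, preserving name/score/strand.

    track/browser/comment lines are skipped; coordinate errors report the
    offending line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinate in {fields[1:3]}"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "0"
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_intervals(
    intervals: Iterable[GenomicInterval], path: str | os.PathLike
) -> None:
    """Write intervals as BED; emits exactly the columns needed (3 to 6)."""
    intervals = list(intervals)
    ncols = 3
    if any(i.strand != "." for i in intervals):
        ncols = 6
    elif any(i.score is not None for i in intervals):
        ncols = 5
    elif any(i.name is not None for i in intervals):
        ncols = 4
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if ncols >= 4:
                fields.append(iv.name if iv.name is not None else ".")
            if ncols >= 5:
                fields.append(_fmt_score(iv.score))
            if ncols >= 6:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_tags(path: str | os.PathLike, genome: GenomeIndex) -> TagSet:
    """Read single-base fragment-end tags from BED6 (pos = start column)."""
    tags = []
    for iv in read_intervals(path):
        if iv.strand not in ("+", "-"):
            raise ValueError(f"tag record without strand: {iv.chrom}:{iv.start}")
        tags.append(Tag(iv.chrom, iv.start, iv.strand))
    return TagSet(tags, genome)


def write_tags(tagset: TagSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in tagset.tags:
            fh.write(f"{t.chrom}\t{t.pos}\t{t.pos + 1}\ttag\t0\t{t.strand}\n")


# ---------------------------------------------------------------------------
# Indexed overlap queries


class IntervalIndex:
    """Chromosome-partitioned interval tree for overlap and point queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, q: GenomicInterval) -> list[GenomicInterval]:
        """All indexed intervals sharing >=1 bp with ``q``, in coordinate order."""
        tree = self._trees.get(q.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(q.start, q.end)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits

    def contains(self, chrom: str, pos: int) -> list[GenomicInterval]:
        """All indexed intervals with start <= pos < end."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.at(pos)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits

    def any_overlap(self, q: GenomicInterval) -> bool:
        tree = self._trees.get(q.chrom)
        return tree is not None and bool(tree.overlap(q.start, q.end))
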
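"""Genomic-interval data model and standard-format I/O.

Coordinates are 0-based half-open throughout (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  narrowPeak summits are
``start + offset`` where the offset is column 10 of the ENCODE format.

This module is the coordinate currency for every downstream stage: ChIP-seq
summit merging into loci, peak overlap tests, and window resizing around
summits or peak centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Summit",
    "MergedLocus",
    "read_intervals",
    "write_intervals",
    "merge_summits",
    "overlaps",
    "overlaps_any",
    "resize_to_width",
]


@dataclass
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based half-open coordinates; ``0 <= start < end``.
    name : str, optional
        Feature label (BED column 4).
    score : float, optional
        Numeric score (BED column 5).
    strand : str
        One of ``'+'``, ``'-'``, ``'.'``.
    summit_offset : int, optional
        Offset of the point-source summit relative to ``start``
        (narrowPeak column 10); ``None`` when unknown.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end ({self.end}) must be greater than start ({self.start})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def summit(self) -> int | None:
        """Absolute summit position, if a summit offset is recorded."""
        if self.summit_offset is None:
            return None
        return self.start + self.summit_offset


@dataclass
class Summit:
    """A single-base ChIP-seq summit with its condition of origin."""

    chrom: str
    pos: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative summit position: {self.pos}")


@dataclass
class MergedLocus:
    """Envelope of summits merged by proximity.

    ``members`` records ``(source, pos)`` for every merged summit; the
    representative position is the floor of the envelope midpoint.
    """

    chrom: str
    start: int
    end: int
    members: list[tuple[str, int]] = field(default_factory=list)

    @property
    def rep_pos(self) -> int:
        return (self.start + self.end) // 2

    @property
    def sources(self) -> set[str]:
        return {src for src, _ in self.members}

    def to_interval(self, name: str | None = None) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=name)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _parse_line(line: str, fmt: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    min_cols = 10 if fmt == "narrowpeak" else 3
    if len(fields) < min_cols:
        raise ValueError(
            f"line {lineno}: expected >= {min_cols} tab-separated columns, "
            f"got {len(fields)}"
        )
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed coordinates: {exc}") from None
    if start < 0 or end < 0:
        raise ValueError(f"line {lineno}: negative coordinates")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score: float | None = None
    if len(fields) > 4 and fields[4] != ".":
        try:
            score = float(fields[4])
        except ValueError:
            raise ValueError(f"line {lineno}: malformed score {fields[4]!r}") from None
    strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
    summit_offset = None
    if fmt == "narrowpeak":
        try:
            summit_offset = int(fields[9])
        except ValueError:
            raise ValueError(
                f"line {lineno}: malformed narrowPeak summit offset {fields[9]!r}"
            ) from None
        if summit_offset < 0:
            summit_offset = None  # -1 encodes "no summit called"
    try:
        return GenomicInterval(chrom, start, end, name, score, strand, summit_offset)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from None


def read_intervals(path, format: str = "bed") -> list[GenomicInterval]:
    """Read a BED3/BED6 or ENCODE narrowPeak file.

    Comment lines (``#``, ``track``, ``browser``) are skipped; input order is
    preserved.  For narrowPeak, each interval carries its summit offset.
    """
    fmt = format.lower()
    if fmt not in {"bed", "narrowpeak"}:
        raise ValueError(f"unknown format: {format!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            out.append(_parse_line(line, fmt, lineno))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path, format: str = "bed") -> None:
    """Write intervals as BED3/BED6 or narrowPeak.

    BED output is 3-column when no interval carries a name, score or strand,
    6-column otherwise.
    """
    fmt = format.lower()
    intervals = list(intervals)
    with open(path, "w") as fh:
        if fmt == "bed":
            six = any(
                iv.name is not None or iv.score is not None or iv.strand != "."
                for iv in intervals
            )
            for iv in intervals:
                if six:
                    score = "." if iv.score is None else _fmt_num(iv.score)
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                        f"{score}\t{iv.strand}\n"
                    )
                else:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        elif fmt == "narrowpeak":
            for iv in intervals:
                score = 0 if iv.score is None else _fmt_num(iv.score)
                offset = -1 if iv.summit_offset is None else iv.summit_offset
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t"
                    f"{iv.strand}\t0\t-1\t-1\t{offset}\n"
                )
        else:
            raise ValueError(f"unknown format: {format!r}")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# Summit merging and overlap logic
# ---------------------------------------------------------------------------


def merge_summits(summits: Iterable[Summit], max_dist: int = 100) -> list[MergedLocus]:
    """Single-linkage merge of summits within ``max_dist`` bp.

    Two summits end up in the same locus iff they are connected by a chain of
    pairwise distances <= ``max_dist`` on the same chromosome.  On a line this
    is a simple sorted sweep: a new locus starts whenever the gap to the
    previous summit exceeds ``max_dist``.  Loci are returned sorted by
    (chrom, start); each locus's envelope is ``[min pos, max pos + 1)``.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    ordered = sorted(summits, key=lambda s: (s.chrom, s.pos))
    loci: list[MergedLocus] = []
    for s in ordered:
        if (
            loci
            and loci[-1].chrom == s.chrom
            and s.pos - (loci[-1].end - 1) <= max_dist
        ):
            cur = loci[-1]
            cur.end = s.pos + 1
            cur.members.append((s.source, s.pos))
        else:
            loci.append(MergedLocus(s.chrom, s.pos, s.pos + 1, [(s.source, s.pos)]))
    return loci


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the half-open intervals share >= 1 bp on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlaps_any(
    query: Sequence[GenomicInterval], reference: Iterable[GenomicInterval]
) -> list[bool]:
    """For each query interval, whether it overlaps any reference interval.

    bedtools ``intersect -wa -u`` semantics (>= 1 bp, half-open).
    """
    trees: dict[str, IntervalTree] = {}
    for iv in reference:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return [
        bool(trees[q.chrom].overlap(q.start, q.end)) if q.chrom in trees else False
        for q in query
    ]


def resize_to_width(
    interval: GenomicInterval, width: int, anchor: str = "center"
) -> GenomicInterval:
    """Resize an interval to ``width`` bp around an anchor position.

    The anchor (interval center, or its summit for ``anchor='summit'``) lands
    at ``start + width // 2`` of the output.  At the chromosome start the
    window is clipped at 0 and extended right so the width is preserved
    (chromosome length is unknown at this level; callers holding a genome may
    re-clip the right edge).
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if anchor == "center":
        pos = interval.center
    elif anchor == "summit":
        if interval.summit is None:
            raise ValueError("interval has no summit offset")
        pos = interval.summit
    else:
        raise ValueError(f"unknown anchor: {anchor!r}")
    start = pos - width // 2
    if start < 0:
        start = 0
    return GenomicInterval(
        interval.chrom, start, start + width, interval.name, interval.score,
        interval.strand,
    )
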
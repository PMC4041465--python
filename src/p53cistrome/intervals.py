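"""Genomic interval algebra and peak-file I/O.

Coordinates are 0-based, half-open (BED standard) throughout the package.
Chromosome names are compared as exact strings; no ``chr`` aliasing is
performed (a converter is available in the CLI).

Peaks are point-source transcription-factor binding events: an interval, a
single-bp summit (the position of maximal pile-up, used to centre profile
windows), a caller score and the number of sequenced tags falling in the
peak.  Set operations are peak-level — ``subtract`` removes whole peaks
rather than trimming bases — matching Venn-style site counting.

File formats
------------
narrowPeak (ENCODE BED6+4): the 5th (BED score) column carries the integer
tag count, the 7th (signalValue) the floating-point peak score, and the 10th
the summit offset from ``start`` (−1 means unknown, resolved to the interval
midpoint).  BED3/BED6 carry no summit; the interval midpoint (floor) is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "PeakParseError",
    "read_peaks",
    "write_peaks",
    "merge_intervals",
    "overlap_pairs",
    "overlapping",
    "subtract",
]


class PeakParseError(ValueError):
    """Raised for malformed peak-file lines; carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """One called binding site.

    ``summit`` is an absolute bp position inside the interval, ``reads`` the
    tag count in the peak, ``sample_id`` a free-form label identifying
    factor / condition / replicate of origin.
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    reads: int = 0
    sample_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.interval.start}, {self.interval.end})"
            )
        if self.reads < 0:
            raise ValueError("reads must be >= 0")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.sample_id, self.name)


@dataclass
class PeakSet:
    """An ordered collection of peaks, kept sorted by (chrom, start, end).

    Duplicate (chrom, start, end, sample_id) entries are rejected: the same
    caller cannot report the same site twice.
    """

    peaks: list[Peak] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=Peak.sort_key)
        seen: set[tuple] = set()
        for p in self.peaks:
            key = (p.chrom, p.start, p.end, p.sample_id)
            if key in seen:
                raise ValueError(f"duplicate peak {key} in set {self.label!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def with_names(self, prefix: str = "peak") -> "PeakSet":
        """Return a copy in which every unnamed peak gets a positional name."""
        named = [
            p if p.name else replace(p, name=f"{prefix}_{i}")
            for i, p in enumerate(self.peaks)
        ]
        return PeakSet(named, label=self.label)


def _parse_int(tok: str, lineno: int, what: str) -> int:
    try:
        return int(tok)
    except ValueError:
        raise PeakParseError(f"line {lineno}: malformed {what} {tok!r}") from None


def read_peaks(path: str | Path, format: str = "narrowPeak", sample_id: str = "") -> PeakSet:
    """Read a peak file into a :class:`PeakSet`.

    Parameters
    ----------
    format:
        ``"narrowPeak"`` (10-column ENCODE) or ``"bed"`` (BED3/BED6).
    sample_id:
        Label stamped on every peak (defaults to the file stem).
    """
    if format not in ("narrowPeak", "bed"):
        raise ValueError(f"unknown peak format {format!r}")
    path = Path(path)
    sid = sample_id or path.stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise PeakParseError(f"line {lineno}: expected >=3 tab-separated fields")
            chrom = f[0]
            start = _parse_int(f[1], lineno, "start")
            end = _parse_int(f[2], lineno, "end")
            if start >= end:
                raise PeakParseError(f"line {lineno}: start {start} >= end {end}")
            name = f[3] if len(f) > 3 and f[3] != "." else ""
            reads = 0
            score = 0.0
            if format == "narrowPeak":
                if len(f) < 10:
                    raise PeakParseError(
                        f"line {lineno}: narrowPeak requires 10 fields, got {len(f)}"
                    )
                reads = _parse_int(f[4], lineno, "score/reads")
                try:
                    score = float(f[6])
                except ValueError:
                    raise PeakParseError(
                        f"line {lineno}: malformed signalValue {f[6]!r}"
                    ) from None
                offset = _parse_int(f[9], lineno, "summit offset")
                summit = start + offset if offset >= 0 else start + (end - start) // 2
            else:
                if len(f) > 4 and f[4] != ".":
                    try:
                        score = float(f[4])
                    except ValueError:
                        raise PeakParseError(f"line {lineno}: malformed score {f[4]!r}") from None
                summit = start + (end - start) // 2
            if not (start <= summit < end):
                raise PeakParseError(f"line {lineno}: summit {summit} outside [{start}, {end})")
            try:
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end), summit, score, reads, sid, name)
                )
            except ValueError as exc:
                raise PeakParseError(f"line {lineno}: {exc}") from None
    return PeakSet(peaks, label=sid)


def write_peaks(peaks: PeakSet, path: str | Path, format: str = "narrowPeak") -> None:
    """Write a sorted BED6 or narrowPeak file (summits preserved exactly)."""
    if format not in ("narrowPeak", "bed"):
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i}"
            if format == "narrowPeak":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.reads}\t.\t"
                    f"{p.score:g}\t-1\t-1\t{p.summit - p.start}\n"
                )
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score:g}\t.\n")


def merge_intervals(peaks: PeakSet | Iterable[Peak], label: str = "") -> PeakSet:
    """Merge overlapping peaks into non-overlapping sites.

    The union of covered bases is preserved and the interval count equals
    the number of connected runs of covered bases (book-ended intervals
    like [0,10) and [10,20) coalesce, as in ``bedtools merge``).  A merged
    site takes the summit of its highest-scoring constituent (strongest
    local maximum), the sum of constituent tag counts and the maximum
    score.  Idempotent.
    """
    plist = sorted(peaks, key=Peak.sort_key)
    merged: list[Peak] = []
    for p in plist:
        if merged and merged[-1].chrom == p.chrom and p.start <= merged[-1].end:
            cur = merged[-1]
            best = cur if cur.score >= p.score else p
            merged[-1] = Peak(
                GenomicInterval(cur.chrom, cur.start, max(cur.end, p.end)),
                best.summit,
                max(cur.score, p.score),
                cur.reads + p.reads,
                cur.sample_id if cur.sample_id == p.sample_id else "",
                cur.name,
            )
        else:
            merged.append(p)
    return PeakSet(merged, label=label or getattr(peaks, "label", ""))


def _tree_by_chrom(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def overlap_pairs(a: PeakSet, b: PeakSet, min_bp: int = 1) -> list[tuple[Peak, Peak]]:
    """All (peak-in-a, peak-in-b) pairs sharing at least ``min_bp`` bases."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _tree_by_chrom(b)
    pairs: list[tuple[Peak, Peak]] = []
    for pa in a:
        tree = trees.get(pa.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(pa.start, pa.end), key=lambda iv: (iv.begin, iv.end))
        for iv in hits:
            pb: Peak = iv.data
            if pa.interval.overlap_bp(pb.interval) >= min_bp:
                pairs.append((pa, pb))
    return pairs


def overlapping(a: PeakSet, b: PeakSet, min_bp: int = 1) -> PeakSet:
    """Peaks of ``a`` sharing at least ``min_bp`` bases with any peak of ``b``."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _tree_by_chrom(b)
    kept = []
    for pa in a:
        tree = trees.get(pa.chrom)
        if tree is None:
            continue
        if any(pa.interval.overlap_bp(iv.data.interval) >= min_bp for iv in tree.overlap(pa.start, pa.end)):
            kept.append(pa)
    return PeakSet(kept, label=a.label)


def subtract(a: PeakSet, b: PeakSet) -> PeakSet:
    """Whole peaks of ``a`` with zero base overlap against every peak of ``b``.

    Peak-level subtraction (no base trimming): together with
    :func:`overlapping` at ``min_bp=1`` this partitions ``a``.
    """
    trees = _tree_by_chrom(b)
    kept = []
    for pa in a:
        tree = trees.get(pa.chrom)
        if tree is None or not tree.overlap(pa.start, pa.end):
            kept.append(pa)
    return PeakSet(kept, label=a.label)
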
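"""Peak-to-gene annotation within a distance window and TSS stratification.

A peak is associated with every gene whose span, extended by ``window`` bp
on both sides (default 25 kb), it overlaps by at least one base.  Signed
distances are measured from the peak summit to the transcription start site
(TSS) and termination site (TTS), flipped on the minus strand so that
positive always means downstream of the TSS in the direction of
transcription.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import PeakSet

__all__ = [
    "GeneRecord",
    "AnnotationMap",
    "read_genes_bed",
    "write_genes_bed",
    "annotate_peaks",
    "tss_distances",
    "stratify_by_distance",
]


@dataclass(frozen=True)
class GeneRecord:
    """A stranded gene span (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class AnnotationMap:
    """Peak-gene associations: one row per (peak, gene) pair.

    Columns: peak_id, gene_id, tss_distance, tts_distance, overlap_class
    (``gene_body`` when the peak overlaps the unextended span, ``flank``
    otherwise).
    """

    associations: pd.DataFrame
    window: int

    def to_tsv(self, path: str | Path) -> None:
        self.associations.to_csv(path, sep="\t", index=False)


def read_genes_bed(path: str | Path) -> list[GeneRecord]:
    """Read a BED6 gene-model table (one span per gene)."""
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"line {lineno}: gene BED needs 6 fields")
            genes.append(GeneRecord(f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return genes


def write_genes_bed(genes: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def _signed(summit: int, anchor: int, strand: str) -> int:
    d = summit - anchor
    return d if strand == "+" else -d


def annotate_peaks(
    peaks: PeakSet, genes: list[GeneRecord], window: int = 25000
) -> AnnotationMap:
    """Associate each peak with every gene within ``window`` bp.

    Association holds iff the peak interval overlaps
    [gene.start - window, gene.end + window) by >=1 bp.  A peak may map to
    several genes and vice versa.  Signed distances are summit-based and
    strand-aware (positive = downstream of the TSS).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.start - window), g.end + window, g
        )
    named = peaks.with_names("peak")
    rows = []
    for p in named:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(p.start, p.end), key=lambda iv: (iv.begin, iv.end)):
            g: GeneRecord = iv.data
            body = max(p.start, g.start) < min(p.end, g.end)
            rows.append(
                {
                    "peak_id": p.name,
                    "gene_id": g.gene_id,
                    "tss_distance": _signed(p.summit, g.tss, g.strand),
                    "tts_distance": _signed(p.summit, g.tts, g.strand),
                    "overlap_class": "gene_body" if body else "flank",
                }
            )
    cols = ["peak_id", "gene_id", "tss_distance", "tts_distance", "overlap_class"]
    df = pd.DataFrame(rows, columns=cols)
    return AnnotationMap(df, window)


def tss_distances(
    amap: AnnotationMap, bin_edges: np.ndarray | list[int]
) -> dict[str, np.ndarray]:
    """Per-association signed distances plus histogram counts.

    Returns arrays ``tss``, ``tts`` and histogram counts ``tss_hist`` /
    ``tts_hist`` over the supplied strictly increasing bin edges.
    """
    edges = np.asarray(bin_edges)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    tss = amap.associations["tss_distance"].to_numpy(dtype=float)
    tts = amap.associations["tts_distance"].to_numpy(dtype=float)
    return {
        "tss": tss,
        "tts": tts,
        "tss_hist": np.histogram(tss, bins=edges)[0],
        "tts_hist": np.histogram(tts, bins=edges)[0],
    }


def stratify_by_distance(peaks: PeakSet, genes: list[GeneRecord]) -> pd.Series:
    """Classify each peak by absolute distance of its summit to the nearest TSS.

    proximal: |d| < 5 kb; distal: 5 kb <= |d| <= 25 kb; remote: |d| > 25 kb.
    With no genes supplied every peak is remote (with a warning).
    """
    named = peaks.with_names("peak")
    if not genes:
        warnings.warn("no genes supplied; all peaks classified remote")
        return pd.Series("remote", index=[p.name for p in named], name="tss_class")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])  # type: ignore[arg-type]
        tss_by_chrom[g.chrom].append(g.tss)  # type: ignore[union-attr]
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    classes = []
    for p in named:
        arr = tss_by_chrom.get(p.chrom)
        if arr is None:
            classes.append("remote")
            continue
        i = np.searchsorted(arr, p.summit)
        cand = [abs(p.summit - arr[j]) for j in (i - 1, i) if 0 <= j < len(arr)]
        d = min(cand)
        if d < 5000:
            classes.append("proximal")
        elif d <= 25000:
            classes.append("distal")
        else:
            classes.append("remote")
    return pd.Series(classes, index=[p.name for p in named], name="tss_class")
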
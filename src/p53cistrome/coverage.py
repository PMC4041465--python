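"""Normalized signal tracks, summit-centred matrices, profiles and clustering.

Tracks are per-chromosome step vectors of non-negative coverage (one value
per ``step`` bp).  Normalization scales signal to a fixed sequencing depth
of 10 million mapped reads, so that samples of different library size are
comparable.  Summit-centred matrices underlie the binding-intensity
heatmaps and average ("sitepro"-style) profiles; k-means clustering runs on
the raw, unscaled rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .intervals import PeakSet

__all__ = [
    "SignalTrack",
    "SignalMatrix",
    "read_bedgraph",
    "read_wiggle",
    "write_bedgraph",
    "normalize_track",
    "site_matrix",
    "average_profile",
    "kmeans_rows",
]

DEPTH_SCALE = 1e7  # reference depth: per 10 million reads


@dataclass
class SignalTrack:
    """Step-vector coverage: ``values[chrom][i]`` covers bases [i*step, (i+1)*step)."""

    values: dict[str, np.ndarray]
    step: int
    library_size: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        for chrom, v in self.values.items():
            if np.any(np.asarray(v) < 0):
                raise ValueError(f"negative coverage on {chrom}")


@dataclass
class SignalMatrix:
    """Sites x bins matrix of mean signal around summits (summit +/- flank)."""

    values: np.ndarray
    site_ids: list[str]
    flank: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.values.shape[1] != 2 * self.flank // self.bin_size:
            raise ValueError("column count inconsistent with flank/bin_size")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        centres = np.arange(self.values.shape[1]) * self.bin_size - self.flank + self.bin_size // 2
        df = pd.DataFrame(self.values, index=self.site_ids, columns=centres)
        df.index.name = "site_id"
        df.to_csv(path, sep="\t")


def read_bedgraph(
    path: str | Path, chrom_sizes: dict[str, int], step: int, library_size: float
) -> SignalTrack:
    """Read a bedGraph into a step-vector track (mean value per step window)."""
    per_base = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"line {lineno}: bedGraph needs 4 fields")
            chrom, start, end, val = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in per_base:
                raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
            per_base[chrom][start : min(end, chrom_sizes[chrom])] = val
    return SignalTrack(_downsample(per_base, step), step, library_size)


def read_wiggle(
    path: str | Path, chrom_sizes: dict[str, int], library_size: float
) -> SignalTrack:
    """Read a fixedStep wiggle file; the declared step becomes the track step."""
    per_base: dict[str, np.ndarray] = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    chrom, pos, span, wig_step = None, 0, 1, 1
    steps_seen: set[int] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                if chrom not in per_base:
                    raise ValueError(f"unknown chromosome {chrom!r} in wiggle")
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                wig_step = int(kv.get("step", 1))
                span = int(kv.get("span", wig_step))
                steps_seen.add(wig_step)
                continue
            if chrom is None:
                raise ValueError("wiggle data before fixedStep header")
            val = float(line)
            end = min(pos + span, chrom_sizes[chrom])
            per_base[chrom][pos:end] = val
            pos += wig_step
    step = steps_seen.pop() if len(steps_seen) == 1 else 1
    return SignalTrack(_downsample(per_base, step), step, library_size)


def _downsample(per_base: dict[str, np.ndarray], step: int) -> dict[str, np.ndarray]:
    out = {}
    for chrom, v in per_base.items():
        n = len(v)
        nsteps = -(-n // step)
        padded = np.zeros(nsteps * step)
        padded[:n] = v
        out[chrom] = padded.reshape(nsteps, step).mean(axis=1)
    return out


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write the track as bedGraph, one line per step with nonzero value."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            for i in np.nonzero(v)[0]:
                s = int(i) * track.step
                fh.write(f"{chrom}\t{s}\t{s + track.step}\t{v[i]:g}\n")


def normalize_track(track: SignalTrack) -> SignalTrack:
    """Scale values to a 10-million-read library (multiply by 1e7/library_size)."""
    if track.normalized:
        raise ValueError("track already normalized")
    factor = DEPTH_SCALE / track.library_size
    values = {c: v * factor for c, v in track.values.items()}
    return replace(track, values=values, normalized=True)


def site_matrix(
    track: SignalTrack, sites: PeakSet, flank: int = 5000, bin_size: int = 50
) -> SignalMatrix:
    """Mean signal in ``bin_size`` windows across summit +/- ``flank`` per site.

    Bins reaching past chromosome ends contribute zero signal for the
    out-of-range bases.  Sites on chromosomes absent from the track yield a
    zero row and a warning.
    """
    if flank % bin_size:
        raise ValueError("flank must be divisible by bin_size")
    if not track.normalized:
        raise ValueError("normalize the track before building matrices")
    named = sites.with_names("site")
    ncol = 2 * flank // bin_size
    mat = np.zeros((len(named), ncol))
    for i, p in enumerate(named):
        v = track.values.get(p.chrom)
        if v is None:
            warnings.warn(f"chromosome {p.chrom!r} absent from track; zero row")
            continue
        chrom_len = len(v) * track.step
        pos = np.arange(p.summit - flank, p.summit + flank)
        valid = (pos >= 0) & (pos < chrom_len)
        base_vals = np.zeros(2 * flank)
        base_vals[valid] = v[pos[valid] // track.step]
        mat[i] = base_vals.reshape(ncol, bin_size).mean(axis=1)
    return SignalMatrix(mat, [p.name for p in named], flank, bin_size)


def average_profile(m: SignalMatrix) -> np.ndarray:
    """Column-wise mean of the site matrix (the average binding profile)."""
    if m.values.shape[0] == 0:
        raise ValueError("cannot average an empty matrix")
    return m.values.mean(axis=0)


def kmeans_rows(m: SignalMatrix, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd k-means on raw (unscaled) rows with k-means++ seeding.

    Clusters are relabelled by descending mean row signal, so label 0 is
    always the strongest-signal cluster.  Deterministic for a fixed seed.
    Returns (labels, centroids).
    """
    n = m.values.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"{n} rows < k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed, algorithm="lloyd")
    raw_labels = km.fit_predict(m.values)
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw_labels], km.cluster_centers_[order]
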
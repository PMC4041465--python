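"""Consensus scanning for p53-family response elements.

The canonical p53 response element is two RRRCWWGYYY decamers (R = purine,
W = A/T, Y = pyrimidine) separated by a spacer of variable length; one
decamer is a half-site, and the central C..G tetramer (``CxxG``) is the
core contact.  Scanning uses IUPAC class matching (not PWM scoring) on
explicit base-class arrays; N never matches any class.

Because the decamer's class pattern is its own reverse complement (as is
CxxG), every match on the forward strand corresponds to a match at the same
offset on the reverse strand.  Hits are therefore reported once with
strand ``+``, and all coverage statistics are strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .intervals import PeakSet

__all__ = [
    "MotifHit",
    "extract_windows",
    "scan_p53_sites",
    "motif_coverage",
    "HALF_SITE_LEN",
]

HALF_SITE_LEN = 10
DEFAULT_SPACERS = range(0, 14)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One response-element match inside a sequence."""

    seq_id: str
    offset: int
    kind: str  # full_site | half_site | core
    spacer: int  # full sites only; -1 otherwise
    text: str
    strand: str = "+"


def _class_arrays(seq: str) -> dict[str, np.ndarray]:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    legal = np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if not legal.all():
        pos = int(np.nonzero(~legal)[0][0])
        raise ValueError(f"illegal character {seq[pos]!r} at position {pos}")
    a, c, g, t = (arr == ord(b) for b in "ACGT")
    return {
        "R": a | g,
        "Y": c | t,
        "W": a | t,
        "C": c,
        "G": g,
        "X": a | c | g | t,  # any non-N base
    }


def _match_pattern(classes: dict[str, np.ndarray], pattern: str) -> np.ndarray:
    """Boolean array: True at every offset where ``pattern`` matches."""
    n = len(classes["C"])
    w = len(pattern)
    if n < w:
        return np.zeros(0, dtype=bool)
    out = np.ones(n - w + 1, dtype=bool)
    for i, sym in enumerate(pattern):
        out &= classes[sym][i : i + n - w + 1]
    return out


def scan_p53_sites(
    seq: str, spacer_range: Iterable[int] = DEFAULT_SPACERS, seq_id: str = ""
) -> list[MotifHit]:
    """All half-site, full-site and core matches in ``seq``.

    half_site: RRRCWWGYYY.  full_site: two half-sites separated by a spacer
    whose length lies in ``spacer_range`` (default 0-13 bp).  core: C..G
    with any two intervening non-N bases; reported separately and never
    counted toward half/full statistics.  Overlapping hits are all
    reported, in ascending offset.
    """
    classes = _class_arrays(seq)
    half = _match_pattern(classes, "RRRCWWGYYY")
    core = _match_pattern(classes, "CXXG")
    hits: list[MotifHit] = []
    half_offsets = np.nonzero(half)[0]
    spacers = sorted(set(int(s) for s in spacer_range))
    for i in half_offsets:
        for s in spacers:
            j = i + HALF_SITE_LEN + s
            if j < len(half) and half[j]:
                width = 2 * HALF_SITE_LEN + s
                hits.append(
                    MotifHit(seq_id, int(i), "full_site", s, seq[i : i + width])
                )
        hits.append(
            MotifHit(seq_id, int(i), "half_site", -1, seq[i : i + HALF_SITE_LEN])
        )
    for i in np.nonzero(core)[0]:
        hits.append(MotifHit(seq_id, int(i), "core", -1, seq[i : i + 4]))
    hits.sort(key=lambda h: (h.offset, h.kind, h.spacer))
    return hits


def extract_windows(
    peaks: PeakSet,
    genome: dict[str, str],
    width: int = 500,
    max_peaks: int = 5000,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Summit-centred sequence windows, subsampled when the set is large.

    Each window spans [summit - width/2, summit + width/2), clipped at
    chromosome ends.  When more than ``max_peaks`` peaks are supplied a
    seeded uniform subsample of exactly ``max_peaks`` is taken.  ``genome``
    is any mapping from chromosome name to sequence (a ``pyfaidx.Fasta``
    works via ``str``-conversion of its records).
    """
    if width % 2:
        raise ValueError("width must be even")
    named = peaks.with_names("peak")
    chosen = list(named)
    if len(chosen) > max_peaks:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(chosen), size=max_peaks, replace=False))
        chosen = [chosen[i] for i in idx]
    windows = []
    for p in chosen:
        if p.chrom not in genome:
            raise ValueError(f"chromosome {p.chrom!r} missing from genome")
        seq = str(genome[p.chrom])
        lo = max(0, p.summit - width // 2)
        hi = min(len(seq), p.summit + width // 2)
        windows.append((p.name, seq[lo:hi].upper()))
    return windows


def motif_coverage(
    windows: Sequence[tuple[str, str]],
    spacer_range: Iterable[int] = DEFAULT_SPACERS,
    density_bin: int = 25,
) -> dict:
    """Per-peakset motif coverage statistics.

    Fractions of windows containing at least one full site, half site and
    core, plus the positional density of the best hit per window (the full
    site — or half site when no full site exists — whose centre lies
    nearest the window centre), binned at ``density_bin`` bp relative to
    the window centre.
    """
    if not windows:
        raise ValueError("need at least one window")
    n = len(windows)
    n_full = n_half = n_core = 0
    best_offsets: list[float] = []
    for seq_id, seq in windows:
        hits = scan_p53_sites(seq, spacer_range, seq_id)
        fulls = [h for h in hits if h.kind == "full_site"]
        halves = [h for h in hits if h.kind == "half_site"]
        cores = [h for h in hits if h.kind == "core"]
        n_full += bool(fulls)
        n_half += bool(halves)
        n_core += bool(cores)
        pool = fulls or halves
        if pool:
            centre = len(seq) / 2
            best = min(pool, key=lambda h: abs(h.offset + len(h.text) / 2 - centre))
            best_offsets.append(best.offset + len(best.text) / 2 - centre)
    offsets = np.asarray(best_offsets)
    if offsets.size:
        half_span = max(np.abs(offsets).max(), density_bin)
        nbins = int(np.ceil(half_span / density_bin))
        edges = np.arange(-nbins, nbins + 1) * density_bin
        counts = np.histogram(offsets, bins=edges)[0]
    else:
        edges = np.array([-density_bin, 0, density_bin])
        counts = np.zeros(2, dtype=int)
    return {
        "full_site_fraction": n_full / n,
        "half_site_fraction": n_half / n,
        "core_fraction": n_core / n,
        "density_edges": edges,
        "density_counts": counts,
    }
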
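import numpy as np
import pytest

from p53cistrome.intervals import GenomicInterval, Peak, PeakSet
from p53cistrome.simulate import TruthConfig


def random_peakset(rng, n, chrom_len=10_000, chroms=("chrA",), label="x", max_len=200):
    """Random peaks for brute-force comparisons (duplicates skipped)."""
    peaks, seen = [], set()
    while len(peaks) < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - 2))
        length = int(rng.integers(1, max_len + 1))
        end = min(start + length, chrom_len)
        key = (chrom, start, end)
        if key in seen:
            continue
        seen.add(key)
        summit = int(rng.integers(start, end))
        peaks.append(
            Peak(GenomicInterval(chrom, start, end), summit,
                 float(rng.random()), int(rng.integers(0, 100)), label,
                 f"{label}_{len(peaks)}")
        )
    return PeakSet(peaks, label=label)


def coverage_mask(peaks, chrom, chrom_len):
    """Per-base boolean occupancy — the brute-force interval oracle."""
    mask = np.zeros(chrom_len, dtype=bool)
    for p in peaks:
        if p.chrom == chrom:
            mask[p.start : p.end] = True
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(20240513)


@pytest.fixture
def small_cfg():
    """Scaled-down generator configuration for fast end-to-end tests."""
    return TruthConfig(
        seed=7,
        chrom_sizes={"chr1": 770_000, "chr2": 770_000, "chr3": 770_000},
        n_genes=40,
        n_shared=40,
        n_tp53_only=24,
        n_tp63_only=36,
        n_tp53_tp63reponly=8,
        n_tp63_tp53reponly=8,
        n_rep_only=6,
        n_blacklist_artifact=4,
        n_highread_artifact=4,
        n_induced=8,
        n_repressed=6,
        n_tp63_maintained=4,
        n_undetected=4,
    )


@pytest.fixture
def small_cfg_noiseless(small_cfg):
    small_cfg.jitter_sd = 0.0
    small_cfg.dropout = 0.0
    small_cfg.expr_noise_sd = 0.0
    return small_cfg
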
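"""Differential occupancy from per-site read counts.

Per-site counts across samples are compared between two groups with an
exact conditional binomial test: counts are pooled within each group and,
conditional on the site total, the group-A share is binomial with success
probability equal to group A's share of the total library.  This uses
library-size (sequencing-depth) normalization only — no replicate-wise
dispersion modelling — and yields exact two-sided p-values even at low
counts.  Multiplicity is controlled by Benjamini-Hochberg; a site is called
significant when its q-value falls below the FDR threshold (default 0.1).

Fold changes are reported on the reads-per-10-million scale with a 0.5
pseudocount, and ``conc`` is the log2 mean normalized concentration used
for MA-style plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet

__all__ = [
    "SiteCountTable",
    "differential_sites",
    "bh_adjust",
    "count_reads_in_sites",
    "read_count_table",
    "write_count_table",
]

DEPTH_SCALE = 1e7


@dataclass
class SiteCountTable:
    """Integer counts (sites x samples) with per-sample library sizes."""

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample labels")
        missing = set(self.counts.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"library sizes missing for samples: {sorted(missing)}")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be > 0")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")


def write_count_table(table: SiteCountTable, path: str | Path) -> None:
    """TSV with a ``#library_sizes`` header line before the count matrix."""
    with open(path, "w") as fh:
        sizes = "\t".join(
            f"{s}={table.library_sizes[s]:g}" for s in table.counts.columns
        )
        fh.write(f"#library_sizes\t{sizes}\n")
        table.counts.to_csv(fh, sep="\t", index_label="site_id")


def read_count_table(path: str | Path) -> SiteCountTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#library_sizes"):
            raise ValueError("count table must start with a #library_sizes line")
        sizes = {}
        for tok in header.split("\t")[1:]:
            name, val = tok.split("=")
            sizes[name] = float(val)
        counts = pd.read_csv(fh, sep="\t", index_col="site_id")
    return SiteCountTable(counts.astype(np.int64), pd.Series(sizes))


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_sites(
    table: SiteCountTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Exact conditional test of differential occupancy, B versus A.

    Counts are pooled per group (x_a, x_b; libraries L_a, L_b).  The
    two-sided p-value is the exact binomial test of x_a successes in
    x_a + x_b trials at success probability L_a / (L_a + L_b).  log2_fc is
    log2((x_b + 0.5)/L_b) - log2((x_a + 0.5)/L_a); conc is the log2 mean of
    the two normalized concentrations on the per-10-million scale.  Sites
    with zero total count get p = 1, log2_fc = 0 and ``testable`` False.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    for s in group_a + group_b:
        if s not in table.counts.columns:
            raise ValueError(f"unknown sample {s!r}")
    x_a = table.counts[group_a].sum(axis=1).to_numpy()
    x_b = table.counts[group_b].sum(axis=1).to_numpy()
    l_a = float(table.library_sizes[group_a].sum())
    l_b = float(table.library_sizes[group_b].sum())
    p_null = l_a / (l_a + l_b)
    total = x_a + x_b
    pvals = np.ones(len(total))
    for i, (xa, n) in enumerate(zip(x_a, total)):
        if n > 0:
            pvals[i] = stats.binomtest(int(xa), int(n), p_null).pvalue
    rate_a = (x_a + 0.5) / l_a * DEPTH_SCALE
    rate_b = (x_b + 0.5) / l_b * DEPTH_SCALE
    log2_fc = np.where(total > 0, np.log2(rate_b) - np.log2(rate_a), 0.0)
    conc = np.log2((rate_a + rate_b) / 2)
    q = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "conc": conc,
            "log2_fc": log2_fc,
            "pvalue": pvals,
            "qvalue": q,
            "significant": q < fdr,
            "testable": total > 0,
        },
        index=table.counts.index,
    )


def count_reads_in_sites(
    read_positions: dict[str, np.ndarray], sites: PeakSet
) -> pd.Series:
    """Count read start positions falling inside each site interval.

    ``read_positions`` maps chromosome to a (not necessarily sorted) array
    of 0-based read start coordinates; a read counts once for every site
    whose [start, end) contains it.
    """
    named = sites.with_names("site")
    sorted_pos = {c: np.sort(v) for c, v in read_positions.items()}
    out = {}
    for p in named:
        arr = sorted_pos.get(p.chrom)
        if arr is None:
            out[p.name] = 0
        else:
            out[p.name] = int(
                np.searchsorted(arr, p.end, "left") - np.searchsorted(arr, p.start, "left")
            )
    return pd.Series(out, name="reads")
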
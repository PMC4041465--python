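"""Replicate-consensus peaksets, artifact filtering and cistrome set algebra.

A consensus site is kept only when supported by peak calls in *both*
biological replicates of a factor x condition combination.  Consensus sets
from the three treatment conditions (untreated, adriamycin, cisplatin) are
pooled into a factor cistrome with per-condition membership flags, from
which the subtractive site classes are computed: factor-unique sites
(present in one factor's pooled set, absent from every sample of the other)
and damage-induced classes (sites appearing only after genotoxic treatment,
split by agent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import (
    GenomicInterval,
    Peak,
    PeakSet,
    merge_intervals,
    overlapping,
    subtract,
)

__all__ = [
    "ConsensusSet",
    "PooledCistrome",
    "consensus_replicates",
    "filter_peaks",
    "pool_conditions",
    "unique_sites",
    "damage_induced_classes",
    "condition_venn",
    "write_membership_table",
]

CONDITIONS = ("untreated", "adriamycin", "cisplatin")


@dataclass
class ConsensusSet:
    """Merged replicate-supported sites for one factor x condition.

    ``provenance[i]`` lists the (sample_id, name) identifiers of the
    replicate peaks supporting consensus peak ``i``.
    """

    factor: str
    condition: str
    peaks: PeakSet
    provenance: list[list[tuple[str, str]]] = field(default_factory=list)


@dataclass
class PooledCistrome:
    """Union of a factor's consensus sites across conditions.

    ``membership`` is a boolean DataFrame indexed by site name with one
    column per condition; a flag is true iff the pooled site overlaps (>=1
    bp) a peak of that condition's consensus set.
    """

    factor: str
    sites: PeakSet
    membership: pd.DataFrame


def consensus_replicates(
    rep1: PeakSet, rep2: PeakSet, factor: str = "", condition: str = ""
) -> ConsensusSet:
    """Derive the consensus peakset of two biological replicates.

    Peaks of rep1 u rep2 are grouped into connected components of the
    pairwise-overlap graph (a chain of >=1-bp overlaps).  A component
    yields one consensus site iff it contains at least one peak from each
    replicate; the site spans the union of the component, takes the summit
    of the highest-scoring member and the maximum member tag count.
    Symmetric in its arguments.
    """
    if rep1.label and rep1.label == rep2.label:
        raise ValueError(f"replicate labels identical: {rep1.label!r}")
    tagged = [(p, 0) for p in rep1] + [(p, 1) for p in rep2]
    tagged.sort(key=lambda t: t[0].sort_key())
    out: list[Peak] = []
    prov: list[list[tuple[str, str]]] = []
    component: list[tuple[Peak, int]] = []

    def flush() -> None:
        if not component:
            return
        origins = {o for _, o in component}
        if origins == {0, 1}:
            members = [p for p, _ in component]
            best = max(members, key=lambda p: (p.score, -p.start))
            start = min(p.start for p in members)
            end = max(p.end for p in members)
            out.append(
                Peak(
                    GenomicInterval(members[0].chrom, start, end),
                    best.summit,
                    best.score,
                    max(p.reads for p in members),
                    f"{factor}:{condition}" if factor or condition else "consensus",
                )
            )
            prov.append([(p.sample_id, p.name) for p in members])
        component.clear()

    cur_chrom, cur_end = None, -1
    for p, origin in tagged:
        if p.chrom != cur_chrom or p.start >= cur_end:
            flush()
            cur_chrom, cur_end = p.chrom, p.end
        else:
            cur_end = max(cur_end, p.end)
        component.append((p, origin))
    flush()
    label = f"{factor}_{condition}_consensus".strip("_")
    ps = PeakSet(out, label=label).with_names(label or "consensus")
    return ConsensusSet(factor, condition, ps, prov)


def filter_peaks(peaks: PeakSet, blacklist: PeakSet | None, max_reads: int = 1000) -> PeakSet:
    """Remove blacklist-overlapping peaks and read-count artifacts.

    A peak is dropped when it overlaps any blacklist interval by >=1 bp or
    when its tag count strictly exceeds ``max_reads`` (peaks with exactly
    ``max_reads`` tags are retained).  Order is preserved.
    """
    if max_reads <= 0:
        raise ValueError("max_reads must be > 0")
    kept = peaks
    if blacklist is not None and len(blacklist):
        kept = subtract(kept, blacklist)
    return PeakSet([p for p in kept if p.reads <= max_reads], label=peaks.label)


def pool_conditions(sets: Sequence[ConsensusSet]) -> PooledCistrome:
    """Merge a factor's consensus sets across conditions into one cistrome."""
    if not sets:
        raise ValueError("need at least one consensus set")
    factors = {s.factor for s in sets}
    if len(factors) > 1:
        raise ValueError(f"mixed factors in pooling: {sorted(factors)}")
    factor = sets[0].factor
    all_peaks = [p for s in sets for p in s.peaks]
    pooled = merge_intervals(all_peaks, label=f"{factor}_pooled").with_names(
        f"{factor or 'pooled'}_site"
    )
    flags = {}
    for s in sets:
        hit_names = {p.name for p in overlapping(pooled, s.peaks)}
        flags[s.condition] = [p.name in hit_names for p in pooled]
    membership = pd.DataFrame(flags, index=[p.name for p in pooled])
    return PooledCistrome(factor, pooled, membership)


def unique_sites(
    pooled_a: PooledCistrome,
    pooled_b: PooledCistrome,
    individual_b_samples: Iterable[PeakSet],
) -> dict[str, PeakSet]:
    """Factor-unique sites of ``a`` at two stringencies.

    ``non_overlapping``: pooled sites of ``a`` with no overlap against
    ``b``'s pooled consensus cistrome.  ``strict_unique``: those further
    lacking overlap with any *individual* (pre-consensus) replicate peak
    call of factor ``b`` — the robust factor-only definition.
    """
    non_overlapping = subtract(pooled_a.sites, pooled_b.sites)
    raw_b = merge_intervals([p for s in individual_b_samples for p in s])
    strict = subtract(non_overlapping, raw_b)
    return {"non_overlapping": non_overlapping, "strict_unique": strict}


def damage_induced_classes(
    untreated: ConsensusSet, adr: ConsensusSet, cis: ConsensusSet
) -> dict[str, PeakSet]:
    """Subtractive classification of damage-induced binding events.

    ``adr_only``: consensus sites under adriamycin overlapping neither the
    untreated nor the cisplatin consensus; ``cis_only`` symmetric;
    ``shared_damage``: sites present under both agents but absent untreated.
    The three outputs are pairwise disjoint by construction.
    """
    factors = {untreated.factor, adr.factor, cis.factor}
    if len(factors) > 1:
        raise ValueError(f"mixed factors: {sorted(factors)}")
    adr_only = subtract(subtract(adr.peaks, untreated.peaks), cis.peaks)
    cis_only = subtract(subtract(cis.peaks, untreated.peaks), adr.peaks)
    shared = subtract(overlapping(adr.peaks, cis.peaks), untreated.peaks)
    return {"adr_only": adr_only, "cis_only": cis_only, "shared_damage": shared}


def condition_venn(pooled: PooledCistrome) -> dict[tuple[bool, ...], int]:
    """Counts of pooled sites per combination of condition membership flags.

    Keys are tuples of flags in the column order of ``pooled.membership``.
    """
    counts: dict[tuple[bool, ...], int] = {}
    for _, row in pooled.membership.iterrows():
        key = tuple(bool(v) for v in row)
        counts[key] = counts.get(key, 0) + 1
    return counts


def write_membership_table(pooled: PooledCistrome, path: str | Path) -> None:
    """Tab-separated site table: id, coordinates, per-condition flags."""
    rows = []
    for p in pooled.sites:
        rec = {"site_id": p.name, "chrom": p.chrom, "start": p.start, "end": p.end}
        rec.update({c: int(v) for c, v in pooled.membership.loc[p.name].items()})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
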
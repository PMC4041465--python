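"""Replicate consensus, artifact filtering and subtractive cistrome classes."""

import pytest

from p53cistrome.consensus import (
    ConsensusSet,
    condition_venn,
    consensus_replicates,
    damage_induced_classes,
    filter_peaks,
    pool_conditions,
    unique_sites,
)
from p53cistrome.intervals import GenomicInterval, Peak, PeakSet, overlapping, subtract


def mk(intervals, label, reads=10, score=None):
    peaks = []
    for i, (start, end) in enumerate(intervals):
        s = score[i] if score is not None else 1.0
        peaks.append(
            Peak(GenomicInterval("chr1", start, end), (start + end) // 2, s, reads,
                 label, f"{label}_{i}")
        )
    return PeakSet(peaks, label=label)


class TestConsensusReplicates:
    def test_overlapping_pair_unioned(self):
        cs = consensus_replicates(mk([(100, 200)], "r1"), mk([(150, 250)], "r2"))
        assert [(p.start, p.end) for p in cs.peaks] == [(100, 250)]
        assert len(cs.provenance[0]) == 2

    def test_replicate_only_peak_excluded(self):
        cs = consensus_replicates(mk([(100, 200)], "r1"), mk([(500, 600)], "r2"))
        assert len(cs.peaks) == 0

    def test_symmetric(self):
        r1 = mk([(0, 100), (300, 400), (800, 900)], "r1")
        r2 = mk([(50, 150), (820, 870)], "r2")
        a = consensus_replicates(r1, r2)
        b = consensus_replicates(r2, r1)
        assert [(p.start, p.end) for p in a.peaks] == [(p.start, p.end) for p in b.peaks]

    def test_identical_labels_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            consensus_replicates(mk([(0, 10)], "r"), mk([(5, 15)], "r"))

    def test_planted_shared_plus_distractors(self):
        # 300 shared slots + 50 rep1-only + 50 rep2-only, none cross-overlapping
        shared = [(i * 1000, i * 1000 + 200) for i in range(300)]
        only1 = [(400_000 + i * 1000, 400_000 + i * 1000 + 200) for i in range(50)]
        only2 = [(600_000 + i * 1000, 600_000 + i * 1000 + 200) for i in range(50)]
        r1 = mk(shared + only1, "r1")
        r2 = mk([(s + 30, e + 30) for s, e in shared] + only2, "r2")
        cs = consensus_replicates(r1, r2)
        assert len(cs.peaks) == 300

    def test_summit_from_higher_score_member(self):
        r1 = mk([(100, 200)], "r1", score=[5.0])
        r2 = mk([(150, 250)], "r2", score=[9.0])
        cs = consensus_replicates(r1, r2)
        assert cs.peaks[0].summit == (150 + 250) // 2
        assert cs.peaks[0].reads == 10  # max of member read counts


class TestFilterPeaks:
    def test_read_threshold_strictly_greater(self):
        ps = PeakSet(
            [
                Peak(GenomicInterval("c", 0, 10), 5, 0, 1000, "s", "keep"),
                Peak(GenomicInterval("c", 20, 30), 25, 0, 1001, "s", "drop"),
            ]
        )
        out = filter_peaks(ps, None, max_reads=1000)
        assert [p.name for p in out] == ["keep"]

    def test_blacklist_overlap_removed(self):
        ps = mk([(100, 200), (500, 600)], "s")
        bl = mk([(120, 130)], "bl")
        assert [(p.start, p.end) for p in filter_peaks(ps, bl)] == [(500, 600)]

    def test_identity_without_criteria(self):
        ps = mk([(0, 10), (50, 60)], "s", reads=5)
        assert len(filter_peaks(ps, PeakSet([]), 1000)) == 2


def consensus_of(intervals, factor="TP53", condition="untreated"):
    return ConsensusSet(factor, condition, mk(intervals, f"{factor}_{condition}"))


class TestPooling:
    def test_same_site_three_conditions(self):
        sets = [consensus_of([(100, 200)], condition=c)
                for c in ("untreated", "adriamycin", "cisplatin")]
        pooled = pool_conditions(sets)
        assert len(pooled.sites) == 1
        assert pooled.membership.iloc[0].all()

    def test_disjoint_sites_one_flag_each(self):
        sets = [
            consensus_of([(100, 200)], condition="untreated"),
            consensus_of([(500, 600)], condition="adriamycin"),
            consensus_of([(900, 1000)], condition="cisplatin"),
        ]
        pooled = pool_conditions(sets)
        assert len(pooled.sites) == 3
        assert (pooled.membership.sum(axis=1) == 1).all()

    def test_mixed_factors_rejected(self):
        with pytest.raises(ValueError, match="factor"):
            pool_conditions([consensus_of([(0, 10)], factor="TP53"),
                             consensus_of([(20, 30)], factor="TP63")])

    def test_planted_seven_region_venn(self):
        # one site per membership pattern of the 3-condition Venn
        patterns = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1),
                    (0, 1, 1), (1, 1, 1)]
        per_cond = {c: [] for c in ("untreated", "adriamycin", "cisplatin")}
        for i, pat in enumerate(patterns):
            iv = (i * 10_000, i * 10_000 + 300)
            for flag, cond in zip(pat, per_cond):
                if flag:
                    per_cond[cond].append(iv)
        sets = [consensus_of(ivs, condition=c) for c, ivs in per_cond.items()]
        pooled = pool_conditions(sets)
        venn = condition_venn(pooled)
        assert len(pooled.sites) == 7
        assert all(venn[tuple(bool(x) for x in pat)] == 1 for pat in patterns)

    def test_pooled_partition_against_other_factor(self):
        a = pool_conditions([consensus_of([(0, 100), (500, 600), (900, 1000)])])
        b = pool_conditions(
            [consensus_of([(50, 150)], factor="TP63")]
        )
        assert len(subtract(a.sites, b.sites)) + len(overlapping(a.sites, b.sites)) == len(a.sites)


class TestUniqueSites:
    def test_empty_b_identity(self):
        a = pool_conditions([consensus_of([(0, 100), (500, 600)])])
        b = pool_conditions([ConsensusSet("TP63", "untreated", PeakSet([]))])
        out = unique_sites(a, b, [PeakSet([])])
        assert len(out["non_overlapping"]) == 2
        assert len(out["strict_unique"]) == 2

    def test_replicate_only_overlap_blocks_strict(self):
        a = pool_conditions([consensus_of([(0, 100), (500, 600)])])
        b = pool_conditions([ConsensusSet("TP63", "untreated", PeakSet([]))])
        raw_b = [mk([(520, 580)], "TP63_rep1")]
        out = unique_sites(a, b, raw_b)
        assert [(p.start, p.end) for p in out["non_overlapping"]] == [(0, 100), (500, 600)]
        assert [(p.start, p.end) for p in out["strict_unique"]] == [(0, 100)]


class TestDamageClasses:
    def test_examples_and_planted_sizes(self):
        # planted: 40 adr-only, 10 cis-only, 60 shared-damage, 20 constitutive
        adr_only = [(i * 1000, i * 1000 + 200) for i in range(40)]
        cis_only = [(100_000 + i * 1000, 100_000 + i * 1000 + 200) for i in range(10)]
        shared = [(200_000 + i * 1000, 200_000 + i * 1000 + 200) for i in range(60)]
        consti = [(400_000 + i * 1000, 400_000 + i * 1000 + 200) for i in range(20)]
        unt = consensus_of(consti, condition="untreated")
        adr = consensus_of(adr_only + shared + consti, condition="adriamycin")
        cis = consensus_of(cis_only + shared + consti, condition="cisplatin")
        out = damage_induced_classes(unt, adr, cis)
        assert len(out["adr_only"]) == 40
        assert len(out["cis_only"]) == 10
        assert len(out["shared_damage"]) == 60

    def test_constitutive_site_in_no_class(self):
        unt = consensus_of([(0, 100)], condition="untreated")
        adr = consensus_of([(0, 100)], condition="adriamycin")
        cis = consensus_of([(10, 110)], condition="cisplatin")
        out = damage_induced_classes(unt, adr, cis)
        assert all(len(v) == 0 for v in out.values())

    def test_outputs_pairwise_disjoint(self):
        unt = consensus_of([], condition="untreated")
        adr = consensus_of([(0, 100), (500, 600)], condition="adriamycin")
        cis = consensus_of([(50, 150), (900, 1000)], condition="cisplatin")
        out = damage_induced_classes(unt, adr, cis)
        names = [
            (p.start, p.end) for v in out.values() for p in v
        ]
        assert len(names) == len(set(names))
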
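"""Generator determinism, planted structure and noiseless recovery."""

import numpy as np
import pandas as pd
import pytest

from p53cistrome.annotate import read_genes_bed
from p53cistrome.consensus import (
    CONDITIONS,
    consensus_replicates,
    damage_induced_classes,
    filter_peaks,
    pool_conditions,
    unique_sites,
)
from p53cistrome.diffcount import read_count_table
from p53cistrome.expression import (
    classify_response,
    filter_expressed,
    fold_changes,
    read_expression,
)
from p53cistrome.intervals import read_peaks
from p53cistrome.motif import scan_p53_sites
from p53cistrome.simulate import (
    FACTORS,
    TruthConfig,
    make_cistromes,
    make_expression,
    make_genome,
    simulate_all,
    site_recovery,
)

TP53_FAMILY = ("shared", "tp53_only", "tp53_tp63reponly")
TP63_FAMILY = ("shared", "tp63_only", "tp63_tp53reponly")


def build_consensus(cfg, genome, cist):
    cons, raw = {}, {f: [] for f in FACTORS}
    for f in FACTORS:
        for cond in CONDITIONS:
            reps = []
            for r in (1, 2):
                ps = filter_peaks(cist.peaks[(f, cond, r)], cist.blacklist, 1000)
                reps.append(ps)
                raw[f].append(ps)
            cons[(f, cond)] = consensus_replicates(reps[0], reps[1], f, cond)
    pooled = {f: pool_conditions([cons[(f, c)] for c in CONDITIONS]) for f in FACTORS}
    return cons, pooled, raw


class TestGenome:
    def test_deterministic_per_seed(self, small_cfg):
        g1 = make_genome(small_cfg)
        g2 = make_genome(small_cfg)
        assert g1.sequences == g2.sequences
        assert g1.sites.equals(g2.sites)

    def test_genes_non_overlapping_within_bounds(self, small_cfg):
        g = make_genome(small_cfg)
        by_chrom = {}
        for gene in g.genes:
            assert 0 <= gene.start < gene.end <= g.chrom_sizes[gene.chrom]
            by_chrom.setdefault(gene.chrom, []).append((gene.start, gene.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_planted_motifs_scannable(self, small_cfg):
        g = make_genome(small_cfg)
        genuine = g.sites[g.sites.site_class.isin(set(TP53_FAMILY) | set(TP63_FAMILY))]
        for _, row in genuine.head(25).iterrows():
            window = g.sequences[row.chrom][row.summit - 30 : row.summit + 30]
            hits = scan_p53_sites(window)
            assert any(h.kind == "full_site" for h in hits)

    def test_infeasible_layout_rejected(self, small_cfg):
        small_cfg.chrom_sizes = {"chr1": 60_000}
        with pytest.raises(ValueError):
            make_genome(small_cfg)


@pytest.fixture(scope="module")
def run():
    cfg = TruthConfig(
        seed=7,
        chrom_sizes={"chr1": 770_000, "chr2": 770_000, "chr3": 770_000},
        n_genes=40, n_shared=40, n_tp53_only=24, n_tp63_only=36,
        n_tp53_tp63reponly=8, n_tp63_tp53reponly=8, n_rep_only=6,
        n_blacklist_artifact=4, n_highread_artifact=4,
        n_induced=8, n_repressed=6, n_tp63_maintained=4, n_undetected=4,
        jitter_sd=0.0, dropout=0.0, expr_noise_sd=0.0,
    )
    genome = make_genome(cfg)
    cist = make_cistromes(cfg, genome)
    cons, pooled, raw = build_consensus(cfg, genome, cist)
    return cfg, genome, cist, cons, pooled, raw


class TestNoiselessRecovery:
    def test_pooled_cistromes_exact(self, run):
        _, genome, _, _, pooled, _ = run
        ts = genome.sites
        for factor, fam in (("TP53", TP53_FAMILY), ("TP63", TP63_FAMILY)):
            truth = ts[ts.site_class.isin(fam)]
            assert len(pooled[factor].sites) == len(truth)
            assert site_recovery(truth, pooled[factor].sites) == (1.0, 1.0)

    def test_artifacts_absent_after_filtering(self, run):
        _, genome, _, _, pooled, _ = run
        arts = genome.sites[genome.sites.site_class.isin(
            ("blacklist_artifact", "highread_artifact"))]
        recall, _ = site_recovery(arts, pooled["TP53"].sites)
        assert recall == 0.0

    def test_strict_unique_recovers_planted_class(self, run):
        _, genome, _, _, pooled, raw = run
        ts = genome.sites
        out = unique_sites(pooled["TP53"], pooled["TP63"], raw["TP63"])
        truth_only = ts[ts.site_class == "tp53_only"]
        # the replicate-only TP63 overlap class is excluded from strict_unique
        assert len(out["non_overlapping"]) == len(truth_only) + (
            ts.site_class == "tp53_tp63reponly"
        ).sum()
        assert len(out["strict_unique"]) == len(truth_only)
        assert site_recovery(truth_only, out["strict_unique"]) == (1.0, 1.0)

    def test_damage_classes_exact(self, run):
        _, genome, _, cons, _, _ = run
        out = damage_induced_classes(
            cons[("TP53", "untreated")],
            cons[("TP53", "adriamycin")],
            cons[("TP53", "cisplatin")],
        )
        ts = genome.sites[genome.sites.site_class.isin(TP53_FAMILY)]
        for key, timing in (("adr_only", "adr_only"), ("cis_only", "cis_only"),
                            ("shared_damage", "shared_damage")):
            truth = ts[ts.tp53_timing == timing]
            assert len(out[key]) == len(truth)
            assert site_recovery(truth, out[key]) == (1.0, 1.0)

    def test_expression_classes_exact(self, run):
        cfg, genome, _, _, _, _ = run
        em, truth = make_expression(cfg, genome)
        em_f, removed = filter_expressed(em)
        assert set(removed) == set(truth.index[truth.role == "undetected"])
        cls = classify_response(fold_changes(em_f))
        both = ["adriamycin", "cisplatin"]
        ind = set(cls.category.index[(cls.category[both] == "induced").all(axis=1)
                                     & cls.tp53_dependent[both].all(axis=1)])
        rep = set(cls.category.index[(cls.category[both] == "repressed").all(axis=1)
                                     & cls.tp53_dependent[both].all(axis=1)])
        assert ind == set(truth.index[truth.role == "induced"])
        assert rep == set(truth.index[truth.role == "repressed"])
        down = set(cls.tp63_sensitive.index[cls.tp63_sensitive == "down_on_siTP63"])
        assert down == set(truth.index[truth.role == "tp63_maintained"])


class TestEmittedFiles:
    def test_files_parse_through_readers(self, small_cfg_noiseless, tmp_path):
        files = simulate_all(small_cfg_noiseless, tmp_path)
        ps = read_peaks(files["peaks/TP53_untreated_rep1"], format="narrowPeak")
        assert len(ps) > 0
        bl = read_peaks(files["blacklist"], format="bed")
        assert len(bl) == small_cfg_noiseless.n_blacklist_artifact
        genes = read_genes_bed(files["genes"])
        assert len(genes) == small_cfg_noiseless.n_genes
        table = read_count_table(files["counts"])
        assert table.counts.shape[1] == 6
        em = read_expression(files["expression"], files["detection"])
        assert em.values.shape == (small_cfg_noiseless.n_genes, 12)

    def test_fasta_bytes_deterministic(self, small_cfg, tmp_path):
        f1 = simulate_all(small_cfg, tmp_path / "a")
        f2 = simulate_all(small_cfg, tmp_path / "b")
        assert f1["genome"].read_bytes() == f2["genome"].read_bytes()
        assert f1["expression"].read_bytes() == f2["expression"].read_bytes()


class TestNoisyRecovery:
    def test_pooled_recall_with_default_noise(self, small_cfg):
        # jitter sd 20 bp, dropout 0.05 (the configured defaults)
        recalls = []
        for seed in range(3):
            small_cfg.seed = seed
            genome = make_genome(small_cfg)
            cist = make_cistromes(small_cfg, genome)
            _, pooled, _ = build_consensus(small_cfg, genome, cist)
            truth = genome.sites[genome.sites.site_class.isin(TP53_FAMILY)]
            recalls.append(site_recovery(truth, pooled["TP53"].sites)[0])
        assert np.mean(recalls) >= 0.9
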
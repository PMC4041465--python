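"""Synthetic genome, cistromes, counts, tracks and expression with ground truth.

The generator emulates the study design the pipeline targets: two ChIP
replicates per factor (TP53, TP63) per condition (untreated, adriamycin,
cisplatin), site classes shared / TP53-only / TP63-only crossed with
constitutive / damage-induced timing, overdispersed per-site read counts
with condition effects, and a 12-condition expression matrix (four siRNA
series x three treatments) with planted TP53-dependent induced/repressed
genes located near planted sites.  Every emitted peak, count and expression
value is traceable to a machine-readable truth table, so each pipeline
stage can be scored against planted truth.

Layout: genes and binding sites are placed on a slot grid (non-overlapping
site windows), full p53 response elements are written into the genome
sequence at every genuine site summit, and per-replicate peak calls are
jittered and dropped out according to the configuration.  Replicate-only
distractor peaks (present in a single replicate, hence removed by the
consensus step), blacklist artifacts and spurious high-read peaks are
planted to exercise the filtering stages.

Counts are negative-binomial although the differential test downstream is
an exact conditional binomial — a deliberate stress on the test's
robustness to overdispersion.  All randomness flows through
``numpy.random.default_rng`` seeded from the configuration, so outputs are
byte-identical per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneRecord, write_genes_bed
from .consensus import CONDITIONS
from .coverage import SignalTrack, write_bedgraph
from .diffcount import SiteCountTable, write_count_table
from .expression import SIRNAS, TREATMENTS, ExpressionMatrix, write_expression
from .intervals import GenomicInterval, Peak, PeakSet, write_peaks

__all__ = [
    "TruthConfig",
    "SyntheticGenome",
    "CistromeData",
    "make_genome",
    "make_cistromes",
    "make_expression",
    "simulate_all",
    "site_recovery",
]

FACTORS = ("TP53", "TP63")

# truth site classes
TP53_CLASSES = ("shared", "tp53_only", "tp53_tp63reponly")
TP63_CLASSES = ("shared", "tp63_only", "tp63_tp53reponly")

_TP53_TIMING_CONDS = {
    "constitutive": {"untreated", "adriamycin", "cisplatin"},
    "adr_only": {"adriamycin"},
    "cis_only": {"cisplatin"},
    "shared_damage": {"adriamycin", "cisplatin"},
}
_TP63_TIMING_CONDS = {
    "constitutive": {"untreated", "adriamycin", "cisplatin"},
    "untreated_cis": {"untreated", "cisplatin"},
    "untreated_only": {"untreated"},
}


@dataclass
class TruthConfig:
    """Generator configuration; the defaults define the study conditions."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_750_000, "chr2": 2_750_000, "chr3": 2_750_000}
    )
    # genes / regulatory blocks
    n_genes: int = 150
    gene_length: tuple[int, int] = (1000, 3000)
    block_size: int = 55_000
    # site class counts
    n_shared: int = 200
    n_tp53_only: int = 120
    n_tp63_only: int = 180
    n_tp53_tp63reponly: int = 30  # TP53 consensus + one-replicate TP63 peak
    n_tp63_tp53reponly: int = 30  # TP63 consensus + one-replicate TP53 peak
    n_rep_only: int = 25  # per factor: single-replicate distractors
    n_blacklist_artifact: int = 8
    n_highread_artifact: int = 8
    # timing mix
    tp53_timing: dict[str, float] = field(
        default_factory=lambda: {
            "constitutive": 0.30,
            "adr_only": 0.05,
            "cis_only": 0.25,
            "shared_damage": 0.40,
        }
    )
    tp63_timing: dict[str, float] = field(
        default_factory=lambda: {
            "constitutive": 0.60,
            "untreated_cis": 0.30,
            "untreated_only": 0.10,
        }
    )
    # replicate noise
    jitter_sd: float = 20.0
    dropout: float = 0.05
    peak_halfwidth: int = 150
    sites_per_block: int = 4
    # count model
    nb_mean: float = 150.0
    nb_dispersion: float = 0.2
    unbound_mean: float = 8.0
    condition_effect: dict[str, float] = field(
        default_factory=lambda: {"untreated": 1.0, "adriamycin": 1.2, "cisplatin": 1.5}
    )
    tp63_condition_effect: dict[str, float] = field(
        default_factory=lambda: {"untreated": 1.0, "adriamycin": 0.6, "cisplatin": 0.8}
    )
    artifact_reads: int = 3000
    # expression model
    n_induced: int = 30
    n_repressed: int = 30
    n_tp63_maintained: int = 20
    n_undetected: int = 10
    effect_fold: float = 2.5
    tp63_effect_fold: float = 2.0
    expr_noise_sd: float = 0.1  # log2 scale
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.dropout < 0 or self.dropout > 1:
            raise ValueError("dropout must lie in [0, 1]")
        if self.effect_fold <= 1 or self.tp63_effect_fold <= 1:
            raise ValueError("effect sizes must be > 1")
        for frac in (self.tp53_timing, self.tp63_timing):
            if abs(sum(frac.values()) - 1.0) > 1e-9:
                raise ValueError("timing fractions must sum to 1")


@dataclass
class SyntheticGenome:
    """Sequences, gene models and the planted site truth table."""

    sequences: dict[str, str]
    chrom_sizes: dict[str, int]
    genes: list[GeneRecord]
    sites: pd.DataFrame  # site_id, chrom, summit, site_class, tp53_timing, tp63_timing


@dataclass
class CistromeData:
    """Per-replicate peak calls, blacklist, count table and signal tracks."""

    peaks: dict[tuple[str, str, int], PeakSet]  # (factor, condition, replicate)
    blacklist: PeakSet
    counts: SiteCountTable
    tracks: dict[tuple[str, str, int], SignalTrack]


def _counts_from_fractions(n: int, fractions: dict[str, float]) -> list[str]:
    """Deterministic class labels for n items honouring the given mix."""
    keys = list(fractions)
    raw = np.array([fractions[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    labels: list[str] = []
    for k, c in zip(keys, base):
        labels.extend([k] * int(c))
    return labels


def _random_re_instance(rng: np.random.Generator) -> str:
    """A concrete full p53 response element (two decamers, spacer 0)."""
    pick = lambda s: s[rng.integers(len(s))]
    half = lambda: "".join(
        pick(c) for c in ("AG", "AG", "AG", "C", "AT", "AT", "G", "CT", "CT", "CT")
    )
    return half() + half()


def make_genome(cfg: TruthConfig) -> SyntheticGenome:
    """Random genome with genes and motif-bearing sites in isolated blocks.

    The genome is partitioned into ``block_size`` regulatory blocks, one
    gene at each block centre.  Genuine binding sites of a single class
    family (TP53-containing, TP63-containing, or shared) are placed within
    +/- ~17.5 kb of their block's gene, and blocks are wide enough that the
    25-kb annotation window of one gene can never reach another block's
    sites — so each gene has a well-defined planted binding category.
    Distractor classes (single-replicate peaks, blacklist and high-read
    artifacts) are spread across all blocks; they vanish during consensus
    building or filtering and do not contribute categories.
    """
    for chrom, size in cfg.chrom_sizes.items():
        if size < 50_000:
            raise ValueError(f"{chrom}: chromosome must be >= 50 kb")
    rng = np.random.default_rng(cfg.seed)
    bases = np.array(list("ACGT"))
    seqs = {
        c: bases[rng.integers(0, 4, size=n)]  # char array; joined after planting
        for c, n in cfg.chrom_sizes.items()
    }

    blocks = [
        (chrom, start)
        for chrom, size in cfg.chrom_sizes.items()
        for start in range(0, size - cfg.block_size + 1, cfg.block_size)
    ]
    if len(blocks) < cfg.n_genes:
        raise ValueError(
            f"only {len(blocks)} blocks of {cfg.block_size} bp for {cfg.n_genes} genes"
        )
    blocks = blocks[: cfg.n_genes]

    # genes at block centres, random length and strand
    genes: list[GeneRecord] = []
    for gi, (chrom, bstart) in enumerate(blocks):
        length = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
        centre = bstart + cfg.block_size // 2
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(f"gene_{gi:04d}", chrom, centre - length // 2,
                       centre - length // 2 + length, strand)
        )

    # block types sized to the genuine site classes
    spb = cfg.sites_per_block
    groups = {
        "both": [("shared", cfg.n_shared)],
        "tp53": [("tp53_only", cfg.n_tp53_only),
                 ("tp53_tp63reponly", cfg.n_tp53_tp63reponly)],
        "tp63": [("tp63_only", cfg.n_tp63_only),
                 ("tp63_tp53reponly", cfg.n_tp63_tp53reponly)],
    }
    n_blocks_needed = {
        t: -(-sum(c for _, c in plan) // spb) for t, plan in groups.items()
    }
    if sum(n_blocks_needed.values()) > cfg.n_genes:
        raise ValueError("site classes do not fit the gene blocks; lower site counts")
    block_ids = rng.permutation(cfg.n_genes)
    block_type = {}
    cursor = 0
    for t in ("both", "tp53", "tp63"):
        for b in block_ids[cursor : cursor + n_blocks_needed[t]]:
            block_type[int(b)] = t
        cursor += n_blocks_needed[t]
    for b in block_ids[cursor:]:
        block_type[int(b)] = "empty"

    # candidate summit slots per block: symmetric around the gene centre,
    # 1.25-kb apart, between 2.5 and 17.5 kb out (inside the 25-kb window)
    offsets = [d * s for d in range(2500, 18000, 1250) for s in (-1, 1)]
    free_slots: dict[int, list[int]] = {}
    for b, (chrom, bstart) in enumerate(blocks):
        centre = bstart + cfg.block_size // 2
        slots = [centre + o for o in offsets]
        free_slots[b] = list(rng.permutation(slots))

    rows = []
    k = 0

    def place(cls: str, block: int) -> None:
        nonlocal k
        if not free_slots[block]:
            raise ValueError(f"block {block} ran out of site slots")
        summit = int(free_slots[block].pop())
        chrom = blocks[block][0]
        rows.append(
            {"site_id": f"site_{k:04d}", "chrom": chrom, "summit": summit,
             "site_class": cls, "block_gene": genes[block].gene_id}
        )
        k += 1

    for t, plan in groups.items():
        tblocks = sorted(b for b, bt in block_type.items() if bt == t)
        i = 0
        for cls, count in plan:
            for _ in range(count):
                place(cls, tblocks[i % len(tblocks)])
                i += 1
    distractors = (
        [("tp53_reponly", cfg.n_rep_only), ("tp63_reponly", cfg.n_rep_only),
         ("blacklist_artifact", cfg.n_blacklist_artifact),
         ("highread_artifact", cfg.n_highread_artifact)]
    )
    all_blocks = sorted(free_slots)
    i = 0
    for cls, count in distractors:
        for _ in range(count):
            while not free_slots[all_blocks[i % len(all_blocks)]]:
                i += 1
            place(cls, all_blocks[i % len(all_blocks)])
            i += 1
    sites = pd.DataFrame(rows)

    # timing labels (rng-shuffled so timing is not confounded with position)
    sites["tp53_timing"] = ""
    sites["tp63_timing"] = ""
    tp53_idx = sites.index[sites.site_class.isin(TP53_CLASSES)]
    labels53 = _counts_from_fractions(len(tp53_idx), cfg.tp53_timing)
    sites.loc[tp53_idx, "tp53_timing"] = rng.permutation(labels53)
    tp63_idx = sites.index[sites.site_class.isin(TP63_CLASSES)]
    labels63 = _counts_from_fractions(len(tp63_idx), cfg.tp63_timing)
    sites.loc[tp63_idx, "tp63_timing"] = rng.permutation(labels63)

    # plant response elements at genuine factor sites (not distractors)
    genuine = sites.site_class.isin(set(TP53_CLASSES) | set(TP63_CLASSES))
    for _, row in sites[genuine].iterrows():
        motif = _random_re_instance(rng)
        s = row.summit - len(motif) // 2
        seqs[row.chrom][s : s + len(motif)] = list(motif)

    sequences = {c: "".join(v) for c, v in seqs.items()}
    return SyntheticGenome(sequences, dict(cfg.chrom_sizes), genes, sites)


def _tp53_bound_in(row: pd.Series, condition: str) -> bool:
    return (
        row.site_class in TP53_CLASSES
        and condition in _TP53_TIMING_CONDS[row.tp53_timing]
    )


def _tp63_bound_in(row: pd.Series, condition: str) -> bool:
    return (
        row.site_class in TP63_CLASSES
        and condition in _TP63_TIMING_CONDS[row.tp63_timing]
    )


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """Negative binomial with variance mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def make_cistromes(cfg: TruthConfig, genome: SyntheticGenome) -> CistromeData:
    """Replicate peak calls, blacklist, count table and tracks from truth."""
    rng = np.random.default_rng(cfg.seed + 1)
    hw = cfg.peak_halfwidth
    jmax = int(3 * cfg.jitter_sd)

    def jitter() -> int:
        if cfg.jitter_sd == 0:
            return 0
        return int(np.clip(round(rng.normal(0, cfg.jitter_sd)), -jmax, jmax))

    peak_sets: dict[tuple[str, str, int], list[Peak]] = {
        (f, c, r): [] for f in FACTORS for c in CONDITIONS for r in (1, 2)
    }

    def emit(factor: str, condition: str, rep: int, row: pd.Series, reads: int) -> None:
        if cfg.dropout > 0 and rng.random() < cfg.dropout:
            return
        start = max(0, row.summit - hw + jitter())
        end = min(genome.chrom_sizes[row.chrom], row.summit + hw + jitter())
        if end - start < 50:
            return
        summit = int(np.clip(row.summit, start, end - 1))
        score = reads * 0.1 + rng.random()
        peak_sets[(factor, condition, rep)].append(
            Peak(
                GenomicInterval(row.chrom, int(start), int(end)),
                summit,
                float(score),
                int(reads),
                f"{factor}_{condition}_rep{rep}",
                row.site_id,
            )
        )

    count_rows: dict[str, dict[str, int]] = {}
    for _, row in genome.sites.iterrows():
        cls = row.site_class
        for condition in CONDITIONS:
            mult = cfg.condition_effect[condition]
            # TP53 emission
            tp53_here = _tp53_bound_in(row, condition) or cls in (
                "blacklist_artifact",
                "highread_artifact",
            ) or (cls == "tp63_tp53reponly" and condition == "untreated")
            if tp53_here:
                reps = (1,) if cls == "tp63_tp53reponly" else (1, 2)
                for rep in reps:
                    if cls == "highread_artifact":
                        reads = cfg.artifact_reads + int(rng.integers(0, 500))
                    else:
                        reads = int(_nb_draw(rng, cfg.nb_mean * mult, cfg.nb_dispersion))
                    emit("TP53", condition, rep, row, reads)
            if cls == "tp53_reponly" and condition == "untreated":
                emit("TP53", condition, 1, row, int(_nb_draw(rng, cfg.nb_mean, cfg.nb_dispersion)))
            # TP63 emission
            if _tp63_bound_in(row, condition):
                mult63 = cfg.tp63_condition_effect[condition]
                for rep in (1, 2):
                    reads = int(_nb_draw(rng, cfg.nb_mean * mult63, cfg.nb_dispersion))
                    emit("TP63", condition, rep, row, max(1, reads))
            if cls == "tp53_tp63reponly" and condition == "untreated":
                emit("TP63", condition, 1, row, int(_nb_draw(rng, cfg.nb_mean, cfg.nb_dispersion)))
            if cls == "tp63_reponly" and condition == "untreated":
                emit("TP63", condition, 1, row, int(_nb_draw(rng, cfg.nb_mean, cfg.nb_dispersion)))
        # per-site counts for the TP53 differential stage
        if cls in TP53_CLASSES:
            crow = {}
            for condition in CONDITIONS:
                bound = _tp53_bound_in(row, condition)
                mean = cfg.nb_mean * cfg.condition_effect[condition] if bound else cfg.unbound_mean
                for rep in (1, 2):
                    crow[f"TP53_{condition}_rep{rep}"] = int(
                        _nb_draw(rng, mean, cfg.nb_dispersion)
                    )
            count_rows[row.site_id] = crow

    peaks = {
        key: PeakSet(plist, label="_".join((key[0], key[1], f"rep{key[2]}")))
        for key, plist in peak_sets.items()
    }

    bl_rows = genome.sites[genome.sites.site_class == "blacklist_artifact"]
    blacklist = PeakSet(
        [
            Peak(
                GenomicInterval(r.chrom, max(0, r.summit - hw - 200), r.summit + hw + 200),
                r.summit,
                0.0,
                0,
                "blacklist",
                f"bl_{i}",
            )
            for i, r in enumerate(bl_rows.itertuples())
        ],
        label="blacklist",
    )

    counts_df = pd.DataFrame.from_dict(count_rows, orient="index").astype(np.int64)
    counts_df.index.name = "site_id"
    lib = pd.Series(
        {s: float(rng.uniform(0.9e7, 1.1e7)) for s in counts_df.columns}
    )
    counts = SiteCountTable(counts_df, lib)

    tracks: dict[tuple[str, str, int], SignalTrack] = {}
    step = 10
    for (factor, condition, rep), ps in peaks.items():
        vals = {
            c: np.zeros(-(-n // step)) for c, n in genome.chrom_sizes.items()
        }
        for p in ps:
            centre = p.summit // step
            width = 30  # 300 bp triangular pile-up
            height = p.reads / 10.0
            for off in range(-width, width + 1):
                i = centre + off
                if 0 <= i < len(vals[p.chrom]):
                    vals[p.chrom][i] += height * (1 - abs(off) / (width + 1))
        lib_size = float(rng.uniform(0.9e7, 1.1e7))
        tracks[(factor, condition, rep)] = SignalTrack(vals, step, lib_size)

    return CistromeData(peaks, blacklist, counts, tracks)


def make_expression(
    cfg: TruthConfig, genome: SyntheticGenome
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression matrix with planted TP53-dependent responses, plus truth.

    Planted induced genes lie within 25 kb of a TP53-containing site,
    repressed and TP63-maintained genes within 25 kb of a TP63-only site,
    mirroring the regulatory architecture the integration stage is meant to
    recover.  Returns the matrix and a per-gene truth table with columns
    ``role`` (induced / repressed / tp63_maintained / null / undetected)
    and ``linked_site``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    sites = genome.sites

    def linked(classes: tuple[str, ...]) -> list[tuple[str, str]]:
        sel = sites[sites.site_class.isin(classes)]
        first = sel.groupby("block_gene", sort=True)["site_id"].first()
        return list(first.items())

    eligible53 = linked(("shared",))  # canonical targets: TP53+TP63 co-bound
    eligible63 = linked(("tp63_only", "tp63_tp53reponly"))

    roles: dict[str, tuple[str, str]] = {}

    def assign(pool: list[tuple[str, str]], n: int, role: str) -> None:
        avail = [t for t in pool if t[0] not in roles]
        if len(avail) < n:
            raise ValueError(f"only {len(avail)} genes eligible for role {role!r}")
        idx = rng.choice(len(avail), size=n, replace=False)
        for i in idx:
            roles[avail[i][0]] = (role, avail[i][1])

    assign(eligible53, cfg.n_induced, "induced")
    assign(eligible63, cfg.n_repressed, "repressed")
    assign(eligible63, cfg.n_tp63_maintained, "tp63_maintained")
    unassigned = [g.gene_id for g in genome.genes if g.gene_id not in roles]
    und = rng.choice(len(unassigned), size=min(cfg.n_undetected, len(unassigned)), replace=False)
    for i in und:
        roles[unassigned[i]] = ("undetected", "")

    genuine = sites[sites.site_class.isin(set(TP53_CLASSES) | set(TP63_CLASSES))]
    fam_by_gene: dict[str, set[str]] = {}
    for _, srow in genuine.iterrows():
        fams = fam_by_gene.setdefault(srow.block_gene, set())
        if srow.site_class in TP53_CLASSES:
            fams.add("TP53")
        if srow.site_class in TP63_CLASSES:
            fams.add("TP63")

    def true_binding(gene_id: str) -> str:
        fams = fam_by_gene.get(gene_id, set())
        if fams == {"TP53", "TP63"}:
            return "both"
        if fams == {"TP53"}:
            return "TP53-only"
        if fams == {"TP63"}:
            return "TP63-only"
        return "none"

    cols = pd.MultiIndex.from_tuples(
        [(s, t) for s in SIRNAS for t in TREATMENTS], names=["sirna", "treatment"]
    )
    gene_ids = [g.gene_id for g in genome.genes]
    values = pd.DataFrame(0.0, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    detection = pd.DataFrame(0.0, index=values.index, columns=cols)
    truth_rows = []
    for g in genome.genes:
        role, linked_site = roles.get(g.gene_id, ("null", ""))
        if role == "undetected":
            base = float(rng.uniform(0.1, 0.6))
        else:
            base = float(2 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd))
        for sirna in SIRNAS:
            for treat in TREATMENTS:
                v = base
                drug = treat != "untreated"
                if role == "induced" and drug and sirna != "siTP53":
                    v *= cfg.effect_fold
                if role == "repressed" and drug and sirna != "siTP53":
                    v /= cfg.effect_fold
                if role == "tp63_maintained" and sirna == "siTP63":
                    v /= cfg.tp63_effect_fold
                if cfg.expr_noise_sd > 0:
                    v *= 2 ** rng.normal(0, cfg.expr_noise_sd)
                values.loc[g.gene_id, (sirna, treat)] = v
                detection.loc[g.gene_id, (sirna, treat)] = float(
                    rng.uniform(0.2, 0.9) if role == "undetected" else rng.uniform(0, 0.04)
                )
        truth_rows.append(
            {"gene_id": g.gene_id, "role": role, "linked_site": linked_site,
             "true_binding": true_binding(g.gene_id)}
        )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return ExpressionMatrix(values, detection), truth


def simulate_all(cfg: TruthConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full generator and write every artifact as plain text files.

    Returns a name -> path manifest of the emitted files.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    genome = make_genome(cfg)
    cist = make_cistromes(cfg, genome)
    expr, gene_truth = make_expression(cfg, genome)
    files: dict[str, Path] = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    files["genome"] = fasta

    sizes = outdir / "chrom.sizes"
    with open(sizes, "w") as fh:
        for chrom in sorted(genome.chrom_sizes):
            fh.write(f"{chrom}\t{genome.chrom_sizes[chrom]}\n")
    files["chrom_sizes"] = sizes

    genes_bed = outdir / "genes.bed"
    write_genes_bed(genome.genes, genes_bed)
    files["genes"] = genes_bed

    bl = outdir / "blacklist.bed"
    write_peaks(cist.blacklist, bl, format="bed")
    files["blacklist"] = bl

    for (factor, condition, rep), ps in sorted(cist.peaks.items()):
        p = outdir / "peaks" / f"{factor}_{condition}_rep{rep}.narrowPeak"
        write_peaks(ps, p, format="narrowPeak")
        files[f"peaks/{factor}_{condition}_rep{rep}"] = p

    for (factor, condition, rep), track in sorted(cist.tracks.items()):
        p = outdir / "tracks" / f"{factor}_{condition}_rep{rep}.bedGraph"
        write_bedgraph(track, p)
        files[f"tracks/{factor}_{condition}_rep{rep}"] = p
    lib_tsv = outdir / "tracks" / "library_sizes.tsv"
    with open(lib_tsv, "w") as fh:
        fh.write("sample\tlibrary_size\n")
        for (factor, condition, rep), track in sorted(cist.tracks.items()):
            fh.write(f"{factor}_{condition}_rep{rep}\t{track.library_size:g}\n")
    files["track_library_sizes"] = lib_tsv

    counts_tsv = outdir / "counts_tp53.tsv"
    write_count_table(cist.counts, counts_tsv)
    files["counts"] = counts_tsv

    expr_tsv = outdir / "expression.tsv"
    write_expression(expr, expr_tsv)
    files["expression"] = expr_tsv
    det_tsv = outdir / "detection.tsv"
    det = expr.detection_p.copy()
    det.columns = [f"{s}:{t}" for s, t in det.columns]
    det.to_csv(det_tsv, sep="\t", index_label="gene_id")
    files["detection"] = det_tsv

    st = outdir / "truth_sites.tsv"
    genome.sites.to_csv(st, sep="\t", index=False)
    files["truth_sites"] = st
    gt = outdir / "truth_genes.tsv"
    gene_truth.to_csv(gt, sep="\t")
    files["truth_genes"] = gt
    return files


def site_recovery(
    truth_sites: pd.DataFrame, recovered: PeakSet, halfwidth: int = 150
) -> tuple[float, float]:
    """(recall, precision) of recovered peaks against a truth-site subset.

    A truth site counts as recovered when some peak overlaps its
    summit +/- ``halfwidth`` window; a recovered peak is a true positive
    when it overlaps some truth window.
    """
    if truth_sites.empty:
        return (1.0, 0.0 if len(recovered) else 1.0)
    windows = {
        c: np.array(sorted(truth_sites.summit[truth_sites.chrom == c]))
        for c in truth_sites.chrom.unique()
    }
    hit_truth = 0
    for _, row in truth_sites.iterrows():
        lo, hi = row.summit - halfwidth, row.summit + halfwidth
        if any(p.chrom == row.chrom and p.start < hi and p.end > lo for p in recovered):
            hit_truth += 1
    tp = 0
    for p in recovered:
        summits = windows.get(p.chrom)
        if summits is None or summits.size == 0:
            continue
        i = np.searchsorted(summits, p.summit)
        cand = [summits[j] for j in (i - 1, i) if 0 <= j < len(summits)]
        if any(p.start < s + halfwidth and p.end > s - halfwidth for s in cand):
            tp += 1
    recall = hit_truth / len(truth_sites)
    precision = tp / len(recovered) if len(recovered) else 1.0
    return recall, precision
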
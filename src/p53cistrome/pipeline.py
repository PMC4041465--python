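"""End-to-end orchestration of the analysis stages.

Stages run in dependency order: simulate (optional) -> consensus ->
annotate -> diff -> expression -> integrate -> motif.  Every stage writes
plain-text outputs into its own subdirectory of ``outdir`` and the run ends
with a JSON manifest listing every file with its SHA-256 checksum, the
parameter values and the seed — two runs with identical config produce
identical manifests.  A stage failure aborts the run with the stage named;
partial outputs of the failing stage are moved under ``failed/``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path
from typing import Any

import pandas as pd
from pyfaidx import Fasta

from . import __version__
from .annotate import annotate_peaks, read_genes_bed, stratify_by_distance
from .consensus import (
    CONDITIONS,
    condition_venn,
    consensus_replicates,
    damage_induced_classes,
    filter_peaks,
    pool_conditions,
    unique_sites,
    write_membership_table,
)
from .diffcount import differential_sites, read_count_table
from .expression import classify_response, filter_expressed, fold_changes, read_expression
from .integrate import gene_binding_categories, network_summary
from .intervals import read_peaks, write_peaks
from .motif import extract_windows, motif_coverage
from .simulate import FACTORS, TruthConfig, simulate_all

log = logging.getLogger("p53cistrome")


class ConfigurationError(ValueError):
    """Invalid or incomplete pipeline configuration."""


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": True,
    "window": 25000,
    "induce_threshold": 1.7,
    "depend_threshold": 1.5,
    "fdr": 0.1,
    "max_reads": 1000,
    "flank": 5000,
    "bin": 50,
    "motif_width": 500,
    "motif_max_peaks": 5000,
    "spacer_min": 0,
    "spacer_max": 13,
    "simulate_params": {},
    "inputs": {},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, what: str) -> Path:
    if not Path(path).exists():
        raise ConfigurationError(f"missing input for {what}: {path}")
    return Path(path)


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to disk)."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stage = "configure"
    try:
        if cfg["simulate"]:
            stage = "simulate"
            log.info("stage %s", stage)
            tc = TruthConfig(seed=seed, **cfg["simulate_params"])
            simulate_all(tc, outdir / "simulated")
            inputs = {
                "peaks_dir": outdir / "simulated" / "peaks",
                "blacklist": outdir / "simulated" / "blacklist.bed",
                "genes": outdir / "simulated" / "genes.bed",
                "genome": outdir / "simulated" / "genome.fa",
                "counts": outdir / "simulated" / "counts_tp53.tsv",
                "expression": outdir / "simulated" / "expression.tsv",
                "detection": outdir / "simulated" / "detection.tsv",
            }
        else:
            inputs = {k: Path(v) for k, v in cfg["inputs"].items()}
        for key in ("peaks_dir", "blacklist", "genes", "genome", "counts", "expression", "detection"):
            if key not in inputs:
                raise ConfigurationError(f"config inputs lack required key {key!r}")
            _require(inputs[key], key)

        stage = "consensus"
        log.info("stage %s", stage)
        cons_dir = outdir / "consensus"
        cons_dir.mkdir(exist_ok=True)
        blacklist = read_peaks(inputs["blacklist"], format="bed")
        consensus_sets: dict[tuple[str, str], Any] = {}
        raw_samples: dict[str, list] = {f: [] for f in FACTORS}
        for factor in FACTORS:
            for condition in CONDITIONS:
                reps = []
                for rep in (1, 2):
                    p = _require(
                        Path(inputs["peaks_dir"]) / f"{factor}_{condition}_rep{rep}.narrowPeak",
                        f"{factor} {condition} replicate {rep} peaks",
                    )
                    ps = read_peaks(p, format="narrowPeak")
                    ps = filter_peaks(ps, blacklist, max_reads=int(cfg["max_reads"]))
                    reps.append(ps)
                    raw_samples[factor].append(ps)
                cs = consensus_replicates(reps[0], reps[1], factor, condition)
                consensus_sets[(factor, condition)] = cs
                write_peaks(cs.peaks, cons_dir / f"{factor}_{condition}_consensus.bed", "bed")
        pooled = {
            f: pool_conditions([consensus_sets[(f, c)] for c in CONDITIONS])
            for f in FACTORS
        }
        for f in FACTORS:
            write_membership_table(pooled[f], cons_dir / f"{f}_pooled_membership.tsv")
            venn = condition_venn(pooled[f])
            with open(cons_dir / f"{f}_condition_venn.tsv", "w") as fh:
                fh.write("\t".join(pooled[f].membership.columns) + "\tcount\n")
                for key in sorted(venn):
                    fh.write("\t".join(str(int(v)) for v in key) + f"\t{venn[key]}\n")
        uniq53 = unique_sites(pooled["TP53"], pooled["TP63"], raw_samples["TP63"])
        uniq63 = unique_sites(pooled["TP63"], pooled["TP53"], raw_samples["TP53"])
        for name, ps in (
            ("TP53_non_overlapping", uniq53["non_overlapping"]),
            ("TP53_strict_unique", uniq53["strict_unique"]),
            ("TP63_non_overlapping", uniq63["non_overlapping"]),
            ("TP63_strict_unique", uniq63["strict_unique"]),
        ):
            write_peaks(ps, cons_dir / f"{name}.bed", "bed")
        damage = damage_induced_classes(
            consensus_sets[("TP53", "untreated")],
            consensus_sets[("TP53", "adriamycin")],
            consensus_sets[("TP53", "cisplatin")],
        )
        for name, ps in damage.items():
            write_peaks(ps, cons_dir / f"TP53_damage_{name}.bed", "bed")

        stage = "annotate"
        log.info("stage %s", stage)
        ann_dir = outdir / "annotate"
        ann_dir.mkdir(exist_ok=True)
        genes = read_genes_bed(_require(inputs["genes"], "gene models"))
        window = int(cfg["window"])
        maps = {}
        for f in FACTORS:
            amap = annotate_peaks(pooled[f].sites, genes, window=window)
            amap.to_tsv(ann_dir / f"{f}_annotation.tsv")
            maps[f] = amap
            strat = stratify_by_distance(pooled[f].sites, genes)
            strat.to_csv(ann_dir / f"{f}_tss_classes.tsv", sep="\t", header=True)

        stage = "diff"
        log.info("stage %s", stage)
        diff_dir = outdir / "diff"
        diff_dir.mkdir(exist_ok=True)
        table = read_count_table(_require(inputs["counts"], "count table"))
        untreated = [c for c in table.counts.columns if "untreated" in c]
        for condition in ("adriamycin", "cisplatin"):
            grp = [c for c in table.counts.columns if condition in c]
            res = differential_sites(table, untreated, grp, fdr=float(cfg["fdr"]))
            res.to_csv(diff_dir / f"TP53_{condition}_vs_untreated.tsv", sep="\t")

        stage = "expression"
        log.info("stage %s", stage)
        expr_dir = outdir / "expression"
        expr_dir.mkdir(exist_ok=True)
        em = read_expression(
            _require(inputs["expression"], "expression matrix"),
            _require(inputs["detection"], "detection p-values"),
        )
        em_f, removed = filter_expressed(em)
        fc = fold_changes(em_f)
        fc_out = fc.copy()
        fc_out.columns = [f"{s}:{t}" for s, t in fc_out.columns]
        fc_out.to_csv(expr_dir / "fold_changes.tsv", sep="\t", index_label="gene_id")
        cls = classify_response(
            fc,
            induce_threshold=float(cfg["induce_threshold"]),
            depend_threshold=float(cfg["depend_threshold"]),
        )
        cls.to_tsv(expr_dir / "classification.tsv")
        with open(expr_dir / "filtered_out.txt", "w") as fh:
            fh.write("\n".join(removed) + ("\n" if removed else ""))

        stage = "integrate"
        log.info("stage %s", stage)
        int_dir = outdir / "integrate"
        int_dir.mkdir(exist_ok=True)
        universe = list(em_f.values.index)
        cats = gene_binding_categories(maps["TP53"], maps["TP63"], pooled["TP53"], genes=universe)
        cats.to_csv(int_dir / "gene_binding_categories.tsv", sep="\t")
        summary, gene_lists = network_summary(cls, cats, universe=universe)
        summary.to_csv(int_dir / "network_summary.tsv", sep="\t", index=False)
        lists_dir = int_dir / "gene_lists"
        lists_dir.mkdir(exist_ok=True)
        for (treat, ecat, bcat), gl in sorted(gene_lists.items()):
            if gl:
                with open(lists_dir / f"{treat}_{ecat}_{bcat}.txt", "w") as fh:
                    fh.write("\n".join(gl) + "\n")

        stage = "motif"
        log.info("stage %s", stage)
        motif_dir = outdir / "motif"
        motif_dir.mkdir(exist_ok=True)
        genome = Fasta(str(_require(inputs["genome"], "genome FASTA")))
        genome_map = {name: str(genome[name]) for name in genome.keys()}
        spacers = range(int(cfg["spacer_min"]), int(cfg["spacer_max"]) + 1)
        rows = []
        peaksets = {f: pooled[f].sites for f in FACTORS}
        peaksets["TP53_strict_unique"] = uniq53["strict_unique"]
        peaksets["TP63_strict_unique"] = uniq63["strict_unique"]
        for name, ps in peaksets.items():
            if not len(ps):
                continue
            windows = extract_windows(
                ps,
                genome_map,
                width=int(cfg["motif_width"]),
                max_peaks=int(cfg["motif_max_peaks"]),
                seed=seed,
            )
            cov = motif_coverage(windows, spacer_range=spacers)
            rows.append(
                {
                    "peakset": name,
                    "n_windows": len(windows),
                    "full_site_fraction": cov["full_site_fraction"],
                    "half_site_fraction": cov["half_site_fraction"],
                    "core_fraction": cov["core_fraction"],
                }
            )
        pd.DataFrame(rows).to_csv(motif_dir / "motif_coverage.tsv", sep="\t", index=False)
    except ConfigurationError:
        raise
    except Exception as exc:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        stage_dir = outdir / stage
        if stage_dir.exists():
            dest = failed / stage
            if dest.exists():
                shutil.rmtree(dest)
            shutil.move(str(stage_dir), str(dest))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "parameters": {
            k: v for k, v in cfg.items() if k not in ("inputs", "simulate_params")
        },
        "simulate_params": cfg["simulate_params"],
        "files": [],
    }
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"].append(
                {"path": str(path.relative_to(outdir)), "sha256": _sha256(path)}
            )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
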
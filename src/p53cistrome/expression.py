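"""siRNA x treatment expression matrices and response classification.

The experimental design crosses four siRNA series (none, scrambled, siTP53,
siTP63) with three treatments (untreated, adriamycin, cisplatin).  Fold
changes are computed per gene against the mean of the two untreated control
samples (no-siRNA and scrambled).  A gene is *induced* by a treatment when
its scrambled-series fold change reaches the induction threshold (default
1.7-fold, inclusive) and *repressed* below the reciprocal.  TP53 dependence
of an induced/repressed gene requires a change in the opposite direction
(default 1.5-fold) when comparing the siTP53 sample with the scrambled
sample under the same treatment.  TP63 sensitivity is read from the
siTP63/controls fold change in untreated cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SIRNAS",
    "TREATMENTS",
    "ExpressionMatrix",
    "ResponseClassification",
    "read_expression",
    "write_expression",
    "filter_expressed",
    "fold_changes",
    "classify_response",
]

SIRNAS = ("none", "scrambled", "siTP53", "siTP63")
TREATMENTS = ("untreated", "adriamycin", "cisplatin")
CONTROL_COLS = [("none", "untreated"), ("scrambled", "untreated")]


@dataclass
class ExpressionMatrix:
    """Genes x conditions expression with optional per-cell detection p-values.

    Columns are a two-level (sirna, treatment) MultiIndex.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError("columns must be a (sirna, treatment) MultiIndex")
        for col in CONTROL_COLS:
            if col not in self.values.columns:
                raise ValueError(f"required control column {col} missing")
        if self.detection_p is not None and not self.detection_p.index.equals(
            self.values.index
        ):
            raise ValueError("detection p-values must share the gene index")


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """TSV with a two-line header: sample ids, then sirna:treatment labels."""
    cols = list(m.values.columns)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(f"s{i}" for i in range(len(cols))) + "\n")
        fh.write("condition\t" + "\t".join(f"{s}:{t}" for s, t in cols) + "\n")
        m.values.to_csv(fh, sep="\t", header=False)


def read_expression(
    path: str | Path, detection_path: str | Path | None = None
) -> ExpressionMatrix:
    with open(path) as fh:
        fh.readline()  # sample ids (informational)
        cond_line = fh.readline().rstrip("\n").split("\t")[1:]
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.split(":")) for c in cond_line], names=["sirna", "treatment"]
        )
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
        df.columns = cols
        df.index.name = "gene_id"
    det = None
    if detection_path is not None:
        det = pd.read_csv(detection_path, sep="\t", index_col=0)
        det.columns = cols
    return ExpressionMatrix(df, det)


def filter_expressed(
    m: ExpressionMatrix, dabg_alpha: float = 0.05, min_expr: float = 1.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes undetected or weakly expressed in every control sample.

    A gene is retained when at least one of the two untreated control
    columns shows both detection (DABG p < ``dabg_alpha``) and expression
    >= ``min_expr``.  Returns the filtered matrix and the removed gene ids.
    """
    if m.detection_p is None:
        raise ValueError("detection p-values required for expression filtering")
    ctrl_vals = m.values[CONTROL_COLS]
    ctrl_det = m.detection_p[CONTROL_COLS]
    ok = ((ctrl_det < dabg_alpha) & (ctrl_vals >= min_expr)).any(axis=1)
    removed = list(m.values.index[~ok])
    return (
        ExpressionMatrix(m.values.loc[ok], m.detection_p.loc[ok]),
        removed,
    )


def fold_changes(m: ExpressionMatrix) -> pd.DataFrame:
    """Linear fold change of every sample vs the mean of the untreated controls."""
    vals = m.values
    if (vals <= 0).any().any():
        raise ValueError("non-positive expression values; filter first")
    baseline = vals[CONTROL_COLS].mean(axis=1)
    return vals.div(baseline, axis=0)


@dataclass
class ResponseClassification:
    """Per-gene expression response categories.

    ``category``: genes x treatments (adriamycin, cisplatin) in
    {induced, repressed, neither}.  ``tp53_dependent``: same shape, True
    only where category != neither and the siTP53 series reverses the
    change.  ``tp63_sensitive``: per gene, one of
    {down_on_siTP63, up_on_siTP63, none}.
    """

    category: pd.DataFrame
    tp53_dependent: pd.DataFrame
    tp63_sensitive: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat(
            {
                "category": self.category,
                "tp53_dependent": self.tp53_dependent.astype(int),
            },
            axis=1,
        )
        out.columns = ["_".join(c) for c in out.columns]
        out["tp63_sensitive"] = self.tp63_sensitive
        out.to_csv(path, sep="\t", index_label="gene_id")


def classify_response(
    fc: pd.DataFrame,
    induce_threshold: float = 1.7,
    depend_threshold: float = 1.5,
) -> ResponseClassification:
    """Classify treatment responses and their TP53/TP63 dependence.

    Works on the fold-change table of :func:`fold_changes`.  Thresholds are
    inclusive: FC exactly at ``induce_threshold`` counts as induced.  The
    dependence ratio siTP53/scrambled equals the ratio of their fold
    changes (shared control denominator).
    """
    if induce_threshold <= 1 or depend_threshold <= 1:
        raise ValueError("thresholds must be > 1")
    drugs = [t for t in TREATMENTS if t != "untreated"]
    for sirna in ("scrambled", "siTP53"):
        for t in drugs:
            if (sirna, t) not in fc.columns:
                raise ValueError(f"missing required column {(sirna, t)}")
    cat = pd.DataFrame("neither", index=fc.index, columns=drugs)
    dep = pd.DataFrame(False, index=fc.index, columns=drugs)
    for t in drugs:
        treat_fc = fc[("scrambled", t)]
        induced = treat_fc >= induce_threshold
        repressed = treat_fc <= 1.0 / induce_threshold
        cat.loc[induced, t] = "induced"
        cat.loc[repressed, t] = "repressed"
        ratio = fc[("siTP53", t)] / fc[("scrambled", t)]
        dep[t] = (induced & (ratio <= 1.0 / depend_threshold)) | (
            repressed & (ratio >= depend_threshold)
        )
    if ("siTP63", "untreated") in fc.columns:
        r63 = fc[("siTP63", "untreated")]
        tp63 = pd.Series("none", index=fc.index)
        tp63[r63 <= 1.0 / depend_threshold] = "down_on_siTP63"
        tp63[r63 >= depend_threshold] = "up_on_siTP63"
    else:
        tp63 = pd.Series("none", index=fc.index)
    tp63.name = "tp63_sensitive"
    return ResponseClassification(cat, dep, tp63)
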
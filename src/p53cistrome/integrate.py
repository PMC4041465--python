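"""Binding x expression integration and genelist-overlap enrichment.

Each gene is assigned a binding category — both, TP53-only, TP63-only or
none — from its 25-kb peak annotations against the two pooled cistromes.
TP53-bound genes are further flagged constitutive (at least one associated
site present in the untreated consensus) and/or damage-induced (at least
one associated site detected only after treatment).  Expression response
classes are then cross-tabulated against binding categories, with the
significance of each cell assessed by the upper-tail hypergeometric test of
genelist overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import AnnotationMap
from .consensus import PooledCistrome
from .expression import ResponseClassification

__all__ = [
    "OverlapTestResult",
    "gene_binding_categories",
    "overlap_enrichment",
    "network_summary",
]

BINDING_CATEGORIES = ("both", "TP53-only", "TP63-only", "none")


@dataclass(frozen=True)
class OverlapTestResult:
    """Upper-tail hypergeometric test of the overlap of two gene lists."""

    universe: int
    size_a: int
    size_b: int
    overlap: int
    pvalue: float


def gene_binding_categories(
    tp53_map: AnnotationMap,
    tp63_map: AnnotationMap,
    tp53_pooled: PooledCistrome,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene binding category and TP53 constitutive/damage flags.

    ``tp53_map`` must be built on the pooled TP53 sites (peak ids matching
    ``tp53_pooled`` site names) so that condition membership can be read
    off.  ``genes`` optionally fixes the output universe; genes absent from
    both maps are categorized ``none``.
    """
    site_names = set(tp53_pooled.membership.index)
    unknown = set(tp53_map.associations["peak_id"]) - site_names
    if unknown:
        raise ValueError(
            f"TP53 annotation references sites missing from the pooled cistrome: "
            f"{sorted(unknown)[:5]}"
        )
    tp53_by_gene = tp53_map.associations.groupby("gene_id")["peak_id"].agg(list)
    tp63_by_gene = tp63_map.associations.groupby("gene_id")["peak_id"].agg(list)
    if genes is None:
        universe = sorted(set(tp53_by_gene.index) | set(tp63_by_gene.index))
    else:
        universe = list(genes)
    if "untreated" not in tp53_pooled.membership.columns:
        raise ValueError("pooled TP53 cistrome lacks an 'untreated' condition flag")
    untreated = tp53_pooled.membership["untreated"]
    rows = []
    for g in universe:
        sites53 = tp53_by_gene.get(g, [])
        sites63 = tp63_by_gene.get(g, [])
        b53, b63 = bool(sites53), bool(sites63)
        if b53 and b63:
            cat = "both"
        elif b53:
            cat = "TP53-only"
        elif b63:
            cat = "TP63-only"
        else:
            cat = "none"
        constitutive = any(untreated[s] for s in sites53)
        damage = any(not untreated[s] for s in sites53)
        rows.append(
            {
                "gene_id": g,
                "binding_category": cat,
                "bound_tp53": b53,
                "bound_tp63": b63,
                "tp53_constitutive": constitutive,
                "tp53_damage_induced": damage,
                "n_tp53_sites": len(sites53),
                "n_tp63_sites": len(sites63),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def overlap_enrichment(
    list_a: Collection[str], list_b: Collection[str], universe: Collection[str]
) -> OverlapTestResult:
    """Hypergeometric upper-tail p for the overlap of two gene lists.

    With N = |universe|, K = |list_a|, n = |list_b| and observed overlap k,
    p = P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated via the
    log-space survival function (exact and stable for large N).
    """
    uni = set(universe)
    a, b = set(list_a), set(list_b)
    if a - uni or b - uni:
        stray = sorted((a | b) - uni)[:5]
        raise ValueError(f"gene list elements outside the universe: {stray}")
    n_uni, k_a, k_b = len(uni), len(a), len(b)
    k = len(a & b)
    # sf(k-1) = P(X >= k); exact for k = 0 (p = 1)
    p = float(stats.hypergeom.sf(k - 1, n_uni, k_a, k_b))
    return OverlapTestResult(n_uni, k_a, k_b, k, min(max(p, 0.0), 1.0))


def network_summary(
    cls: ResponseClassification,
    cats: pd.DataFrame,
    universe: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], list[str]]]:
    """Cross-tabulate expression response x treatment x binding category.

    Returns a table with one row per (treatment, expression category,
    binding category) cell carrying the gene count and the hypergeometric
    enrichment p of that cell's gene list against the binding-category
    list, plus a dict of per-cell gene lists.  The universe defaults to the
    genes shared by the classification and the binding table.
    """
    shared = cls.category.index.intersection(cats.index)
    if universe is None:
        universe = list(shared)
    universe = list(universe)
    uni_set = set(universe)
    rows = []
    gene_lists: dict[tuple[str, str, str], list[str]] = {}
    for treatment in cls.category.columns:
        for expr_cat in ("induced", "repressed"):
            expr_genes = [
                g
                for g in shared
                if cls.category.at[g, treatment] == expr_cat and g in uni_set
            ]
            for bind_cat in BINDING_CATEGORIES:
                bind_genes = [
                    g
                    for g in universe
                    if g in cats.index and cats.at[g, "binding_category"] == bind_cat
                ]
                cell = sorted(set(expr_genes) & set(bind_genes))
                res = overlap_enrichment(expr_genes, bind_genes, universe)
                rows.append(
                    {
                        "treatment": treatment,
                        "expression_category": expr_cat,
                        "binding_category": bind_cat,
                        "n_genes": len(cell),
                        "pvalue": res.pvalue,
                    }
                )
                gene_lists[(treatment, expr_cat, bind_cat)] = cell
    return pd.DataFrame(rows), gene_lists
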
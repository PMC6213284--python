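"""Element-to-gene linkage, differential expression, and class-wise summaries.

Each co-bound element is linked to its single closest gene when that gene
lies within 20 kb (inclusive). Differential expression between two conditions
uses a Welch two-sample test on log2 values with Benjamini-Hochberg FDR
control — a deliberately simple, documented stand-in for a moderated-variance
model; a precomputed DE table can be supplied instead. Linked DE genes are
partitioned into ClassI-only / ClassII-only / Both and summarized as
boxplot-style fold-change distributions per condition. Ranked-list target
enrichment asks how many known target genes fall into the top/bottom k of
genes ranked by fold change, with an upper-tail hypergeometric P.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .binding import CoboundElement
from .formats_io import ExpressionMatrix, GeneModel, nearest_gene_distance

__all__ = [
    "GeneLink",
    "link_elements_to_genes",
    "simple_de",
    "ClassExpressionSummary",
    "class_expression_summary",
    "target_rank_enrichment",
    "boxplot_stats",
]


@dataclass(frozen=True)
class GeneLink:
    element_id: str
    gene_id: str
    distance: int
    class_label: str | None = None


def link_elements_to_genes(
    elements: Sequence[CoboundElement],
    genes: Sequence[GeneModel],
    max_distance: int = 20_000,
) -> list[GeneLink]:
    """Link each element to its closest gene iff the gap is <= max_distance bp.

    The boundary is inclusive; elements without a gene in range yield no link.
    """
    if not genes:
        raise ValueError("gene set is empty")
    links: list[GeneLink] = []
    for el in elements:
        gene_id, dist = nearest_gene_distance(el.region, genes)
        if gene_id is not None and dist is not None and dist <= max_distance:
            links.append(
                GeneLink(
                    element_id=el.element_id,
                    gene_id=gene_id,
                    distance=dist,
                    class_label=el.class_label,
                )
            )
    return links


def simple_de(
    matrix: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Welch-test differential expression between two conditions.

    Returns a DataFrame indexed by gene with columns log2fc (mean a - mean b),
    p_value, fdr (Benjamini-Hochberg over all genes), is_de (fdr <= cutoff).
    """
    a = matrix.condition_values(cond_a)
    b = matrix.condition_values(cond_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >=2 replicates per condition")
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a.values, b.values, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: Welch is undefined; call by the mean difference
    bad = ~np.isfinite(p)
    if bad.any():
        p[bad] = np.where(np.isclose(log2fc.values[bad], 0.0), 1.0, 0.0)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "is_de": fdr <= fdr_cutoff,
        },
        index=matrix.genes,
    )


def boxplot_stats(values: Sequence[float]) -> dict[str, float]:
    """Median/quartiles/1.5-IQR whiskers/outlier count for one distribution."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return {k: float("nan") for k in ("median", "q1", "q3", "lo_whisker", "hi_whisker")} | {
            "n_outliers": 0
        }
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr]
    hi = v[v <= q3 + 1.5 * iqr]
    lo_w = float(lo[0]) if lo.size else float(v[0])
    hi_w = float(hi[-1]) if hi.size else float(v[-1])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "lo_whisker": lo_w,
        "hi_whisker": hi_w,
        "n_outliers": int(np.sum((v < lo_w) | (v > hi_w))),
    }


@dataclass
class ClassExpressionSummary:
    """Fold-change distributions of DE genes linked to one element class."""

    class_label: str  # ClassI-only, ClassII-only, or Both
    n_linked: int
    n_de: int
    per_condition: dict[str, dict[str, float]]  # condition -> boxplot stats of log2fc
    genes: list[str]


def class_expression_summary(
    links: Sequence[GeneLink],
    de: pd.DataFrame,
    matrix: ExpressionMatrix,
    reference: str,
    conditions: Sequence[str] | None = None,
) -> dict[str, ClassExpressionSummary]:
    """Per-class expression summaries of linked differential genes.

    Genes linked to Class I elements only, Class II elements only, or both are
    summarized separately; a gene linked to elements of both classes appears
    only in "Both". Fold changes are per-gene condition means minus the
    reference-condition mean.
    """
    if conditions is None:
        conditions = [c for c in dict.fromkeys(matrix.conditions) if c != reference]
    linked_by_class: dict[str, set[str]] = {"ClassI": set(), "ClassII": set()}
    for link in links:
        if link.class_label in linked_by_class:
            linked_by_class[link.class_label].add(link.gene_id)
    both = linked_by_class["ClassI"] & linked_by_class["ClassII"]
    groups = {
        "ClassI-only": linked_by_class["ClassI"] - both,
        "ClassII-only": linked_by_class["ClassII"] - both,
        "Both": both,
    }
    ref_mean = matrix.condition_mean(reference)
    out: dict[str, ClassExpressionSummary] = {}
    for name, genes in groups.items():
        genes_in = sorted(g for g in genes if g in de.index)
        de_genes = [g for g in genes_in if bool(de.loc[g, "is_de"])]
        per_condition = {}
        for cond in conditions:
            fc = matrix.condition_mean(cond).loc[de_genes] - ref_mean.loc[de_genes]
            per_condition[cond] = boxplot_stats(fc.values)
        out[name] = ClassExpressionSummary(
            class_label=name,
            n_linked=len(genes_in),
            n_de=len(de_genes),
            per_condition=per_condition,
            genes=de_genes,
        )
    return out


def target_rank_enrichment(
    de: pd.DataFrame,
    targets: Iterable[str],
    k_each_tail: int = 400,
) -> tuple[float, float]:
    """Enrichment of a target gene set in the top/bottom k of the fold-change ranking.

    Genes are ranked by log2fc (descending, ties by gene_id); the selection is
    the top k plus the bottom k. Returns (fraction of targets in the
    selection, upper-tail hypergeometric P of seeing at least that many).
    """
    targets = set(targets)
    if not targets:
        raise ValueError("empty target set")
    unknown = targets - set(de.index)
    if unknown:
        raise ValueError(f"targets outside the ranked universe: {sorted(unknown)[:5]}...")
    universe = len(de)
    draws = 2 * k_each_tail
    if draws >= universe:
        raise ValueError("2k must be smaller than the universe")
    # descending fold change, ties broken by gene id for a deterministic selection
    fc = de["log2fc"]
    order = sorted(de.index, key=lambda g: (-fc[g], g))
    selection = set(order[:k_each_tail]) | set(order[-k_each_tail:])
    observed = len(targets & selection)
    fraction = observed / len(targets)
    p = float(stats.hypergeom.sf(observed - 1, universe, len(targets), draws))
    return fraction, p
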
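"""Developmental staging of expression profiles by Pearson correlation.

A query transcriptome is compared against reference epiblast/ectoderm stage
profiles (CAV, PS, ES, MS, LMS, LS, OB/EB, LB in the default embryo panel) by
correlating over the genes that best discriminate successive stages. The gene
restriction ranks genes by a per-gene two-sample Hotelling T-squared score
(univariate form: pooled-variance squared t) maximized over consecutive stage
pairs, keeping the top 500 by default. A moving-average trendline utility for
scatter summaries lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import ExpressionMatrix
from .linkage import boxplot_stats, simple_de

__all__ = [
    "StageProfileSet",
    "StagingResult",
    "pearson",
    "hotelling_rank",
    "select_top_k",
    "stage_samples",
    "updown_marker_summary",
    "moving_average_trend",
]


@dataclass
class StageProfileSet:
    """Ordered reference stages with replicate expression vectors (log2)."""

    stages: list[str]
    values: pd.DataFrame  # genes x samples
    stage_of: pd.Series  # sample -> stage

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("need >=2 stages")
        for stage in self.stages:
            if not (self.stage_of == stage).any():
                raise ValueError(f"stage {stage!r} has no replicates")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def replicates(self, stage: str) -> pd.DataFrame:
        cols = self.stage_of.index[self.stage_of == stage]
        return self.values[cols]

    def stage_means(self) -> pd.DataFrame:
        return pd.DataFrame({s: self.replicates(s).mean(axis=1) for s in self.stages})

    def as_expression_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.values, dict(self.stage_of))


@dataclass
class StagingResult:
    correlation: pd.DataFrame  # samples x stages, Pearson r
    best_stage: pd.Series  # sample -> argmax stage
    gene_subset: list[str]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.dot(xc, yc) / denom)


def hotelling_rank(profiles: StageProfileSet) -> pd.DataFrame:
    """Rank genes by between-stage separation.

    Per gene and per consecutive stage pair, the univariate two-sample
    Hotelling T-squared statistic
    ``T2 = (m1 - m2)^2 / (sp^2 (1/n1 + 1/n2))`` with pooled variance sp^2;
    the gene's score is the maximum over pairs. Zero pooled variance gives 0
    when the means agree and +inf otherwise. Returns a DataFrame sorted by
    score descending (ties by gene_id) with a ``score`` column.
    """
    groups = []
    for stage in profiles.stages:
        reps = profiles.replicates(stage)
        if reps.shape[1] < 2:
            raise ValueError(f"stage {stage!r} has <2 replicates")
        groups.append(reps.values)
    score = np.zeros(len(profiles.genes))
    for g1, g2 in zip(groups[:-1], groups[1:]):
        n1, n2 = g1.shape[1], g2.shape[1]
        m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
        ss1 = np.sum((g1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.sum((g2 - m2[:, None]) ** 2, axis=1)
        sp2 = (ss1 + ss2) / (n1 + n2 - 2)
        diff2 = (m1 - m2) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = diff2 / (sp2 * (1 / n1 + 1 / n2))
        t2 = np.where(sp2 == 0, np.where(diff2 == 0, 0.0, np.inf), t2)
        score = np.maximum(score, t2)
    # stable sort after an index sort gives the gene_id tie-break
    ranked = (
        pd.DataFrame({"score": score}, index=profiles.genes)
        .sort_index()
        .sort_values("score", ascending=False, kind="stable")
    )
    return ranked


def select_top_k(ranked: pd.DataFrame | Sequence[str], k: int = 500) -> list[str]:
    """First min(k, n) genes of a ranked list."""
    if k <= 0:
        raise ValueError("k must be positive")
    ids = list(ranked.index) if isinstance(ranked, pd.DataFrame) else list(ranked)
    if not ids:
        raise ValueError("ranked list is empty")
    return ids[:k]


def stage_samples(
    samples: ExpressionMatrix,
    profiles: StageProfileSet,
    gene_subset: Iterable[str],
) -> StagingResult:
    """Correlate each query sample against every stage's replicate-mean profile.

    Uses only the intersection of ``gene_subset`` with both universes; the
    best stage is the argmax of Pearson r (earliest stage on exact ties).
    """
    subset = [g for g in gene_subset if g in samples.genes and g in profiles.genes.values]
    if len(subset) < 3:
        raise ValueError("gene subset smaller than 3 after intersection")
    means = profiles.stage_means().loc[subset]
    rows = {}
    for sample in samples.samples:
        vec = samples.values.loc[subset, sample].values
        rows[sample] = [pearson(vec, means[s].values) for s in profiles.stages]
    corr = pd.DataFrame(rows, index=profiles.stages).T
    best = corr.idxmax(axis=1)
    return StagingResult(correlation=corr, best_stage=best, gene_subset=subset)


def updown_marker_summary(
    samples: ExpressionMatrix,
    profiles: StageProfileSet,
    early_stages: Sequence[str] = ("CAV", "PS"),
    late_stages: Sequence[str] = ("LMS", "LS"),
    fdr_cutoff: float = 0.05,
) -> dict[str, dict[str, dict[str, float]]]:
    """Distributions of early/late stage-marker genes in each query sample.

    Marker sets are the genes differentially expressed between the pooled
    early and pooled late stage replicates, split by direction: "up" = higher
    in late stages, "down" = lower in late stages. Returns
    {sample: {"up": boxplot stats, "down": boxplot stats}} of the marker
    expression values in that sample.
    """
    for group, name in ((early_stages, "early"), (late_stages, "late")):
        missing = [s for s in group if s not in profiles.stages]
        if missing:
            raise ValueError(f"{name} stages absent from profiles: {missing}")
    cond = {}
    for s in profiles.stage_of.index:
        stage = profiles.stage_of[s]
        if stage in early_stages:
            cond[s] = "early"
        elif stage in late_stages:
            cond[s] = "late"
    pooled = ExpressionMatrix(profiles.values[list(cond)], cond)
    de = simple_de(pooled, "late", "early", fdr_cutoff=fdr_cutoff)
    up = de.index[(de["is_de"]) & (de["log2fc"] > 0)]
    down = de.index[(de["is_de"]) & (de["log2fc"] < 0)]
    out: dict[str, dict[str, dict[str, float]]] = {}
    shared_up = [g for g in up if g in samples.genes]
    shared_down = [g for g in down if g in samples.genes]
    for sample in samples.samples:
        out[sample] = {
            "up": boxplot_stats(samples.values.loc[shared_up, sample].values),
            "down": boxplot_stats(samples.values.loc[shared_down, sample].values),
        }
    return out


def moving_average_trend(
    x: Sequence[float], y: Sequence[float], window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average of y over x-sorted points, truncated at edges.

    Returns (x sorted ascending, trend values). ``window`` must be odd.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("need non-empty equal-length vectors")
    if window < 1 or window % 2 == 0 or window > x.size:
        raise ValueError("window must be odd, >=1 and <= n")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    half = window // 2
    trend = np.array(
        [ys[max(0, i - half) : i + half + 1].mean() for i in range(len(ys))]
    )
    return xs, trend
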
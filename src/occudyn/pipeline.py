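"""End-to-end orchestration: files in, classified elements and reports out.

``run_pipeline`` consumes a bundle directory with a ``manifest.yaml`` (as
written by the synthetic generator, or hand-written for real peak/track
files), executes quantify -> retention/status -> co-bound taxonomy -> gene
linkage -> DE -> class summaries -> enrichment -> staging (when stage
profiles are present) -> motifs (when sequences are present), and writes
every module's table plus a JSON summary report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import binding, linkage, motifs, staging
from .formats_io import (
    read_bed,
    read_bedgraph,
    read_expression_matrix,
    read_fasta,
    read_gene_table,
    write_bed,
)
from .formats_io import GenomicRegion

logger = logging.getLogger("occudyn")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved thresholds and paths; defaults follow the published analysis."""

    bundle_dir: Path
    out_dir: Path
    threshold: float = 0.5  # retention below this is "lost"
    comparator: str = "strict"  # "strict" (< threshold) or "inclusive" (<=)
    max_gene_distance: int = 20_000
    fdr_cutoff: float = 0.05
    top_k_stage_genes: int = 500
    tail_k: int = 400
    seed: int = 0
    run_motifs: bool = True

    def __post_init__(self) -> None:
        if self.comparator not in ("strict", "inclusive"):
            raise ValueError("comparator must be 'strict' or 'inclusive'")
        self.bundle_dir = Path(self.bundle_dir)
        self.out_dir = Path(self.out_dir)

    @property
    def inclusive(self) -> bool:
        return self.comparator == "inclusive"


@dataclass
class PipelineResult:
    tables: dict[str, binding.OccupancyTable]
    elements: list[binding.CoboundElement]
    class_counts: pd.DataFrame
    links: list[linkage.GeneLink]
    de: pd.DataFrame
    class_summaries: dict[str, linkage.ClassExpressionSummary]
    enrichment: tuple[float, float] | None
    staging_result: staging.StagingResult | None
    motif_results: dict[str, list[motifs.KmerResult]] = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def _load_bundle(cfg: PipelineConfig):
    manifest_path = cfg.bundle_dir / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.yaml in {cfg.bundle_dir}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    igg = {}
    for cond, entry in manifest["igg"].items():
        igg[cond] = read_bedgraph(
            cfg.bundle_dir / entry["track"], entry["library_size"], label=f"IgG_{cond}"
        )
    factors = {}
    for factor, by_cond in manifest["factors"].items():
        peaks, tracks = {}, {}
        for cond, entry in by_cond.items():
            peaks[cond] = read_bed(cfg.bundle_dir / entry["peaks"])
            if cond not in igg:
                raise ValueError(
                    f"quantification stage: no IgG background track for condition {cond!r}"
                )
            chip = read_bedgraph(
                cfg.bundle_dir / entry["chip"],
                entry["library_size"],
                label=f"{factor}_{cond}",
            )
            tracks[cond] = (chip, igg[cond])
        factors[factor] = (peaks, tracks)
    return manifest, factors


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("resolved config: %s", cfg)
    manifest, factors = _load_bundle(cfg)
    reference = manifest["reference"]
    terminal = manifest["terminal"]

    # quantify + status per factor
    tables: dict[str, binding.OccupancyTable] = {}
    for factor, (peaks, tracks) in factors.items():
        table = binding.build_occupancy_table(factor, peaks, tracks)
        tables[factor] = table
        table.to_frame().to_csv(cfg.out_dir / f"occupancy_{factor}.tsv", sep="\t")
        ret = table.retention_table()
        status = table.status_table(
            reference, threshold=cfg.threshold, inclusive=cfg.inclusive
        )
        pd.concat(
            [ret.add_prefix("retention_"), status.add_prefix("status_")], axis=1
        ).to_csv(cfg.out_dir / f"retention_{factor}.tsv", sep="\t")

    # co-bound taxonomy
    elements = binding.cobound_elements(
        tables["OCT4"],
        tables["NANOG"],
        reference,
        terminal,
        threshold=cfg.threshold,
        inclusive=cfg.inclusive,
    )
    counts = pd.Series([e.class_label for e in elements]).value_counts().to_dict()
    class_counts = binding.class_count_table(counts)
    class_counts.to_csv(cfg.out_dir / "class_counts.tsv", sep="\t")
    write_bed(
        cfg.out_dir / "cobound_elements.bed",
        [
            GenomicRegion(e.region.chrom, e.region.start, e.region.end, e.class_label)
            for e in elements
        ],
    )

    # gene linkage + DE + class summaries
    genes = read_gene_table(cfg.bundle_dir / manifest["genes"])
    expr = read_expression_matrix(cfg.bundle_dir / manifest["expression"])
    links = linkage.link_elements_to_genes(elements, genes, cfg.max_gene_distance)
    pd.DataFrame(
        [(l.element_id, l.gene_id, l.distance, l.class_label) for l in links],
        columns=["element_id", "gene_id", "distance", "class_label"],
    ).to_csv(cfg.out_dir / "gene_links.tsv", sep="\t", index=False)
    de = linkage.simple_de(expr, terminal, reference, fdr_cutoff=cfg.fdr_cutoff)
    de.to_csv(cfg.out_dir / "de_results.tsv", sep="\t", index_label="gene_id")
    summaries = linkage.class_expression_summary(links, de, expr, reference=reference)
    summary_rows = []
    for name, s in summaries.items():
        for cond, st in s.per_condition.items():
            summary_rows.append({"class": name, "condition": cond, "n_linked": s.n_linked, "n_de": s.n_de} | st)
    pd.DataFrame(summary_rows).to_csv(
        cfg.out_dir / "class_expression_summary.tsv", sep="\t", index=False
    )

    # ranked-list target enrichment over linked DE genes
    enrichment = None
    targets = sorted({l.gene_id for l in links if bool(de.loc[l.gene_id, "is_de"])})
    if targets and 2 * cfg.tail_k < len(de):
        enrichment = linkage.target_rank_enrichment(de, targets, cfg.tail_k)

    # staging (optional: only when the bundle ships stage profiles)
    staging_result = None
    stage_path = cfg.bundle_dir / "stage_profiles.tsv"
    if stage_path.exists():
        prof_expr = read_expression_matrix(stage_path)
        stage_names = list(dict.fromkeys(prof_expr.conditions))
        profiles = staging.StageProfileSet(
            stages=stage_names, values=prof_expr.values, stage_of=prof_expr.conditions
        )
        ranked = staging.hotelling_rank(profiles)
        subset = staging.select_top_k(ranked, cfg.top_k_stage_genes)
        query_path = cfg.bundle_dir / "stage_queries.tsv"
        queries = read_expression_matrix(query_path) if query_path.exists() else expr
        staging_result = staging.stage_samples(queries, profiles, subset)
        out = staging_result.correlation.copy()
        out["best_stage"] = staging_result.best_stage
        out.to_csv(cfg.out_dir / "staging.tsv", sep="\t", index_label="sample")

    # differential k-mers between Class I and Class II sequences (optional)
    motif_results: dict[str, list[motifs.KmerResult]] = {}
    fasta_path = cfg.bundle_dir / manifest.get("sequences", "element_sequences.fa")
    if cfg.run_motifs and fasta_path.exists():
        seqs = read_fasta(fasta_path)
        # sequence ids carry their element coordinates (id|chrom:start-end);
        # classes come from the pipeline's own classification
        by_region: dict[tuple[str, int, int], str] = {
            (e.region.chrom, e.region.start, e.region.end): e.class_label
            for e in elements
        }
        fg, bg = [], []
        for seq_id, seq in seqs.items():
            if "|" not in seq_id:
                continue
            coord = seq_id.split("|", 1)[1]
            chrom, span = coord.rsplit(":", 1)
            start, end = (int(x) for x in span.split("-"))
            label = by_region.get((chrom, start, end))
            if label == "ClassI":
                fg.append(seq)
            elif label == "ClassII":
                bg.append(seq)
        if fg and bg:
            motif_results["ClassI_vs_ClassII"] = motifs.differential_kmers(
                fg, bg, k_range=(6,)
            )
            motif_results["ClassII_vs_ClassI"] = motifs.differential_kmers(
                bg, fg, k_range=(6,)
            )
            for name, res in motif_results.items():
                pd.DataFrame(
                    [
                        (r.kmer, r.k, r.fg_count, r.bg_count, r.p_value, r.e_value)
                        for r in res[:50]
                    ],
                    columns=["kmer", "k", "fg_count", "bg_count", "p_value", "e_value"],
                ).to_csv(cfg.out_dir / f"kmers_{name}.tsv", sep="\t", index=False)

    report = {
        "config": {
            "threshold": cfg.threshold,
            "comparator": cfg.comparator,
            "max_gene_distance": cfg.max_gene_distance,
            "fdr_cutoff": cfg.fdr_cutoff,
            "top_k_stage_genes": cfg.top_k_stage_genes,
            "tail_k": cfg.tail_k,
            "seed": cfg.seed,
        },
        "reference": reference,
        "terminal": terminal,
        "class_counts": {k: int(v) for k, v in class_counts["n"].items()},
        "n_links": len(links),
        "n_de": int(de["is_de"].sum()),
        "enrichment": (
            {"fraction_in_tails": enrichment[0], "hypergeometric_p": enrichment[1]}
            if enrichment
            else None
        ),
        "class_medians_terminal": {
            name: s.per_condition.get(terminal, {}).get("median")
            for name, s in summaries.items()
        },
    }
    if staging_result is not None:
        report["best_stage"] = staging_result.best_stage.to_dict()
    if motif_results:
        report["top_kmer_ClassI"] = motif_results["ClassI_vs_ClassII"][0].kmer
        report["top_kmer_ClassII"] = motif_results["ClassII_vs_ClassI"][0].kmer
    with open(cfg.out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return PipelineResult(
        tables=tables,
        elements=elements,
        class_counts=class_counts,
        links=links,
        de=de,
        class_summaries=summaries,
        enrichment=enrichment,
        staging_result=staging_result,
        motif_results=motif_results,
        report=report,
    )
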
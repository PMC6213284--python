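"""Synthetic data generator emulating the sorted-ESC ChIP/expression study design.

Generates a fully self-contained bundle with the statistical structure the
analysis assumes: three ESC conditions sorted by reporter level (EH high, EM
medium, EN negative — the reference-to-terminal axis) plus an EpiSC-like
expression condition; two factors (an OCT4-like factor that keeps binding at
roughly half of co-bound elements and a NANOG-like factor whose binding
collapses in the terminal state); planted kept/lost/gained peak dynamics;
genes placed within 20 kb of elements whose differential expression is
coupled to element class (Class I-linked genes down in the terminal state,
Class II-linked stable/up); a staged reference transcriptome with monotone
stage-marker trajectories; and element sequences with class-specific planted
k-mers (a nuclear-receptor half-site-like 6-mer in Class I, an octamer-like
6-mer in Class II).

Everything is driven by one root seed via spawned substreams, so the bundle
is byte-identical given (config, seed). The ground truth (class labels, true
occupancies, planted expression effects) is returned alongside the files for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .formats_io import (
    ExpressionMatrix,
    GeneModel,
    GenomicRegion,
    SignalTrack,
    nearest_gene_distance,
    write_bed,
    write_bedgraph,
    write_expression_matrix,
    write_fasta,
    write_gene_table,
)
from .staging import StageProfileSet

__all__ = [
    "SyntheticConfig",
    "StageConfig",
    "SyntheticDataset",
    "SyntheticTruth",
    "generate_dataset",
    "generate_stage_profiles",
    "generate_motif_sets",
]

# per-class (OCT4 trajectory, NANOG trajectory) over (EH, EM, EN), as fractions
# of peak occupancy; "lost" bottoms out at 5% of maximum, echoing the worked
# Tet2 example, "kept" stays at 75%
_KEPT = {"EH": 1.0, "EM": 0.85, "EN": 0.75}
_LOST = {"EH": 1.0, "EM": 0.40, "EN": 0.05}
_GAINED = {"EH": 0.05, "EM": 0.30, "EN": 1.0}
_ABSENT = {"EH": 0.0, "EM": 0.0, "EN": 0.0}

_CLASS_TRAJ = {
    "ClassI": (_LOST, _LOST),
    "ClassII": (_KEPT, _LOST),
    "KeptNanogOnly": (_LOST, _KEPT),
    "KeptBoth": (_KEPT, _KEPT),
    "OCT4only": (_KEPT, _ABSENT),
    "NANOGonly": (_ABSENT, _KEPT),
    "GainedOCT4": (_GAINED, _ABSENT),
    "GainedNANOG": (_ABSENT, _GAINED),
}

# planted expression effects (log2, relative to EH) for the gene linked to an
# element of each class; Class I-linked genes collapse in EN/Epi, Class
# II-linked genes hold or rise
_CLASS_EFFECT = {
    "ClassI": {"EH": 0.0, "EM": -0.5, "EN": -2.0, "Epi": -2.0},
    "ClassII": {"EH": 0.0, "EM": 0.0, "EN": 0.5, "Epi": 0.5},
    "KeptNanogOnly": {"EH": 0.0, "EM": 0.0, "EN": 0.0, "Epi": 0.0},
    "KeptBoth": {"EH": 0.0, "EM": 0.0, "EN": 0.0, "Epi": 0.0},
    "OCT4only": {"EH": 0.0, "EM": 0.0, "EN": 0.0, "Epi": 0.0},
    "NANOGonly": {"EH": 0.0, "EM": 0.0, "EN": 0.0, "Epi": 0.0},
    "GainedOCT4": {"EH": 0.0, "EM": 0.0, "EN": 0.0, "Epi": 0.0},
    "GainedNANOG": {"EH": 0.0, "EM": 0.0, "EN": 0.0, "Epi": 0.0},
}

CLASS_I_KMER = "AGGTCA"  # nuclear-receptor half-site core
CLASS_II_KMER = "ATGCAA"  # octamer-motif core


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic bundle (defaults ARE the conditions)."""

    chrom: str = "chrS"
    genome_length: int = 10_000_000
    conditions: tuple[str, ...] = ("EH", "EM", "EN")
    reference: str = "EH"
    terminal: str = "EN"
    # co-bound classes in the paper's proportions (~2034:1565:16:60 scaled down)
    n_class_i: int = 200
    n_class_ii: int = 150
    n_kept_nanog_only: int = 5
    n_kept_both: int = 10
    n_oct4_only: int = 100
    n_nanog_only: int = 50
    n_gained_oct4: int = 50
    n_gained_nanog: int = 10
    n_both_pairs: int = 15  # ClassI+ClassII element pairs sharing one gene
    element_width: int = 400
    base_occupancy: float = 10.0  # signal units per bp at full binding
    background_level: float = 0.5  # IgG-normalized background per bp (S/B = 20)
    call_threshold: float = 2.0  # occupancy above which a peak is "called"
    noise_sigma: float = 0.1  # log-normal sigma on occupancy
    library_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"EH": 2.0e7, "EM": 1.5e7, "EN": 2.5e7}
    )
    igg_library_size: float = 1.0e7
    gene_link_fraction: float = 0.9  # fraction of elements given their own gene
    gene_offset: int = 3_000  # bp from element to its gene
    gene_length: int = 1_000
    n_null_genes: int = 1_000
    expr_conditions: tuple[str, ...] = ("EH", "EM", "EN", "Epi")
    n_replicates: int = 3
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.0
    expr_noise_sd: float = 0.1
    n_planted_kmers: int = 3  # copies planted per co-bound element sequence

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            "ClassI": self.n_class_i + self.n_both_pairs,
            "ClassII": self.n_class_ii + self.n_both_pairs,
            "KeptNanogOnly": self.n_kept_nanog_only,
            "KeptBoth": self.n_kept_both,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        return cls(**{k: v for k, v in d.items()})


@dataclass
class SyntheticTruth:
    """Planted generative parameters, the yardstick for recovery tests."""

    seed: int
    elements: pd.DataFrame  # one row per element with class, coords, occupancies
    genes: pd.DataFrame  # gene_id, element_id, class, per-condition planted effect
    config: SyntheticConfig

    def class_counts(self) -> dict[str, int]:
        cobound = self.elements[
            self.elements["class_label"].isin(
                ["ClassI", "ClassII", "KeptNanogOnly", "KeptBoth"]
            )
        ]
        return cobound["class_label"].value_counts().to_dict()


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: SyntheticTruth
    peaks: dict[str, dict[str, list[GenomicRegion]]]  # factor -> cond -> regions
    tracks: dict[str, dict[str, tuple[SignalTrack, SignalTrack]]]
    genes: list[GeneModel]
    expression: ExpressionMatrix
    sequences: dict[str, str]  # cobound element id -> sequence
    sequence_class: dict[str, str]  # cobound element id -> class label

    def write(self, outdir: str | Path) -> None:
        """Emit the full plain-text bundle plus a YAML manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {
            "seed": self.truth.seed,
            "reference": self.config.reference,
            "terminal": self.config.terminal,
            "factors": {},
            "igg": {},
            "genes": "genes.tsv",
            "expression": "expression.tsv",
            "sequences": "element_sequences.fa",
        }
        for factor, by_cond in self.peaks.items():
            manifest["factors"][factor] = {}
            for cond, regions in by_cond.items():
                bed = f"peaks_{factor}_{cond}.bed"
                chip, igg = self.tracks[factor][cond]
                bg = f"chip_{factor}_{cond}.bedgraph"
                write_bed(outdir / bed, regions)
                write_bedgraph(outdir / bg, chip)
                manifest["factors"][factor][cond] = {
                    "peaks": bed,
                    "chip": bg,
                    "library_size": chip.library_size,
                }
                if cond not in manifest["igg"]:
                    iggf = f"igg_{cond}.bedgraph"
                    write_bedgraph(outdir / iggf, igg)
                    manifest["igg"][cond] = {
                        "track": iggf,
                        "library_size": igg.library_size,
                    }
        write_gene_table(outdir / "genes.tsv", self.genes)
        write_expression_matrix(outdir / "expression.tsv", self.expression)
        write_fasta(outdir / "element_sequences.fa", self.sequences)
        truth_el = self.truth.elements.copy()
        truth_el.to_csv(outdir / "truth_elements.tsv", sep="\t", index=False)
        self.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)


def _element_layout(cfg: SyntheticConfig, rng: np.random.Generator):
    """Assign classes to genome slots; returns a list of element dicts."""
    labels = (
        ["ClassI"] * cfg.n_class_i
        + ["ClassII"] * cfg.n_class_ii
        + ["KeptNanogOnly"] * cfg.n_kept_nanog_only
        + ["KeptBoth"] * cfg.n_kept_both
        + ["OCT4only"] * cfg.n_oct4_only
        + ["NANOGonly"] * cfg.n_nanog_only
        + ["GainedOCT4"] * cfg.n_gained_oct4
        + ["GainedNANOG"] * cfg.n_gained_nanog
        + ["BothPair"] * cfg.n_both_pairs
    )
    rng.shuffle(labels)
    n_slots = len(labels)
    stride = cfg.genome_length // n_slots
    w = cfg.element_width
    pair_span = 3 * w + 2 * (cfg.gene_offset + cfg.gene_length)
    min_stride = max(1_000 + 2 * w + cfg.gene_offset + cfg.gene_length, 1_000 + pair_span) + 500
    if stride < min_stride:
        raise ValueError(
            f"infeasible config: {n_slots} elements need stride >= {min_stride} bp, "
            f"got {stride} (enlarge genome_length or reduce counts)"
        )
    elements = []
    eid = 0
    for i, label in enumerate(labels):
        s = i * stride + 1_000
        if label == "BothPair":
            # a Class I and a Class II element flanking one shared gene
            for sub, offset in (("ClassI", 0), ("ClassII", pair_span - int(1.5 * w))):
                eid += 1
                start = s + offset
                elements.append(
                    {
                        "element_id": f"el_{eid:04d}",
                        "class_label": sub,
                        "slot": i,
                        "start": start,
                        "shared_gene_slot": i,
                    }
                )
        else:
            eid += 1
            elements.append(
                {
                    "element_id": f"el_{eid:04d}",
                    "class_label": label,
                    "slot": i,
                    "start": s,
                    "shared_gene_slot": None,
                }
            )
    return elements, stride


def _factor_regions(cfg: SyntheticConfig, el: dict) -> dict[str, GenomicRegion | None]:
    """OCT4/NANOG peak intervals for an element (offset so they overlap, not coincide)."""
    w = cfg.element_width
    s = el["start"]
    oct4_traj, nanog_traj = _CLASS_TRAJ[el["class_label"]]
    oct4 = GenomicRegion(cfg.chrom, s, s + w, el["element_id"] + "_O")
    nanog = GenomicRegion(cfg.chrom, s + w // 2, s + w // 2 + w, el["element_id"] + "_N")
    return {
        "OCT4": oct4 if any(v > 0 for v in oct4_traj.values()) else None,
        "NANOG": nanog if any(v > 0 for v in nanog_traj.values()) else None,
    }


def _build_track(
    cfg: SyntheticConfig,
    bumps: Sequence[tuple[int, int, float]],
    library_size: float,
    ref_library: float,
    label: str,
) -> SignalTrack:
    """Background-plus-bumps step track, scaled so that normalization by
    (library_size / ref_library) recovers the planted per-bp values."""
    scale = library_size / ref_library
    steps: list[tuple[int, int, float]] = []
    pos = 0
    bg = cfg.background_level * scale
    for start, end, occ in sorted(bumps):
        if start > pos:
            steps.append((pos, start, bg))
        steps.append((start, end, (occ + cfg.background_level) * scale))
        pos = end
    if pos < cfg.genome_length:
        steps.append((pos, cfg.genome_length, bg))
    arr = np.array(steps, dtype=np.float64)
    return SignalTrack(
        {cfg.chrom: (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])},
        library_size=library_size,
        label=label,
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def generate_dataset(
    config: SyntheticConfig | None = None, seed: int = 0
) -> SyntheticDataset:
    """Generate the full synthetic bundle and its ground truth."""
    cfg = config or SyntheticConfig()
    root = np.random.SeedSequence(seed)
    rng_layout, rng_noise, rng_expr, rng_seq = [
        np.random.default_rng(s) for s in root.spawn(4)
    ]
    elements, stride = _element_layout(cfg, rng_layout)
    ref_library = max(cfg.library_sizes.values())

    # --- true and noisy occupancies, peak calls -----------------------------
    rows = []
    peaks: dict[str, dict[str, list[GenomicRegion]]] = {
        f: {c: [] for c in cfg.conditions} for f in ("OCT4", "NANOG")
    }
    bumps: dict[str, dict[str, list[tuple[int, int, float]]]] = {
        f: {c: [] for c in cfg.conditions} for f in ("OCT4", "NANOG")
    }
    for el in elements:
        regions = _factor_regions(cfg, el)
        oct4_traj, nanog_traj = _CLASS_TRAJ[el["class_label"]]
        row = {
            "element_id": el["element_id"],
            "class_label": el["class_label"],
            "chrom": cfg.chrom,
        }
        member_starts, member_ends = [], []
        for factor, traj in (("OCT4", oct4_traj), ("NANOG", nanog_traj)):
            region = regions[factor]
            for cond in cfg.conditions:
                true_occ = cfg.base_occupancy * traj[cond]
                noisy = (
                    true_occ * np.exp(rng_noise.normal(0.0, cfg.noise_sigma))
                    if true_occ > 0
                    else 0.0
                )
                row[f"occ_{factor}_{cond}"] = true_occ
                if region is not None:
                    bumps[factor][cond].append((region.start, region.end, noisy))
                    if noisy > cfg.call_threshold:
                        peaks[factor][cond].append(region)
            if region is not None:
                member_starts.append(region.start)
                member_ends.append(region.end)
        row["start"] = min(member_starts)
        row["end"] = max(member_ends)
        rows.append(row)
    truth_elements = pd.DataFrame(rows)

    # --- tracks -------------------------------------------------------------
    tracks: dict[str, dict[str, tuple[SignalTrack, SignalTrack]]] = {}
    igg_by_cond = {
        cond: _build_track(
            cfg, [], cfg.igg_library_size, ref_library, label=f"IgG_{cond}"
        )
        for cond in cfg.conditions
    }
    for factor in ("OCT4", "NANOG"):
        tracks[factor] = {}
        for cond in cfg.conditions:
            chip = _build_track(
                cfg,
                bumps[factor][cond],
                cfg.library_sizes[cond],
                ref_library,
                label=f"{factor}_{cond}",
            )
            tracks[factor][cond] = (chip, igg_by_cond[cond])

    # --- genes and expression ----------------------------------------------
    genes: list[GeneModel] = []
    gene_rows = []
    by_slot_shared: dict[int, str] = {}
    for el in elements:
        slot = el["shared_gene_slot"]
        if slot is not None:
            if slot not in by_slot_shared:
                gid = f"gene_{el['element_id']}"
                # shared gene sits between the paired elements
                gstart = el["start"] + int(1.5 * cfg.element_width) + cfg.gene_offset
                genes.append(
                    GeneModel(gid, GenomicRegion(cfg.chrom, gstart, gstart + cfg.gene_length, gid))
                )
                by_slot_shared[slot] = gid
                # shared genes follow the Class I trajectory (dominant class)
                gene_rows.append(
                    {"gene_id": gid, "element_id": el["element_id"], "class_label": "Both"}
                    | {f"effect_{c}": _CLASS_EFFECT["ClassI"][c] for c in cfg.expr_conditions}
                )
        else:
            if rng_expr.random() < cfg.gene_link_fraction:
                gid = f"gene_{el['element_id']}"
                gstart = el["start"] + 2 * cfg.element_width + cfg.gene_offset
                genes.append(
                    GeneModel(gid, GenomicRegion(cfg.chrom, gstart, gstart + cfg.gene_length, gid))
                )
                gene_rows.append(
                    {
                        "gene_id": gid,
                        "element_id": el["element_id"],
                        "class_label": el["class_label"],
                    }
                    | {
                        f"effect_{c}": _CLASS_EFFECT[el["class_label"]][c]
                        for c in cfg.expr_conditions
                    }
                )
    for j in range(cfg.n_null_genes):
        gene_rows.append(
            {"gene_id": f"null_{j + 1:04d}", "element_id": None, "class_label": None}
            | {f"effect_{c}": 0.0 for c in cfg.expr_conditions}
        )
    truth_genes = pd.DataFrame(gene_rows)

    samples = [
        f"{cond}:{r + 1}" for cond in cfg.expr_conditions for r in range(cfg.n_replicates)
    ]
    baseline = rng_expr.normal(
        cfg.expr_baseline_mean, cfg.expr_baseline_sd, size=len(truth_genes)
    )
    values = np.empty((len(truth_genes), len(samples)))
    for jcol, sample in enumerate(samples):
        cond = sample.split(":")[0]
        effect = truth_genes[f"effect_{cond}"].values
        values[:, jcol] = baseline + effect + rng_expr.normal(
            0.0, cfg.expr_noise_sd, size=len(truth_genes)
        )
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=truth_genes["gene_id"].values, columns=samples),
        {s: s.split(":")[0] for s in samples},
    )

    # --- element sequences with class-specific planted k-mers ---------------
    sequences: dict[str, str] = {}
    sequence_class: dict[str, str] = {}
    for el in elements:
        label = el["class_label"]
        if label not in ("ClassI", "ClassII", "KeptNanogOnly", "KeptBoth"):
            continue
        length = int(1.5 * cfg.element_width)
        seq = list(_random_seq(rng_seq, length))
        planted = CLASS_I_KMER if label == "ClassI" else (
            CLASS_II_KMER if label == "ClassII" else None
        )
        if planted is not None:
            for _ in range(cfg.n_planted_kmers):
                pos = int(rng_seq.integers(0, length - len(planted)))
                seq[pos : pos + len(planted)] = planted
        # coordinates in the id let downstream steps match sequences to elements
        start = el["start"]
        seq_id = f"{el['element_id']}|{cfg.chrom}:{start}-{start + length}"
        sequences[seq_id] = "".join(seq)
        sequence_class[seq_id] = label

    truth = SyntheticTruth(
        seed=seed, elements=truth_elements, genes=truth_genes, config=cfg
    )
    _check_truth_consistency(cfg, truth)
    return SyntheticDataset(
        config=cfg,
        truth=truth,
        peaks=peaks,
        tracks=tracks,
        genes=genes,
        expression=expr,
        sequences=sequences,
        sequence_class=sequence_class,
    )


def _check_truth_consistency(cfg: SyntheticConfig, truth: SyntheticTruth) -> None:
    """Planted labels must re-derive from planted occupancies at the 0.5 threshold."""
    for _, row in truth.elements.iterrows():
        label = row["class_label"]
        if label not in ("ClassI", "ClassII", "KeptNanogOnly", "KeptBoth"):
            continue
        statuses = []
        for factor in ("OCT4", "NANOG"):
            occ = {c: row[f"occ_{factor}_{c}"] for c in cfg.conditions}
            peak = max(occ.values())
            ret = occ[cfg.terminal] / peak if peak > 0 else 0.0
            statuses.append("kept" if ret >= 0.5 else "lost")
        derived = {
            ("lost", "lost"): "ClassI",
            ("kept", "lost"): "ClassII",
            ("lost", "kept"): "KeptNanogOnly",
            ("kept", "kept"): "KeptBoth",
        }[tuple(statuses)]
        if derived != label:
            raise AssertionError(
                f"truth inconsistency at {row['element_id']}: planted {label}, derived {derived}"
            )


def truth_nearest_genes(
    truth: SyntheticTruth, genes: Sequence[GeneModel], max_distance: int = 20_000
) -> pd.DataFrame:
    """Geometric ground-truth linkage (nearest gene within range) per element."""
    rows = []
    for _, row in truth.elements.iterrows():
        region = GenomicRegion(row["chrom"], row["start"], row["end"], row["element_id"])
        gid, dist = nearest_gene_distance(region, list(genes))
        if gid is not None and dist is not None and dist <= max_distance:
            rows.append((row["element_id"], gid, dist))
    return pd.DataFrame(rows, columns=["element_id", "gene_id", "distance"])


# ---------------------------------------------------------------------------
# Staged reference transcriptome
# ---------------------------------------------------------------------------

DEFAULT_STAGES = ("CAV", "PS", "ES", "MS", "LMS", "LS", "OBEB", "LB")


@dataclass
class StageConfig:
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_genes: int = 2_000
    n_replicates: int = 3
    frac_staged: float = 0.5  # genes with monotone stage trajectories
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    span_min: float = 1.0  # total log2 change of a staged gene across stages
    span_max: float = 3.0
    noise_sigma: float = 0.2  # replicate noise, log2 units


def generate_stage_profiles(
    config: StageConfig | None = None,
    seed: int = 0,
    query_stages: Sequence[str] | None = None,
    query_mixes: Sequence[tuple[str, str, float]] = (),
    query_noise: float | None = None,
) -> tuple[StageProfileSet, ExpressionMatrix, pd.DataFrame]:
    """Staged reference profiles plus query samples with known stage identity.

    Staged genes follow per-gene monotone (linear) trajectories across the
    stage order; the rest are flat. Queries are stage means (``query_stages``)
    or convex mixes of two stage means (``query_mixes`` of (stage_a, stage_b,
    weight_a)), with seeded noise. Returns (profiles, queries, truth table).
    """
    cfg = config or StageConfig()
    if len(cfg.stages) < 2 or cfg.n_replicates < 2:
        raise ValueError("need >=2 stages and >=2 replicates")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n, k = cfg.n_genes, len(cfg.stages)
    genes = [f"g{i + 1:05d}" for i in range(n)]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    staged = rng.random(n) < cfg.frac_staged
    span = rng.uniform(cfg.span_min, cfg.span_max, size=n) * rng.choice([-1, 1], size=n)
    span[~staged] = 0.0
    grid = np.linspace(0.0, 1.0, k)
    means = baseline[:, None] + span[:, None] * grid[None, :]  # genes x stages

    cols, stage_of = [], {}
    data = []
    for j, stage in enumerate(cfg.stages):
        for r in range(cfg.n_replicates):
            name = f"{stage}:{r + 1}"
            cols.append(name)
            stage_of[name] = stage
            data.append(means[:, j] + rng.normal(0.0, cfg.noise_sigma, size=n))
    profiles = StageProfileSet(
        stages=list(cfg.stages),
        values=pd.DataFrame(np.column_stack(data), index=genes, columns=cols),
        stage_of=pd.Series(stage_of),
    )

    if query_stages is None:
        query_stages = list(cfg.stages)
    qnoise = cfg.noise_sigma if query_noise is None else query_noise
    qcols, qdata, truth_rows = [], [], []
    for i, stage in enumerate(query_stages):
        j = list(cfg.stages).index(stage)
        name = f"query{i + 1}:{stage}"
        qcols.append(name)
        qdata.append(means[:, j] + rng.normal(0.0, qnoise, size=n))
        truth_rows.append((name, stage, stage, 1.0))
    for i, (sa, sb, wa) in enumerate(query_mixes):
        ja, jb = list(cfg.stages).index(sa), list(cfg.stages).index(sb)
        name = f"mix{i + 1}:{sa}-{sb}"
        qcols.append(name)
        qdata.append(wa * means[:, ja] + (1 - wa) * means[:, jb] + rng.normal(0.0, qnoise, size=n))
        truth_rows.append((name, sa, sb, wa))
    queries = ExpressionMatrix(
        pd.DataFrame(np.column_stack(qdata), index=genes, columns=qcols),
        {c: c.split(":")[1] for c in qcols},
    )
    truth = pd.DataFrame(truth_rows, columns=["sample", "stage_a", "stage_b", "weight_a"])
    return profiles, queries, truth


def generate_motif_sets(
    kmer: str = CLASS_I_KMER,
    fold: float = 5.0,
    n_fg: int = 100,
    n_bg: int = 100,
    seq_len: int = 200,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Foreground/background sequence sets with one k-mer planted in the
    foreground at ``fold`` x its expected background frequency."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    k = len(kmer)
    fg = [_random_seq(rng, seq_len) for _ in range(n_fg)]
    bg = [_random_seq(rng, seq_len) for _ in range(n_bg)]
    positions = n_fg * (seq_len - k + 1)
    natural = 2.0 * 4.0**-k  # canonical (strand-pooled) rate for a non-palindrome
    extra = int(round((fold - 1.0) * natural * positions))
    for _ in range(extra):
        i = int(rng.integers(0, n_fg))
        pos = int(rng.integers(0, seq_len - k))
        s = fg[i]
        fg[i] = s[:pos] + kmer + s[pos + k :]
    return fg, bg


def load_config(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return SyntheticConfig.from_dict(d)


def config_to_dict(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    d["library_sizes"] = dict(d["library_sizes"])
    return d
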
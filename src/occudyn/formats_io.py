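"""Genomic primitives and plain-text format I/O.

All coordinates are 0-based, half-open (BED convention). Every other module
builds on the containers here: :class:`GenomicRegion` for peaks and merged
elements, :class:`SignalTrack` for per-bp coverage (bedGraph), ``GeneModel``
for the gene table, and :class:`ExpressionMatrix` for log2 expression values
with condition/replicate-labelled samples.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "SignalTrack",
    "GeneModel",
    "ExpressionMatrix",
    "FormatError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_table",
    "write_gene_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_fasta",
    "write_fasta",
    "merge_intervals",
    "nearest_gene_distance",
]


class FormatError(ValueError):
    """Raised for malformed input files (line number included when known)."""


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A chromosome interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand; the TSS is implied by the strand."""

    gene_id: str
    region: GenomicRegion
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.region.start if self.strand == "+" else self.region.end - 1


class SignalTrack:
    """Step-function coverage over chromosomes (bedGraph semantics).

    Stores, per chromosome, sorted non-overlapping steps as parallel arrays
    of start, end, value. Positions not covered by any step have value 0.
    ``library_size`` is the sequencing depth (total tags) used for
    between-dataset normalization.
    """

    def __init__(
        self,
        steps: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_size: float,
        label: str = "",
    ) -> None:
        if library_size <= 0:
            raise ValueError("library_size must be positive")
        self.library_size = float(library_size)
        self.label = label
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in steps.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise FormatError(f"empty or inverted step on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"overlapping steps on {chrom}")
            if np.any(values < 0):
                raise FormatError(f"negative signal value on {chrom}")
            self._steps[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._steps)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._steps.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    def extent(self, chrom: str) -> int:
        """Rightmost covered coordinate on ``chrom`` (0 if uncovered)."""
        _, ends, _ = self.steps(chrom)
        return int(ends[-1]) if len(ends) else 0

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of value x overlap-bp over [start, end). Uncovered bp count 0."""
        if end <= start:
            raise ValueError("zero-width interval")
        starts, ends, values = self.steps(chrom)
        if len(starts) == 0:
            return 0.0
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum(values[lo:hi] * (e - s)))

    def interval_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-bp value over [start, end)."""
        return self.interval_sum(chrom, start, end) / (end - start)


class ExpressionMatrix:
    """Log2 expression values, genes x samples, samples labelled condition:replicate."""

    def __init__(self, values: pd.DataFrame, conditions: Mapping[str, str]) -> None:
        if values.index.duplicated().any():
            raise ValueError("duplicated gene ids")
        missing = [s for s in values.columns if s not in conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        self.values = values.astype(float)
        self.conditions = pd.Series({s: conditions[s] for s in values.columns})

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]

    def condition_values(self, condition: str) -> pd.DataFrame:
        cols = self.samples_for(condition)
        if not cols:
            raise KeyError(f"no samples for condition {condition!r}")
        return self.values[cols]

    def condition_mean(self, condition: str) -> pd.Series:
        return self.condition_values(condition).mean(axis=1)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        idx = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[idx], dict(self.conditions))


# ---------------------------------------------------------------------------
# Readers / writers (tab-delimited, LF-terminated)
# ---------------------------------------------------------------------------


def _open_lines(path) -> Iterable[tuple[int, str]]:
    if isinstance(path, io.StringIO):
        lines = path.getvalue().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    for i, line in enumerate(lines, start=1):
        yield i, line


def read_bed(path) -> list[GenomicRegion]:
    """Parse a BED (>=3 column) file into regions, preserving file order.

    ``track``/``browser`` header lines and blank lines are skipped.
    """
    out: list[GenomicRegion] = []
    for lineno, line in _open_lines(path):
        stripped = line.strip()
        if not stripped or stripped.startswith(("track", "browser", "#")):
            continue
        parts = stripped.split()
        if len(parts) < 3:
            raise FormatError(f"line {lineno}: expected >=3 columns")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as err:
            raise FormatError(f"line {lineno}: non-integer coordinates") from err
        name = parts[3] if len(parts) > 3 else None
        try:
            out.append(GenomicRegion(chrom, start, end, name))
        except ValueError as err:
            raise FormatError(f"line {lineno}: {err}") from err
    return out


def write_bed(path, regions: Sequence[GenomicRegion], names: bool = True) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            if names:
                name = r.name if r.name is not None else f"region_{i + 1}"
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_bedgraph(path, library_size: float, label: str = "") -> SignalTrack:
    """Parse a 4-column bedGraph into a :class:`SignalTrack`.

    Steps within a chromosome must be non-overlapping; values must be
    non-negative.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _open_lines(path):
        stripped = line.strip()
        if not stripped or stripped.startswith(("track", "browser", "#")):
            continue
        parts = stripped.split()
        if len(parts) < 4:
            raise FormatError(f"line {lineno}: expected 4 columns")
        try:
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as err:
            raise FormatError(f"line {lineno}: bad coordinates or value") from err
        if value < 0:
            raise FormatError(f"line {lineno}: negative value")
        per_chrom.setdefault(parts[0], []).append((start, end, value))
    steps = {}
    for chrom, triples in per_chrom.items():
        arr = np.array(triples, dtype=np.float64)
        steps[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return SignalTrack(steps, library_size=library_size, label=label)


def write_bedgraph(path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.steps(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_gene_table(path) -> list[GeneModel]:
    """Read a TSV gene table: gene_id, chrom, start, end, strand."""
    genes: list[GeneModel] = []
    for lineno, line in _open_lines(path):
        stripped = line.strip()
        if not stripped or stripped.startswith("#") or stripped.startswith("gene_id\t"):
            continue
        parts = stripped.split("\t")
        if len(parts) < 5:
            raise FormatError(f"line {lineno}: expected 5 columns")
        gene_id, chrom, start, end, strand = parts[:5]
        try:
            region = GenomicRegion(chrom, int(start), int(end), gene_id)
        except ValueError as err:
            raise FormatError(f"line {lineno}: {err}") from err
        genes.append(GeneModel(gene_id, region, strand))
    return genes


def write_gene_table(path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.region.chrom}\t{g.region.start}\t{g.region.end}\t{g.strand}\n"
            )


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes x samples TSV whose header carries condition:replicate labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    conditions = {}
    for col in df.columns:
        if ":" not in col:
            raise FormatError(f"sample {col!r} lacks a condition:replicate label")
        conditions[col] = col.split(":", 1)[0]
    return ExpressionMatrix(df, conditions)


def write_expression_matrix(path, matrix: ExpressionMatrix) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader returning {id: sequence} (uppercased)."""
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    for lineno, line in _open_lines(path):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].split()[0]
            if current in seqs:
                raise FormatError(f"line {lineno}: duplicate sequence id {current!r}")
            seqs[current] = []
        else:
            if current is None:
                raise FormatError(f"line {lineno}: sequence before header")
            seqs[current].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def merge_intervals(regions: Sequence[GenomicRegion]) -> list[GenomicRegion]:
    """Union of overlapping regions into the minimal disjoint cover.

    Two regions are merged iff they share >=1 bp on the same chromosome;
    exactly abutting regions (end == start) stay separate, consistent with
    half-open coordinates. Output is sorted by (chrom, start).
    """
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged: list[GenomicRegion] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start < cur_end:  # strict: abutting intervals not merged
                cur_end = max(cur_end, r.end)
            else:
                merged.append(GenomicRegion(chrom, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        merged.append(GenomicRegion(chrom, cur_start, cur_end))
    return merged


def nearest_gene_distance(
    region: GenomicRegion, genes: Sequence[GeneModel], use_tss: bool = False
) -> tuple[str | None, int | None]:
    """Closest gene to a region and the gap in bp (0 if overlapping).

    By default the gene body anchors the distance; ``use_tss`` measures to the
    TSS instead. Ties are broken by the lexicographically smallest gene_id.
    Returns ``(None, None)`` when no gene shares a chromosome with the region.
    """
    if not genes:
        raise ValueError("gene list is empty")
    best: tuple[int, str] | None = None
    for g in genes:
        if g.region.chrom != region.chrom:
            continue
        if use_tss:
            t = g.tss  # treated as the 1-bp interval [t, t+1)
            if region.start <= t < region.end:
                d = 0
            elif t >= region.end:
                d = t - region.end
            else:
                d = region.start - (t + 1)
        else:
            if region.overlaps(g.region):
                d = 0
            elif g.region.start >= region.end:
                d = g.region.start - region.end
            else:
                d = region.start - g.region.end
        key = (d, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[1], best[0]
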
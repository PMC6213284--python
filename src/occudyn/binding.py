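"""Occupancy quantification and the retention-based kept/lost/gained classifier.

The model: per transcription factor, peaks called in any condition are merged
into one region set; ChIP signal over each region is normalized by library
size and background-subtracted (IgG); each region's *retention* in a condition
is its normalized occupancy divided by its maximum across conditions.
A region is "lost" in a condition when retention falls below the threshold
(default 50%), "gained" when it is called as a peak only outside the reference
condition, and "kept" otherwise. Regions bound by both factors in the
reference state are then classified by what happens in the terminal state:

========  ===============  ================
label     OCT4-like        NANOG-like
========  ===============  ================
ClassI    lost             lost
ClassII   kept             lost
KeptNanogOnly  lost        kept
KeptBoth  kept             kept
========  ===============  ================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GenomicRegion, SignalTrack, merge_intervals

__all__ = [
    "OccupancyTable",
    "CoboundElement",
    "MetaProfile",
    "CLASS_LABELS",
    "quantify_region",
    "build_occupancy_table",
    "retention",
    "classify_status",
    "classify_cobound",
    "cobound_elements",
    "class_count_table",
    "meta_profile",
]

Status = Literal["kept", "lost", "gained"]
CLASS_LABELS = ("ClassI", "ClassII", "KeptNanogOnly", "KeptBoth")


def quantify_region(
    region: GenomicRegion,
    chip: SignalTrack,
    background: SignalTrack,
    ref_library: float,
) -> float:
    """Normalized, background-subtracted mean per-bp occupancy over a region.

    occupancy = max(0, mean_bp(chip) * ref_library / chip.library_size
                     - mean_bp(background) * ref_library / background.library_size)

    Regions outside track coverage contribute zero signal.
    """
    if region.width <= 0:
        raise ValueError("zero-width region")
    chip_mean = chip.interval_mean(region.chrom, region.start, region.end)
    bg_mean = background.interval_mean(region.chrom, region.start, region.end)
    occ = (
        chip_mean * ref_library / chip.library_size
        - bg_mean * ref_library / background.library_size
    )
    return max(0.0, occ)


@dataclass
class OccupancyTable:
    """Merged regions x conditions occupancy for one factor.

    ``signal``: DataFrame (region index x condition) of normalized,
    background-subtracted per-bp occupancy; ``called``: same shape, True where
    the merged region overlaps >=1 original peak of the condition.
    """

    factor: str
    regions: list[GenomicRegion]
    signal: pd.DataFrame
    called: pd.DataFrame

    @property
    def conditions(self) -> list[str]:
        return list(self.signal.columns)

    def retention_table(self) -> pd.DataFrame:
        """Per-region retention fractions (row max scaled to 1)."""
        return self.signal.apply(lambda row: pd.Series(retention(row.to_dict())), axis=1)

    def status_table(
        self, reference: str, threshold: float = 0.5, inclusive: bool = False
    ) -> pd.DataFrame:
        """kept/lost/gained status per region per condition vs ``reference``."""
        ret = self.retention_table()
        out = {}
        for cond in self.conditions:
            out[cond] = [
                classify_status(
                    ret.iloc[i][cond],
                    called_here=bool(self.called.iloc[i][cond]),
                    called_in_reference=bool(self.called.iloc[i][reference]),
                    threshold=threshold,
                    inclusive=inclusive,
                )
                for i in range(len(self.regions))
            ]
        return pd.DataFrame(out, index=self.signal.index)

    def to_frame(self) -> pd.DataFrame:
        """Flat table for TSV export: coordinates + signal + called flags."""
        rows = {
            "chrom": [r.chrom for r in self.regions],
            "start": [r.start for r in self.regions],
            "end": [r.end for r in self.regions],
        }
        df = pd.DataFrame(rows, index=self.signal.index)
        for cond in self.conditions:
            df[f"signal_{cond}"] = self.signal[cond].values
        for cond in self.conditions:
            df[f"called_{cond}"] = self.called[cond].values
        return df


def build_occupancy_table(
    factor: str,
    peaks_by_condition: Mapping[str, Sequence[GenomicRegion]],
    tracks_by_condition: Mapping[str, tuple[SignalTrack, SignalTrack]],
    ref_library: float | None = None,
) -> OccupancyTable:
    """Merge all conditions' peaks for one factor and quantify every condition.

    ``ref_library`` defaults to the largest ChIP library among the factor's
    datasets; retention is a ratio so the choice cancels, fixing it makes
    absolute values reproducible.
    """
    conditions = list(peaks_by_condition)
    if len(conditions) < 2:
        raise ValueError("need >=2 conditions")
    missing = [c for c in conditions if c not in tracks_by_condition and peaks_by_condition[c]]
    if missing:
        raise ValueError(f"missing signal track for condition(s) with peaks: {missing}")
    all_peaks = [r for c in conditions for r in peaks_by_condition[c]]
    if not all_peaks:
        raise ValueError("no peaks in any condition")
    regions = merge_intervals(all_peaks)
    if ref_library is None:
        ref_library = max(t[0].library_size for t in tracks_by_condition.values())

    index = [f"{factor}_{i + 1}" for i in range(len(regions))]
    signal = pd.DataFrame(index=index, columns=list(tracks_by_condition), dtype=float)
    called = pd.DataFrame(False, index=index, columns=list(tracks_by_condition))
    for cond, (chip, bg) in tracks_by_condition.items():
        signal[cond] = [quantify_region(r, chip, bg, ref_library) for r in regions]
        peaks = peaks_by_condition.get(cond, [])
        called[cond] = [any(r.overlaps(p) for p in peaks) for r in regions]
    regions = [
        GenomicRegion(r.chrom, r.start, r.end, name) for r, name in zip(regions, index)
    ]
    return OccupancyTable(factor=factor, regions=regions, signal=signal, called=called)


def retention(signal_by_condition: Mapping[str, float]) -> dict[str, float]:
    """Fraction of the maximum observed occupancy per condition.

    All-zero input yields all-zero retention (nothing was ever bound).
    """
    if not signal_by_condition:
        raise ValueError("need at least one condition")
    values = np.array(list(signal_by_condition.values()), dtype=float)
    if np.any(values < 0):
        raise ValueError("negative occupancy (upstream clamp violated)")
    peak = values.max()
    if peak == 0:
        return {c: 0.0 for c in signal_by_condition}
    return {c: float(v / peak) for c, v in signal_by_condition.items()}


def classify_status(
    retention_frac: float,
    called_here: bool,
    called_in_reference: bool,
    threshold: float = 0.5,
    inclusive: bool = False,
) -> Status:
    """kept/lost/gained call for one region in one condition.

    "gained" when the peak is called here but not in the reference condition;
    otherwise "lost" when retention < threshold (strict comparator; set
    ``inclusive`` for <=), else "kept".
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not 0 <= retention_frac <= 1:
        raise ValueError(f"retention outside [0, 1]: {retention_frac}")
    if called_here and not called_in_reference:
        return "gained"
    if (retention_frac <= threshold) if inclusive else (retention_frac < threshold):
        return "lost"
    return "kept"


def classify_cobound(oct4_status: Status, nanog_status: Status) -> str:
    """Class label for a reference-co-bound element from terminal statuses."""
    for s in (oct4_status, nanog_status):
        if s == "gained":
            raise ValueError("a reference-co-bound region cannot be 'gained'")
        if s not in ("kept", "lost"):
            raise ValueError(f"invalid status {s!r}")
    return {
        ("lost", "lost"): "ClassI",
        ("kept", "lost"): "ClassII",
        ("lost", "kept"): "KeptNanogOnly",
        ("kept", "kept"): "KeptBoth",
    }[(oct4_status, nanog_status)]


@dataclass
class CoboundElement:
    """A connected component of overlapping OCT4/NANOG regions co-bound in the reference state."""

    region: GenomicRegion  # union interval of all member regions
    class_label: str
    oct4_members: list[GenomicRegion] = field(default_factory=list)
    nanog_members: list[GenomicRegion] = field(default_factory=list)

    @property
    def element_id(self) -> str:
        return self.region.name or str(self.region)


def _aggregate(statuses: Sequence[Status], how: str) -> Status:
    if how == "any":
        return "kept" if any(s == "kept" for s in statuses) else "lost"
    if how == "all":
        return "kept" if all(s == "kept" for s in statuses) else "lost"
    raise ValueError(f"unknown aggregation {how!r}")


def cobound_elements(
    oct4_table: OccupancyTable,
    nanog_table: OccupancyTable,
    reference: str,
    terminal: str,
    threshold: float = 0.5,
    inclusive: bool = False,
    aggregation: str = "any",
) -> list[CoboundElement]:
    """Co-bound elements and their Class I/II taxonomy.

    Units are connected components of reference-called OCT4 regions and
    reference-called NANOG regions that overlap by >=1 bp; components lacking
    either factor are not co-bound and are dropped. A factor counts as "kept"
    for a unit when ANY (default) of its member regions is kept in the
    terminal condition.
    """
    tagged: list[tuple[GenomicRegion, str, Status]] = []
    for tab, tag in ((oct4_table, "OCT4"), (nanog_table, "NANOG")):
        statuses = tab.status_table(reference, threshold=threshold, inclusive=inclusive)
        for i, r in enumerate(tab.regions):
            if bool(tab.called.iloc[i][reference]):
                tagged.append((r, tag, statuses.iloc[i][terminal]))

    # sweep per chromosome to find overlap-connected components
    by_chrom: dict[str, list[tuple[GenomicRegion, str, Status]]] = {}
    for item in tagged:
        by_chrom.setdefault(item[0].chrom, []).append(item)

    elements: list[CoboundElement] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0].start, t[0].end))
        component: list[tuple[GenomicRegion, str, Status]] = []
        comp_end = -1
        for item in items:
            r = item[0]
            if component and r.start < comp_end:
                component.append(item)
                comp_end = max(comp_end, r.end)
            else:
                _flush_component(component, elements, aggregation)
                component = [item]
                comp_end = r.end
        _flush_component(component, elements, aggregation)
    for i, el in enumerate(elements):
        el.region = GenomicRegion(
            el.region.chrom, el.region.start, el.region.end, f"cobound_{i + 1}"
        )
    return elements


def _flush_component(
    component: list[tuple[GenomicRegion, str, Status]],
    elements: list[CoboundElement],
    aggregation: str,
) -> None:
    if not component:
        return
    oct4 = [(r, s) for r, tag, s in component if tag == "OCT4"]
    nanog = [(r, s) for r, tag, s in component if tag == "NANOG"]
    if not oct4 or not nanog:
        return  # single-factor component: not co-bound
    for _, s in oct4 + nanog:
        if s == "gained":
            raise ValueError("reference-co-bound region with 'gained' terminal status")
    union = GenomicRegion(
        component[0][0].chrom,
        min(r.start for r, _, _ in component),
        max(r.end for r, _, _ in component),
    )
    label = classify_cobound(
        _aggregate([s for _, s in oct4], aggregation),
        _aggregate([s for _, s in nanog], aggregation),
    )
    elements.append(
        CoboundElement(
            region=union,
            class_label=label,
            oct4_members=[r for r, _ in oct4],
            nanog_members=[r for r, _ in nanog],
        )
    )


def class_count_table(counts: Mapping[str, int]) -> pd.DataFrame:
    """Class-count summary with a total row (the pie-chart numbers as a table)."""
    rows = [(label, int(counts.get(label, 0))) for label in CLASS_LABELS]
    rows.append(("Total", sum(n for _, n in rows)))
    return pd.DataFrame(rows, columns=["class", "n"]).set_index("class")


@dataclass
class MetaProfile:
    """Average normalized signal around region centers."""

    offsets: np.ndarray  # bp, bin centers, symmetric about 0
    mean_signal: np.ndarray
    n_regions: int


def meta_profile(
    regions: Sequence[GenomicRegion],
    chip: SignalTrack,
    background: SignalTrack,
    ref_library: float | None = None,
    half_window: int = 2000,
    bin_size: int = 10,
) -> MetaProfile:
    """Average binding profile around region midpoints.

    Per offset bin, the mean over regions of library-normalized,
    background-subtracted per-bp signal. Windows running off the covered
    chromosome extent are truncated: those bins average over the regions that
    do cover them.
    """
    if not regions:
        raise ValueError("empty region list")
    if not (half_window >= bin_size > 0):
        raise ValueError("need half_window >= bin > 0")
    if ref_library is None:
        ref_library = chip.library_size
    n_bins = (2 * half_window) // bin_size
    edges = -half_window + bin_size * np.arange(n_bins + 1)
    offsets = (edges[:-1] + edges[1:]) / 2.0
    total = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=int)
    chip_scale = ref_library / chip.library_size
    bg_scale = ref_library / background.library_size
    for r in regions:
        center = r.center
        extent = max(chip.extent(r.chrom), background.extent(r.chrom))
        for j in range(n_bins):
            lo, hi = center + edges[j], center + edges[j + 1]
            if lo < 0 or hi > extent:
                continue  # truncated window: bin unavailable for this region
            val = (
                chip.interval_mean(r.chrom, lo, hi) * chip_scale
                - background.interval_mean(r.chrom, lo, hi) * bg_scale
            )
            total[j] += val
            count[j] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return MetaProfile(offsets=offsets, mean_signal=mean, n_regions=len(regions))
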
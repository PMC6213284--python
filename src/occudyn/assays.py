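"""Restriction-protection CpG methylation quantification from qPCR Ct values.

Methylation of a CpG inside a methylation-sensitive restriction site (HpaII,
AciI, Hin6I, TaqI, ...) protects it from digestion, so the methylated
fraction of templates survives and amplifies. With amplification efficiency
``e``, percent methylation = 100 x e^-(Ct_digested - Ct_mock), clamped to
[0, 100]. The value reports total methylation (5mC + 5hmC combined); the two
marks are not distinguished.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["MethylationRecord", "protection_percent", "methylation_table"]


@dataclass(frozen=True)
class MethylationRecord:
    site_id: str
    condition: str
    percent_methylation: float
    undetermined: bool = False


def protection_percent(
    ct_digested: float, ct_mock: float, efficiency: float = 2.0
) -> float:
    """Percent of templates protected from digestion (= percent methylated)."""
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    if not (math.isfinite(ct_digested) and math.isfinite(ct_mock)):
        raise ValueError("Ct values must be finite")
    percent = 100.0 * efficiency ** -(ct_digested - ct_mock)
    return min(100.0, max(0.0, percent))


def methylation_table(ct_table: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Convert a Ct table (site, condition, ct_digested, ct_mock) to percents.

    A missing/NaN digested Ct means no amplification after digestion
    (complete digestion): 0% methylation, flagged ``undetermined``.
    """
    required = {"site", "condition", "ct_digested", "ct_mock"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    rows = []
    for _, row in ct_table.iterrows():
        if pd.isna(row["ct_digested"]):
            rows.append((row["site"], row["condition"], 0.0, True))
        else:
            pct = protection_percent(row["ct_digested"], row["ct_mock"], efficiency)
            rows.append((row["site"], row["condition"], pct, False))
    return pd.DataFrame(
        rows, columns=["site", "condition", "percent_methylation", "undetermined"]
    )
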
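"""Differential short-oligomer (6-8 nt) enrichment between two sequence sets.

A self-contained, simplified analogue of classical oligo-analysis: k-mers are
counted on both strands and pooled under the canonical form (lexicographic
minimum of the k-mer and its reverse complement); the foreground count of each
k-mer is tested against a binomial null whose rate is the background relative
frequency (+1 pseudocount), and P-values are multiplied by the number of
distinct k-mers tested to give E-values. No Markov background or
overlap-aware variance correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = ["KmerResult", "count_kmers", "differential_kmers", "revcomp", "canonical_kmer"]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@lru_cache(maxsize=8)
def _revcomp_codes(k: int) -> np.ndarray:
    """Lookup table mapping every k-mer code to its reverse-complement code."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_CODE_BASE[code & 3])
        code >>= 2
    return "".join(reversed(out))


def count_kmers(sequences: Iterable[str], k: int, allow_any_k: bool = False) -> dict[str, int]:
    """Count canonical k-mers at every N-free position (overlaps counted).

    A k-mer and its reverse complement pool under the canonical form;
    palindromes are counted once per position. ``k`` is restricted to the
    6-8 nt range the analysis uses unless ``allow_any_k``.
    """
    if not allow_any_k and not 6 <= k <= 8:
        raise ValueError("k must be in [6, 8] (pass allow_any_k to override)")
    if k < 1:
        raise ValueError("k must be positive")
    counts = np.zeros(4**k, dtype=np.int64)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    for seq in sequences:
        su = seq.upper()
        if len(su) < k:
            continue
        arr = np.frombuffer(su.encode("ascii"), dtype=np.uint8)
        code = np.full(arr.shape, -1, dtype=np.int64)
        for base, c in _BASE_CODE.items():
            code[arr == ord(base)] = c
        invalid = code < 0
        if invalid.any():
            bad = set(chr(b) for b in arr[invalid]) - {"N"}
            if bad:
                raise ValueError(f"non-ACGTN character(s) in sequence: {sorted(bad)}")
        windows = np.lib.stride_tricks.sliding_window_view(code, k)
        window_valid = (windows >= 0).all(axis=1)  # skip N-containing windows
        if not window_valid.any():
            continue
        kcodes = windows[window_valid] @ weights
        counts += np.bincount(kcodes, minlength=4**k)
    rc = _revcomp_codes(k)
    canon = np.minimum(np.arange(4**k, dtype=np.int64), rc)
    pooled = np.zeros(4**k, dtype=np.int64)
    np.add.at(pooled, canon, counts)
    nz = np.nonzero(pooled)[0]
    return {_decode(int(c), k): int(pooled[c]) for c in nz if canon[c] == c}


def _countable_positions(sequences: Sequence[str], k: int) -> int:
    """Number of N-free k-windows across all sequences."""
    total = 0
    for seq in sequences:
        su = seq.upper()
        if len(su) < k:
            continue
        isn = np.frombuffer(su.encode("ascii"), dtype=np.uint8) == ord("N")
        if not isn.any():
            total += len(su) - k + 1
        else:
            windows = np.lib.stride_tricks.sliding_window_view(isn, k)
            total += int((~windows.any(axis=1)).sum())
    return total


@dataclass(frozen=True)
class KmerResult:
    kmer: str  # canonical form
    k: int
    fg_count: int
    bg_count: int
    fg_total: int
    bg_total: int
    p_value: float
    e_value: float


def differential_kmers(
    fg: Sequence[str],
    bg: Sequence[str],
    k_range: Sequence[int] = (6, 7, 8),
    allow_any_k: bool = False,
) -> list[KmerResult]:
    """Rank k-mers by foreground-vs-background enrichment (E-value ascending).

    For every canonical k-mer observed in either set, the expected foreground
    rate is the background relative frequency with a +1 pseudocount on the
    background count; P is the binomial upper tail P(X >= fg_count) over the
    foreground's countable positions, and E = P x the number of distinct
    k-mers tested across the whole k range.
    """
    if not fg or not bg:
        raise ValueError("both sequence sets must be non-empty")
    per_k = []
    n_tested = 0
    for k in k_range:
        fg_counts = count_kmers(fg, k, allow_any_k=allow_any_k)
        bg_counts = count_kmers(bg, k, allow_any_k=allow_any_k)
        fg_total = _countable_positions(fg, k)
        bg_total = _countable_positions(bg, k)
        if bg_total == 0:
            raise ValueError("background has no countable positions")
        kmers = sorted(set(fg_counts) | set(bg_counts))
        n_tested += len(kmers)
        per_k.append((k, fg_counts, bg_counts, fg_total, bg_total, kmers))
    results: list[KmerResult] = []
    for k, fg_counts, bg_counts, fg_total, bg_total, kmers in per_k:
        for kmer in kmers:
            fgc = fg_counts.get(kmer, 0)
            bgc = bg_counts.get(kmer, 0)
            p0 = min(1.0, (bgc + 1) / (bg_total + 1))
            p = float(stats.binom.sf(fgc - 1, fg_total, p0)) if fg_total else 1.0
            results.append(
                KmerResult(
                    kmer=kmer,
                    k=k,
                    fg_count=fgc,
                    bg_count=bgc,
                    fg_total=fg_total,
                    bg_total=bg_total,
                    p_value=p,
                    e_value=p * n_tested,
                )
            )
    results.sort(key=lambda r: (r.e_value, r.kmer))
    return results
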
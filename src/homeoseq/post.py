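"""Post-hoc utilities: novel-contig filtering, N50, variant depth filter,
and the mapping-ratio vs genetic-distance correlation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class ContigHit:
    """Best reference hit of one assembled contig (identity as a fraction)."""

    contig_id: str
    length: int
    best_identity: float
    has_hit: bool = True

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("contig length must be >= 1")
        if self.has_hit and not (0.0 <= self.best_identity <= 1.0):
            raise ValueError("identity must lie in [0, 1]")


@dataclass(frozen=True)
class VariantRecord:
    position: int
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def read_blast6(path: str | Path) -> pd.DataFrame:
    """Load a 12-column tabular alignment hit file (blast outfmt 6 style)."""
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, header=None)


def contig_hits_from_blast6(
    hits: pd.DataFrame, contig_lengths: dict[str, int]
) -> list[ContigHit]:
    """Summarize a hit table to one best-identity record per contig."""
    best = hits.groupby("qseqid")["pident"].max() / 100.0
    out = []
    for cid, length in contig_lengths.items():
        if cid in best.index:
            out.append(ContigHit(cid, length, float(best[cid]), True))
        else:
            out.append(ContigHit(cid, length, 0.0, False))
    return out


def filter_novel_contigs(
    hits: Sequence[ContigHit], identity_threshold: float = 0.70
) -> list[str]:
    """Keep contigs considered novel relative to the reference.

    A contig is discarded iff its best identity strictly exceeds the
    threshold; no-hit contigs are always kept.
    """
    if not (0.0 < identity_threshold < 1.0):
        raise ValueError("identity threshold must lie in (0, 1)")
    return [
        h.contig_id
        for h in hits
        if (not h.has_hit) or h.best_identity <= identity_threshold
    ]


def n50(lengths: Sequence[int]) -> int:
    """Largest L with contigs of length >= L summing to >= half the total."""
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length list is undefined")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


def filter_variants(
    variants: Sequence[VariantRecord], max_depth: int = 100
) -> list[VariantRecord]:
    """Keep variants with read depth strictly below ``max_depth``."""
    return [v for v in variants if v.depth < max_depth]


def ratio_distance_correlation(
    mapping_ratios: Sequence[float], distances: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and two-sided t-based p between mapping ratio and distance.

    Zero variance in either vector makes r undefined: returns (nan, nan).
    """
    x = np.asarray(mapping_ratios, dtype=float)
    y = np.asarray(distances, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
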
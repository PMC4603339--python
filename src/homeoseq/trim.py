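"""Read cleaning: adapter clipping and phred-quality trimming.

Implements the classic rule set for short-read cleanup — adapter clip,
LEADING/TRAILING low-quality base removal, sliding-window cut and a
minimum-length filter — as pure functions on (sequence, quality) tuples.
The whole rule pipeline is iterated to a fixed point, which makes
trimming idempotent by construction (a single pass is not: cutting a
low-quality tail can expose a fresh adapter suffix).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

# Standard Illumina TruSeq read-through adapters (R1, R2); used when the
# bundled data file is unavailable.
_TRUSEQ_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
_TRUSEQ_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"


def default_adapters() -> tuple[str, ...]:
    """TruSeq adapter sequences bundled with the package."""
    try:
        text = (
            resources.files("homeoseq.data").joinpath("truseq_adapters.fa")
        ).read_text()
        seqs = [
            line.strip()
            for line in text.splitlines()
            if line.strip() and not line.startswith(">")
        ]
        if seqs:
            return tuple(seqs)
    except (FileNotFoundError, ModuleNotFoundError):  # pragma: no cover
        pass
    return (_TRUSEQ_R1, _TRUSEQ_R2)  # pragma: no cover


@dataclass(frozen=True)
class TrimParams:
    """Cleaning thresholds (defaults: LEADING:3 TRAILING:3 SLIDINGWINDOW:4:20 MINLEN:40)."""

    leading_q: int = 3
    trailing_q: int = 3
    window_len: int = 4
    window_q: float = 20.0
    min_len: int = 40
    adapters: tuple[str, ...] = field(default_factory=default_adapters)
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.leading_q < 0 or self.trailing_q < 0 or self.window_q < 0:
            raise ValueError("quality thresholds must be >= 0")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.phred_offset not in (33, 64):
            raise ValueError("phred_offset must be 33 or 64")


DISCARDED = None  # sentinel: read failed MINLEN


def _clip_adapter(seq: str, adapters: Sequence[str], min_overlap: int = 8,
                  max_mismatch: int = 1) -> int:
    """Return the clip index (length to keep) after adapter-suffix search.

    Looks for the longest read suffix matching an adapter prefix with at
    least ``min_overlap`` bases and at most ``max_mismatch`` mismatches;
    clips at its start.  Returns len(seq) when nothing matches.
    """
    n = len(seq)
    for start in range(0, n - min_overlap + 1):  # earliest start = longest suffix
        suffix = seq[start:]
        for ad in adapters:
            overlap = min(len(suffix), len(ad))
            if overlap < min_overlap:
                continue
            mism = sum(
                1 for a, b in zip(suffix[:overlap], ad[:overlap]) if a != b
            )
            if mism <= max_mismatch:
                return start
    return n


def _window_cut(quals: Sequence[int], window_len: int, window_q: float) -> int:
    """Index of the first failing sliding window's start, or len(quals)."""
    n = len(quals)
    for start in range(0, n - window_len + 1):
        window = quals[start:start + window_len]
        if sum(window) / window_len < window_q:
            return start
    return n


def _trim_once(seq: str, quals: list[int], params: TrimParams):
    # adapter clip
    if params.adapters:
        cut = _clip_adapter(seq, params.adapters)
        seq, quals = seq[:cut], quals[:cut]
    # LEADING
    i = 0
    while i < len(seq) and quals[i] < params.leading_q:
        i += 1
    seq, quals = seq[i:], quals[i:]
    # TRAILING
    j = len(seq)
    while j > 0 and quals[j - 1] < params.trailing_q:
        j -= 1
    seq, quals = seq[:j], quals[:j]
    # SLIDINGWINDOW
    cut = _window_cut(quals, params.window_len, params.window_q)
    seq, quals = seq[:cut], quals[:cut]
    return seq, quals


def trim_read(
    seq: str, quals: Sequence[int], params: TrimParams | None = None
) -> tuple[str, list[int]] | None:
    """Clean one read; return (seq, quals) or ``DISCARDED`` (None).

    Rules apply in order adapter → LEADING → TRAILING → SLIDINGWINDOW,
    iterated until the read stops shrinking, then MINLEN.  Returned
    qualities stay aligned with the returned sequence.
    """
    if params is None:
        params = TrimParams()
    if len(seq) != len(quals):
        raise ValueError(
            f"sequence length {len(seq)} != quality length {len(quals)}"
        )
    quals = list(quals)
    while True:
        new_seq, new_quals = _trim_once(seq, quals, params)
        if len(new_seq) == len(seq):
            break
        seq, quals = new_seq, new_quals
    if len(seq) < params.min_len:
        return DISCARDED
    return seq, quals


class PairOutcome(str, enum.Enum):
    PAIR = "PAIR"
    SINGLETON = "SINGLETON"
    DROPPED = "DROPPED"


@dataclass
class TrimmedPair:
    outcome: PairOutcome
    mate1: tuple[str, list[int]] | None
    mate2: tuple[str, list[int]] | None
    surviving_mate: int | None = None  # set for singletons


def trim_pair(
    pair: tuple[tuple[str, Sequence[int]], tuple[str, Sequence[int]]],
    params: TrimParams | None = None,
) -> TrimmedPair:
    """Clean both mates of a pair, tracking pair/singleton/dropped status."""
    (s1, q1), (s2, q2) = pair
    r1 = trim_read(s1, q1, params)
    r2 = trim_read(s2, q2, params)
    if r1 is not DISCARDED and r2 is not DISCARDED:
        return TrimmedPair(PairOutcome.PAIR, r1, r2)
    if r1 is not DISCARDED:
        return TrimmedPair(PairOutcome.SINGLETON, r1, None, surviving_mate=1)
    if r2 is not DISCARDED:
        return TrimmedPair(PairOutcome.SINGLETON, None, r2, surviving_mate=2)
    return TrimmedPair(PairOutcome.DROPPED, None, None)


@dataclass
class TrimSummary:
    """Library-level accounting: total vs clean reads, as in a run summary table."""

    total_pairs: int = 0
    kept_pairs: int = 0
    singletons: int = 0
    dropped_pairs: int = 0

    @property
    def total_reads(self) -> int:
        return 2 * self.total_pairs

    @property
    def clean_reads(self) -> int:
        return 2 * self.kept_pairs + self.singletons

    @property
    def dropped_reads(self) -> int:
        return self.total_reads - self.clean_reads

    def as_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "clean_reads": self.clean_reads,
            "kept_pairs": self.kept_pairs,
            "singletons": self.singletons,
            "dropped_pairs": self.dropped_pairs,
        }


def trim_library(pairs, params: TrimParams | None = None):
    """Trim an iterable of read pairs; yield results while accumulating a summary.

    Returns (list of (read_id, TrimmedPair), TrimSummary).  ``pairs`` is an
    iterable of (read_id, (seq1, quals1), (seq2, quals2)).
    """
    summary = TrimSummary()
    out = []
    for read_id, m1, m2 in pairs:
        res = trim_pair((m1, m2), params)
        summary.total_pairs += 1
        if res.outcome is PairOutcome.PAIR:
            summary.kept_pairs += 1
        elif res.outcome is PairOutcome.SINGLETON:
            summary.singletons += 1
        else:
            summary.dropped_pairs += 1
        out.append((read_id, res))
    return out, summary


def decode_quals(qual_string: str, phred_offset: int = 33) -> list[int]:
    return [ord(c) - phred_offset for c in qual_string]


def encode_quals(quals: Sequence[int], phred_offset: int = 33) -> str:
    return "".join(chr(q + phred_offset) for q in quals)
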
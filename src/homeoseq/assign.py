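"""Subgenome read arbitration for allopolyploid references.

An allotetraploid (AABB) transcriptome aligned separately against its A and
B subgenome references yields, for every read pair, up to two competing
alignments.  This module decides which subgenome each fragment belongs to
using the sum of mapping quality scores (MQS) of its mates, with two
priority rules applied before the score comparison:

1. pair status — fragments aligned as a proper read pair outrank
   singletons (only one mate aligned), which outrank unmapped;
2. uniqueness — fragments whose every aligned mate has a single best hit
   outrank ambiguously mapped ones;
3. MQS — the subgenome with the larger MAPQ sum wins.

A fragment tied on all three criteria is discarded rather than assigned,
so no read is counted twice and no coin-flips enter the quantification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam


class Status(enum.IntEnum):
    """Alignment status of a fragment on one subgenome, ordered by priority."""

    UNMAPPED = 0
    SINGLETON = 1
    PAIR = 2


class Outcome(str, enum.Enum):
    ASSIGN_A = "ASSIGN_A"
    ASSIGN_B = "ASSIGN_B"
    DISCARD_TIE = "DISCARD_TIE"
    UNMAPPED = "UNMAPPED"


class Rule(str, enum.Enum):
    PAIR_PRIORITY = "PAIR_PRIORITY"
    UNIQUE_PRIORITY = "UNIQUE_PRIORITY"
    MQS = "MQS"
    ONLY_ONE = "ONLY_ONE"
    NONE = "NONE"


@dataclass(frozen=True)
class AlignmentRecord:
    """One primary alignment of one mate against one subgenome."""

    read_id: str
    mate: int  # 1 or 2
    subgenome: str  # "A" or "B"
    mapped: bool
    pos: int | None = None  # 1-based leftmost coordinate
    mapq: int | None = None
    n_best_hits: int | None = None  # >=1 when mapped
    proper_pair: bool = False

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        if self.mapped:
            if self.mapq is None or self.pos is None:
                raise ValueError("mapped record needs pos and mapq")
            if self.n_best_hits is not None and self.n_best_hits < 1:
                raise ValueError("n_best_hits must be >= 1 when mapped")
        else:
            if self.mapq is not None or self.pos is not None:
                raise ValueError("unmapped record must not carry pos/mapq")


@dataclass(frozen=True)
class FragmentEvidence:
    """Per-fragment, per-subgenome summary consumed by :func:`arbitrate`."""

    read_id: str
    subgenome: str
    status: Status
    mqs_sum: int
    unique: bool

    def __post_init__(self) -> None:
        if self.status is Status.UNMAPPED and self.mqs_sum != 0:
            raise ValueError("unmapped evidence must have mqs_sum == 0")


@dataclass(frozen=True)
class AssignmentDecision:
    read_id: str
    outcome: Outcome
    deciding_rule: Rule


def summarize_fragment(
    records_a: Iterable[AlignmentRecord],
    records_b: Iterable[AlignmentRecord],
) -> tuple[FragmentEvidence, FragmentEvidence]:
    """Collapse a fragment's primary alignments into per-subgenome evidence.

    Status is PAIR iff both mates aligned on that subgenome, SINGLETON iff
    exactly one did; ``mqs_sum`` is the sum of the aligned mates' MAPQ
    values; ``unique`` holds iff every aligned mate has a single best hit.
    """
    records_a = list(records_a)
    records_b = list(records_b)
    ids = {r.read_id for r in records_a} | {r.read_id for r in records_b}
    if len(ids) > 1:
        raise ValueError(f"records mix read ids: {sorted(ids)}")
    read_id = ids.pop() if ids else ""
    out = []
    for subgenome, records in (("A", records_a), ("B", records_b)):
        mapped = [r for r in records if r.mapped]
        mates = [r.mate for r in mapped]
        if len(mates) != len(set(mates)):
            raise ValueError(
                f"duplicate primary record for a mate on subgenome {subgenome}"
            )
        if len(mapped) == 2:
            status = Status.PAIR
        elif len(mapped) == 1:
            status = Status.SINGLETON
        else:
            status = Status.UNMAPPED
        mqs = sum(int(r.mapq) for r in mapped)
        unique = bool(mapped) and all(
            (r.n_best_hits or 1) == 1 for r in mapped
        )
        out.append(
            FragmentEvidence(
                read_id=read_id,
                subgenome=subgenome,
                status=status,
                mqs_sum=mqs,
                unique=unique,
            )
        )
    return out[0], out[1]


def arbitrate(ev_a: FragmentEvidence, ev_b: FragmentEvidence) -> AssignmentDecision:
    """Decide a fragment's subgenome of origin from its two evidence records.

    Lexicographic comparison: pair status, then uniqueness, then MQS sum.
    A strict winner at the first differing criterion is assigned with that
    criterion as the deciding rule; a full tie is discarded; a fragment
    aligned on one side only is assigned by ONLY_ONE; aligned on neither,
    it stays UNMAPPED.  Total function: every evidence pair gets a decision.
    """
    if ev_a.read_id != ev_b.read_id:
        raise ValueError("evidence records disagree on read_id")
    rid = ev_a.read_id
    a_mapped = ev_a.status is not Status.UNMAPPED
    b_mapped = ev_b.status is not Status.UNMAPPED
    if not a_mapped and not b_mapped:
        return AssignmentDecision(rid, Outcome.UNMAPPED, Rule.NONE)
    if a_mapped != b_mapped:
        outcome = Outcome.ASSIGN_A if a_mapped else Outcome.ASSIGN_B
        return AssignmentDecision(rid, outcome, Rule.ONLY_ONE)
    for rule, key_a, key_b in (
        (Rule.PAIR_PRIORITY, int(ev_a.status), int(ev_b.status)),
        (Rule.UNIQUE_PRIORITY, int(ev_a.unique), int(ev_b.unique)),
        (Rule.MQS, ev_a.mqs_sum, ev_b.mqs_sum),
    ):
        if key_a > key_b:
            return AssignmentDecision(rid, Outcome.ASSIGN_A, rule)
        if key_b > key_a:
            return AssignmentDecision(rid, Outcome.ASSIGN_B, rule)
    return AssignmentDecision(rid, Outcome.DISCARD_TIE, Rule.MQS)


def mapping_ratio(mapped: int, clean: int) -> float:
    """Percent of clean reads mapped, rounded half-up to one decimal."""
    if clean <= 0:
        raise ValueError("clean read count must be positive")
    if mapped > clean:
        raise ValueError("mapped cannot exceed clean")
    pct = Decimal(100 * mapped) / Decimal(clean)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class MappingStats:
    """Per-library arbitration accounting, mirroring a mapping-summary table."""

    total_fragments: int = 0
    assigned_a: int = 0
    assigned_b: int = 0
    ties: int = 0
    unmapped: int = 0
    missing: int = 0
    rules: dict = field(default_factory=dict)

    @property
    def assigned(self) -> int:
        return self.assigned_a + self.assigned_b

    def ratio_a(self) -> float:
        return mapping_ratio(self.assigned_a, self.total_fragments)

    def ratio_b(self) -> float:
        return mapping_ratio(self.assigned_b, self.total_fragments)

    def combined_ratio(self) -> float:
        return mapping_ratio(self.assigned, self.total_fragments)

    def tie_fraction(self) -> float:
        return self.ties / self.total_fragments if self.total_fragments else 0.0

    def as_dict(self) -> dict:
        d = {
            "total_fragments": self.total_fragments,
            "assigned_A": self.assigned_a,
            "assigned_B": self.assigned_b,
            "ties": self.ties,
            "unmapped": self.unmapped,
            "ratio_A_pct": self.ratio_a() if self.total_fragments else 0.0,
            "ratio_B_pct": self.ratio_b() if self.total_fragments else 0.0,
            "combined_ratio_pct": (
                self.combined_ratio() if self.total_fragments else 0.0
            ),
        }
        d.update({f"rule_{k.value}": v for k, v in self.rules.items()})
        return d


def _iter_name_groups(path: str | Path) -> Iterator[tuple[str, list]]:
    """Yield (read_id, primary segments) per name group of a SAM/BAM file.

    Requires name-grouped input: revisiting a name after an intervening one
    raises, with a hint to name-sort.
    """
    seen: set[str] = set()
    current: str | None = None
    bucket: list = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            name = seg.query_name
            if name != current:
                if current is not None:
                    yield current, bucket
                if name in seen:
                    raise ValueError(
                        f"{path}: read {name} reappears after another name; "
                        "input must be name-grouped (samtools sort -n)"
                    )
                seen.add(name)
                current = name
                bucket = []
            bucket.append(seg)
    if current is not None:
        yield current, bucket


def _segment_to_record(seg, subgenome: str) -> AlignmentRecord:
    mate = 1 if (not seg.is_paired or seg.is_read1) else 2
    if seg.is_unmapped:
        return AlignmentRecord(seg.query_name, mate, subgenome, mapped=False)
    nh = seg.get_tag("NH") if seg.has_tag("NH") else 1
    return AlignmentRecord(
        read_id=seg.query_name,
        mate=mate,
        subgenome=subgenome,
        mapped=True,
        pos=seg.reference_start + 1,
        mapq=seg.mapping_quality,
        n_best_hits=int(nh),
        proper_pair=seg.is_proper_pair,
    )


def partition_library(
    sam_a: str | Path,
    sam_b: str | Path,
    unique_only: bool = False,
    out_a: str | Path | None = None,
    out_b: str | Path | None = None,
) -> tuple[dict[str, AssignmentDecision], MappingStats]:
    """Arbitrate every fragment of a library between two subgenome SAMs.

    Both inputs must be name-grouped over the same read universe.  With
    ``unique_only`` set, ambiguously mapped records (NH tag > 1) are
    dropped before evidence building, emulating a report-unique-only
    aligner flag.  Winning fragments' records are written to the matching
    output SAM when provided; ties and unmapped fragments to neither.
    """
    groups_a = dict(_iter_name_groups(sam_a))
    groups_b = dict(_iter_name_groups(sam_b))
    all_ids = sorted(set(groups_a) | set(groups_b))

    writers = {}
    try:
        if out_a is not None:
            with pysam.AlignmentFile(str(sam_a), check_sq=False) as fh:
                writers["A"] = pysam.AlignmentFile(
                    str(out_a), "w", header=fh.header
                )
        if out_b is not None:
            with pysam.AlignmentFile(str(sam_b), check_sq=False) as fh:
                writers["B"] = pysam.AlignmentFile(
                    str(out_b), "w", header=fh.header
                )

        stats = MappingStats()
        decisions: dict[str, AssignmentDecision] = {}
        for rid in all_ids:
            segs_a = groups_a.get(rid)
            segs_b = groups_b.get(rid)
            if segs_a is None and segs_b is None:  # pragma: no cover
                stats.missing += 1
                continue
            if segs_a is None or segs_b is None:
                stats.missing += 1
            recs_a = [_segment_to_record(s, "A") for s in (segs_a or [])]
            recs_b = [_segment_to_record(s, "B") for s in (segs_b or [])]
            if unique_only:
                recs_a = [_drop_ambiguous(r) for r in recs_a]
                recs_b = [_drop_ambiguous(r) for r in recs_b]
            ev_a, ev_b = summarize_fragment(recs_a, recs_b)
            ev_a = FragmentEvidence(rid, "A", ev_a.status, ev_a.mqs_sum, ev_a.unique)
            ev_b = FragmentEvidence(rid, "B", ev_b.status, ev_b.mqs_sum, ev_b.unique)
            decision = arbitrate(ev_a, ev_b)
            decisions[rid] = decision
            stats.total_fragments += 1
            stats.rules[decision.deciding_rule] = (
                stats.rules.get(decision.deciding_rule, 0) + 1
            )
            if decision.outcome is Outcome.ASSIGN_A:
                stats.assigned_a += 1
                if "A" in writers and segs_a:
                    for s in segs_a:
                        writers["A"].write(s)
            elif decision.outcome is Outcome.ASSIGN_B:
                stats.assigned_b += 1
                if "B" in writers and segs_b:
                    for s in segs_b:
                        writers["B"].write(s)
            elif decision.outcome is Outcome.DISCARD_TIE:
                stats.ties += 1
            else:
                stats.unmapped += 1
    finally:
        for w in writers.values():
            w.close()
    return decisions, stats


def _drop_ambiguous(rec: AlignmentRecord) -> AlignmentRecord:
    if rec.mapped and (rec.n_best_hits or 1) > 1:
        return AlignmentRecord(rec.read_id, rec.mate, rec.subgenome, mapped=False)
    return rec


def assignment_accuracy(
    decisions: Mapping[str, AssignmentDecision],
    truth_origin: Mapping[str, str],
) -> tuple[float, int]:
    """Fraction of assigned fragments matching their true subgenome.

    Returns (accuracy, n_assigned); discarded ties and unmapped fragments
    are excluded from the denominator, as only assigned reads flow into
    quantification.
    """
    n_assigned = 0
    n_correct = 0
    for rid, dec in decisions.items():
        if dec.outcome is Outcome.ASSIGN_A:
            call = "A"
        elif dec.outcome is Outcome.ASSIGN_B:
            call = "B"
        else:
            continue
        n_assigned += 1
        if truth_origin.get(rid) == call:
            n_correct += 1
    return (n_correct / n_assigned if n_assigned else float("nan")), n_assigned
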
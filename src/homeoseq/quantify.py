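"""Fragment-per-gene counting of assigned alignments against a GTF.

A fragment (read pair or singleton) increments exactly one gene if and
only if every aligned base of its primary records falls inside that
single gene's exon union; fragments touching zero or two-plus genes are
tallied as unassigned.  A pair counts once, never twice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .assign import _iter_name_groups

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


@dataclass(frozen=True)
class GeneModel:
    """A gene as a union of 1-based inclusive exon intervals on one contig."""

    gene_id: str
    contig: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    subgenome: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene needs at least one exon")
        for s, e in self.exons:
            if e < s or s < 1:
                raise ValueError(f"{self.gene_id}: bad exon interval ({s},{e})")

    def covers(self, start: int, end: int) -> bool:
        """True iff every base of [start, end] (1-based incl.) is exonic."""
        pos = start
        for s, e in sorted(self.exons):
            if pos < s:
                return False
            if pos <= e:
                pos = e + 1
            if pos > end:
                return True
        return pos > end


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GTF, merging exon features per gene_id."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            m = _GENE_ID_RE.search(fields[8])
            if not m:
                raise ValueError(f"GTF line without gene_id attribute: {line!r}")
            gid = m.group(1)
            exons.setdefault(gid, []).append((int(fields[3]), int(fields[4])))
            meta.setdefault(gid, (fields[0], fields[6]))
    return [
        GeneModel(gid, meta[gid][0], tuple(sorted(exons[gid])), meta[gid][1])
        for gid in exons
    ]


@dataclass
class CountSummary:
    assigned: int = 0
    unassigned_no_feature: int = 0
    unassigned_ambiguous: int = 0
    unmapped: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def count_fragments(
    sam_path: str | Path,
    gene_models: Sequence[GeneModel],
    strict_contigs: bool = True,
) -> tuple[pd.Series, CountSummary]:
    """Count fragments per gene from a name-grouped, pre-assigned SAM.

    Returns (counts indexed by gene_id, summary).  Raises if the SAM
    reference dictionary names contigs absent from the gene models (and
    vice versa counting simply finds no feature).
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for gm in gene_models:
        by_contig.setdefault(gm.contig, []).append(gm)
    counts = pd.Series(
        0, index=pd.Index([g.gene_id for g in gene_models], name="gene_id")
    )
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        sam_contigs = list(fh.references)
    if strict_contigs:
        missing = [c for c in sam_contigs if c not in by_contig]
        if missing:
            raise ValueError(
                "SAM reference dictionary contigs missing from gene models: "
                + ", ".join(missing[:10])
            )

    summary = CountSummary()
    for _, segs in _iter_name_groups(sam_path):
        mapped = [s for s in segs if not s.is_unmapped]
        if not mapped:
            summary.unmapped += 1
            continue
        gene_sets = []
        for seg in mapped:
            genes = set()
            for bstart, bend in seg.get_blocks():  # 0-based half-open
                s1, e1 = bstart + 1, bend
                for gm in by_contig.get(seg.reference_name, ()):  # noqa: B020
                    if gm.covers(s1, e1):
                        genes.add(gm.gene_id)
            gene_sets.append(genes)
        common = set.intersection(*gene_sets) if gene_sets else set()
        if any(len(g) == 0 for g in gene_sets):
            # a record whose span is not fully exonic in any single gene
            # makes the whole fragment featureless
            summary.unassigned_no_feature += 1
        elif len(common) == 1:
            counts[common.pop()] += 1
            summary.assigned += 1
        else:
            # mates confined to different genes, or a span inside several
            # overlapping genes: ambiguous either way
            summary.unassigned_ambiguous += 1
    return counts, summary


def build_count_matrix(
    columns: Mapping[str, pd.Series], design: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble per-library count columns into a genes x libraries matrix."""
    mat = pd.DataFrame(columns).fillna(0).astype(int)
    if (mat < 0).any().any():
        raise ValueError("count matrix has negative entries")
    design = pd.Series(design, name="group")
    unknown = [lib for lib in mat.columns if lib not in design.index]
    if unknown:
        raise ValueError(f"libraries missing from design: {unknown}")
    return mat, design.loc[list(mat.columns)]


def expressed_transcript_sets(
    counts: pd.DataFrame,
    design: pd.Series,
    min_count: int = 1,
) -> dict[str, set[str]]:
    """Per-group sets of expressed genes.

    A gene counts as expressed in a group when it reaches ``min_count``
    in at least one of the group's libraries.
    """
    out: dict[str, set[str]] = {}
    for group in design.unique():
        libs = design.index[design == group]
        mask = (counts[list(libs)] >= min_count).any(axis=1)
        out[group] = set(counts.index[mask])
    return out


def venn_regions(sets: Mapping[str, set]) -> dict[str, int]:
    """Sizes of the 7 regions of a three-set Venn diagram.

    Keys name the exclusive regions, e.g. "wild" (only), "wild&landrace"
    (those two but not the third), "wild&landrace&cultivar" (all three).
    """
    names = list(sets)
    if len(names) != 3:
        raise ValueError("venn_regions expects exactly three sets")
    a, b, c = (sets[n] for n in names)
    regions = {
        names[0]: a - b - c,
        names[1]: b - a - c,
        names[2]: c - a - b,
        f"{names[0]}&{names[1]}": (a & b) - c,
        f"{names[0]}&{names[2]}": (a & c) - b,
        f"{names[1]}&{names[2]}": (b & c) - a,
        f"{names[0]}&{names[1]}&{names[2]}": a & b & c,
    }
    return {k: len(v) for k, v in regions.items()}
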
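"""Miniature allotetraploid study generator with known truth.

Builds everything the downstream stages consume — two diverged homoeologous
subgenome references with single-exon gene models, negative-binomial
expression for three genotype groups with planted up/down-regulated genes,
2 x read-length paired reads with positional quality decay, per-subgenome
SAM alignments from a deliberately simple exact-seed fixture aligner — plus
a truth table recording each read's subgenome of origin and each gene's
planted differential-expression status, so accuracy and FDR can be
measured exactly.

The generative model: each homoeolog pair shares an ancestral transcript;
the B copy is derived by iid substitutions at the configured divergence
rate.  A gene pair's expression mean is split evenly between the two
copies, and fragments pick a copy uniformly, emulating balanced homoeolog
expression.  Counts are NB(mean, dispersion) with per-library size
factors; planted genes have their landrace and cultivar group means scaled
by 2^(true log2FC) relative to wild.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = dict(zip("ACGTN", "TGCAN"))

# fixed stage tags mixed into the seed so each stage has an independent,
# reproducible stream
_SEED_SUBGENOMES = 11
_SEED_COUNTS = 23
_SEED_READS = 37


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated study.

    Defaults mirror a three-group (wild, landrace, cultivar), two-replicate
    design sequenced as 2 x 101 bp paired reads; divergence 0.05
    substitutions/site approximates transcript-level homoeolog divergence
    in an allotetraploid of ~0.5 My hybrid origin.
    """

    n_genes: int = 200
    gene_length: tuple[int, int] = (600, 2000)
    homoeolog_divergence: float = 0.05
    groups: tuple[str, ...] = ("wild", "landrace", "cultivar")
    replicates_per_group: int = 2
    reads_per_library: int = 5000
    read_length: int = 101
    fragment_length: tuple[float, float] = (300.0, 30.0)
    planted_up: Mapping[str, float] = field(default_factory=dict)
    planted_down: Mapping[str, float] = field(default_factory=dict)
    nb_dispersion: float = 0.1
    mean_expression: tuple[float, float] = (20.0, 2000.0)
    seq_error_rate: float = 0.001
    phred_offset: int = 33
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.replicates_per_group,
               self.reads_per_library, self.read_length) <= 0:
            raise ValueError("all counts must be > 0")
        if not (0.0 <= self.homoeolog_divergence <= 0.25):
            raise ValueError(
                "homoeolog_divergence must lie in [0, 0.25]; "
                f"got {self.homoeolog_divergence}"
            )
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("planted_up and planted_down must be disjoint")
        if self.read_length > self.gene_length[0]:
            raise ValueError("read_length must not exceed min gene length")
        if any(lfc <= 0 for lfc in self.planted_up.values()):
            raise ValueError("planted_up effects must be positive log2FCs")
        if any(lfc <= 0 for lfc in self.planted_down.values()):
            raise ValueError("planted_down effects must be positive magnitudes")
        if self.phred_offset not in (33, 64):
            raise ValueError("phred_offset must be 33 or 64")

    @property
    def libraries(self) -> list[str]:
        return [
            f"{g}_{r + 1}"
            for g in self.groups
            for r in range(self.replicates_per_group)
        ]

    @property
    def design(self) -> pd.Series:
        return pd.Series(
            {lib: lib.rsplit("_", 1)[0] for lib in self.libraries},
            name="group",
        )


def pair_id(i: int) -> str:
    return f"g{i:04d}"


def copy_id(i: int, subgenome: str) -> str:
    return f"Ta{subgenome}_g{i:04d}"


def auto_plant(
    n_genes: int, n_up: int, n_down: int, effect_lfc: float = 2.0
) -> tuple[dict[str, float], dict[str, float]]:
    """Deterministically pick the first genes as planted up/down sets."""
    if n_up + n_down > n_genes:
        raise ValueError("cannot plant more genes than exist")
    up = {pair_id(i): effect_lfc for i in range(n_up)}
    down = {pair_id(i): effect_lfc for i in range(n_up, n_up + n_down)}
    return up, down


@dataclass
class TruthTable:
    """Ground truth of a simulated study."""

    read_origin: dict[str, str]  # read id -> "A" | "B"
    read_gene: dict[str, str]  # read id -> homoeolog copy id
    gene_de_status: pd.DataFrame  # index pair id; columns status, true_log2fc

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        rows = [
            (rid, self.read_gene[rid], sub)
            for rid, sub in sorted(self.read_origin.items())
        ]
        pd.DataFrame(rows, columns=["read_id", "gene_id", "subgenome"]).to_csv(
            outdir / "truth_read_origin.tsv", sep="\t", index=False
        )
        self.gene_de_status.to_csv(
            outdir / "truth_gene_status.tsv", sep="\t", index_label="gene_id"
        )


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    out = seq.copy()
    if rate <= 0:
        return out
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def simulate_subgenomes(
    cfg: SimConfig,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Generate homoeologous A and B references and their gene models.

    Each gene is one single-exon transcript on its own contig; the B copy
    differs from the A copy by iid substitutions at the configured
    divergence.  Returns (ref_A, ref_B, gene_models); gene model
    coordinates are 1-based inclusive.
    """
    rng = np.random.default_rng([_SEED_SUBGENOMES, cfg.rng_seed])
    lo, hi = cfg.gene_length
    ref_a: dict[str, str] = {}
    ref_b: dict[str, str] = {}
    models = []
    for i in range(cfg.n_genes):
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_seq(rng, length)
        seq_b = _mutate(rng, ancestor, cfg.homoeolog_divergence)
        ca, cb = copy_id(i, "A"), copy_id(i, "B")
        ref_a[ca] = ancestor.tobytes().decode()
        ref_b[cb] = seq_b.tobytes().decode()
        models.append((ca, ca, "A", 1, length, "+", pair_id(i)))
        models.append((cb, cb, "B", 1, length, "+", pair_id(i)))
    gene_models = pd.DataFrame(
        models,
        columns=["gene_id", "contig", "subgenome", "start", "end", "strand",
                 "pair_id"],
    )
    return ref_a, ref_b, gene_models


def simulate_counts(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Draw the per-library NB expression matrix at homoeolog-pair level.

    Returns (counts, design, truth_de, size_factors): counts has one row
    per homoeolog pair and one column per library; truth_de records each
    pair's planted status (up/down/null) and true log2 fold change of the
    domesticated groups relative to wild.
    """
    rng = np.random.default_rng([_SEED_COUNTS, cfg.rng_seed])
    genes = [pair_id(i) for i in range(cfg.n_genes)]
    unknown = (set(cfg.planted_up) | set(cfg.planted_down)) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in simulation: {sorted(unknown)}")
    lo, hi = cfg.mean_expression
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_genes))
    lfc = np.zeros(cfg.n_genes)
    status = np.array(["null"] * cfg.n_genes, dtype=object)
    for g, eff in cfg.planted_up.items():
        i = genes.index(g)
        lfc[i], status[i] = eff, "up"
    for g, eff in cfg.planted_down.items():
        i = genes.index(g)
        lfc[i], status[i] = -eff, "down"

    libraries = cfg.libraries
    size_factors = pd.Series(
        np.exp(rng.normal(0.0, 0.1, size=len(libraries))), index=libraries
    )
    cols = {}
    for lib in libraries:
        group = cfg.design[lib]
        mult = np.where(group == "wild", 1.0, 2.0 ** lfc)
        mean = base * mult * size_factors[lib]
        if cfg.nb_dispersion > 0:
            r = 1.0 / cfg.nb_dispersion
            p = r / (r + mean)
            cols[lib] = rng.negative_binomial(r, p)
        else:
            cols[lib] = rng.poisson(mean)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    truth_de = pd.DataFrame(
        {"status": status, "true_log2fc": lfc},
        index=pd.Index(genes, name="gene_id"),
    )
    return counts, cfg.design, truth_de, size_factors


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    quals1: list[int]
    seq2: str
    quals2: list[int]


def _draw_quals(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Mean phred declining linearly Q38 -> Q22 along the read, jitter sd 3."""
    mean = np.linspace(38.0, 22.0, length)
    q = rng.normal(mean, 3.0, size=(n, length))
    return np.clip(np.rint(q), 2, 40).astype(np.int16)


def simulate_reads(
    cfg: SimConfig,
    refs: tuple[dict[str, str], dict[str, str]],
    gene_models: pd.DataFrame,
    expression: pd.DataFrame,
) -> tuple[dict[str, list[ReadPair]], TruthTable, int]:
    """Sequence paired reads from the simulated transcripts.

    Each library draws ``reads_per_library`` fragments multinomially in
    proportion to the library's expression column; every fragment picks
    the A or B homoeolog uniformly (recorded in the truth table), mate 2
    is the reverse complement of the fragment's 3' end, qualities decay
    along the read, and substitution errors are injected at
    ``seq_error_rate``.  Returns (reads per library, truth, n_resampled)
    where n_resampled counts fragment-length draws clamped to short
    transcripts.
    """
    rng = np.random.default_rng([_SEED_READS, cfg.rng_seed])
    ref_a, ref_b = refs
    seqs = {**ref_a, **ref_b}
    genes = list(expression.index)
    rl = cfg.read_length
    fl_mean, fl_sd = cfg.fragment_length
    libraries: dict[str, list[ReadPair]] = {}
    read_origin: dict[str, str] = {}
    read_gene: dict[str, str] = {}
    n_resampled = 0

    for lib in expression.columns:
        weights = expression[lib].to_numpy(dtype=float)
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
        probs = weights / weights.sum()
        per_gene = rng.multinomial(cfg.reads_per_library, probs)
        pairs: list[ReadPair] = []
        idx = 0
        for gi, n_frag in enumerate(per_gene):
            if n_frag == 0:
                continue
            pair = genes[gi]
            i = int(pair[1:])
            for _ in range(n_frag):
                sub = "A" if rng.random() < 0.5 else "B"
                gene = f"Ta{sub}_{pair}"
                transcript = seqs[gene]
                tlen = len(transcript)
                flen = int(np.rint(rng.normal(fl_mean, fl_sd)))
                attempts = 0
                while flen > tlen and attempts < 10:
                    flen = int(np.rint(rng.normal(fl_mean, fl_sd)))
                    attempts += 1
                if flen > tlen:
                    n_resampled += 1
                    flen = tlen
                flen = max(flen, rl)
                start = int(rng.integers(0, tlen - flen + 1))
                frag = transcript[start:start + flen]
                rid = f"{lib}:p{idx:06d}"
                idx += 1
                s1 = frag[:rl]
                s2 = revcomp(frag[-rl:])
                q = _draw_quals(rng, 2, rl)
                s1 = _inject_errors(rng, s1, cfg.seq_error_rate)
                s2 = _inject_errors(rng, s2, cfg.seq_error_rate)
                pairs.append(ReadPair(rid, s1, list(q[0]), s2, list(q[1])))
                read_origin[rid] = sub
                read_gene[rid] = gene
        libraries[lib] = pairs

    truth = TruthTable(
        read_origin=read_origin,
        read_gene=read_gene,
        gene_de_status=pd.DataFrame(index=expression.index),
    )
    return libraries, truth, n_resampled


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_study(cfg: SimConfig):
    """Convenience wrapper running the full generative chain.

    Returns (refs, gene_models, counts, design, truth, size_factors) with
    the truth table's gene_de_status filled in.
    """
    ref_a, ref_b, gene_models = simulate_subgenomes(cfg)
    counts, design, truth_de, size_factors = simulate_counts(cfg)
    libraries, truth, _ = simulate_reads(
        cfg, (ref_a, ref_b), gene_models, counts
    )
    truth.gene_de_status = truth_de
    return (ref_a, ref_b), gene_models, libraries, counts, design, truth, size_factors


# ---------------------------------------------------------------------------
# fixture aligner


@dataclass
class Alignment:
    """One mate's best hit against one reference (or an unmapped record)."""

    read_id: str
    mate: int
    paired: bool
    mapped: bool
    seq: str
    quals: list[int]
    contig: str | None = None
    pos: int | None = None  # 1-based
    reverse: bool = False
    mapq: int = 0
    n_best_hits: int = 0
    mismatches: int = 0


class KmerIndex:
    """Exact k-mer index over a reference sequence set."""

    def __init__(self, ref: Mapping[str, str], k: int = 21):
        if not ref:
            raise ValueError("empty reference")
        self.k = k
        self.names = list(ref)
        self.seqs = {n: np.frombuffer(s.encode(), dtype=np.uint8)
                     for n, s in ref.items()}
        index: dict[bytes, list[tuple[str, int]]] = {}
        for name, s in ref.items():
            b = s.encode()
            for i in range(0, len(b) - k + 1):
                index.setdefault(b[i:i + k], []).append((name, i))
        self.index = index


def _candidates(idx: KmerIndex, seq: str, step: int) -> set[tuple[str, int]]:
    k = idx.k
    n = len(seq)
    b = seq.encode()
    cands: set[tuple[str, int]] = set()
    positions = list(range(0, n - k + 1, step))
    if positions and positions[-1] != n - k:
        positions.append(n - k)
    for off in positions:
        for contig, ref_pos in idx.index.get(b[off:off + k], ()):
            diag = ref_pos - off
            if diag >= 0 and diag + n <= len(idx.seqs[contig]):
                cands.add((contig, diag))
    return cands


def align_read(
    idx: KmerIndex,
    seq: str,
    *,
    max_mismatch: int = 10,
    mapq_scale: int = 6,
    seed_step: int = 5,
) -> tuple[str, int, bool, int, int, int] | None:
    """Ungapped best-hit alignment of one read against the index.

    Candidate loci come from exact k-mer seeds in both orientations and
    are scored by mismatch count; loci with more than ``max_mismatch``
    mismatches are rejected.  MAPQ is the score gap between the best and
    second-best locus scaled by ``mapq_scale`` and capped at 60; with a
    single candidate the gap is measured against the acceptance floor
    (max_mismatch + 1), so MAPQ degrades with mismatch count.  Returns
    (contig, pos0, reverse, mapq, n_best, mismatches) or None if unmapped.
    """
    if len(seq) < idx.k:
        return None
    scored: list[tuple[int, str, int, bool]] = []
    for reverse in (False, True):
        s = revcomp(seq) if reverse else seq
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        for contig, pos in _candidates(idx, s, seed_step):
            ref = idx.seqs[contig]
            mism = int((ref[pos:pos + len(arr)] != arr).sum())
            if mism <= max_mismatch:
                scored.append((mism, contig, pos, reverse))
    if not scored:
        return None
    scored.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    best_mism, contig, pos, reverse = scored[0]
    n_best = sum(1 for t in scored if t[0] == best_mism)
    second = scored[1][0] if len(scored) > 1 else max_mismatch + 1
    mapq = min(60, mapq_scale * (second - best_mism))
    return contig, pos, reverse, mapq, n_best, best_mism


def fixture_align(
    fragments: Sequence,
    ref: Mapping[str, str],
    k: int = 21,
    *,
    max_mismatch: int = 10,
    mapq_scale: int = 6,
    seed_step: int = 5,
) -> list[Alignment]:
    """Align read pairs (or singletons) against one subgenome reference.

    ``fragments`` holds ``ReadPair`` objects or ``(read_id, seq, quals)``
    singleton tuples.  Explicitly a testing fixture, not a production
    aligner: exact-seed candidates, ungapped scoring, no indels.
    """
    idx = KmerIndex(ref, k=k)
    out: list[Alignment] = []
    for frag in fragments:
        if isinstance(frag, ReadPair):
            mates = [(1, frag.seq1, frag.quals1), (2, frag.seq2, frag.quals2)]
            rid = frag.read_id
            paired = True
        else:
            rid, seq, quals = frag
            mates = [(1, seq, quals)]
            paired = False
        for mate, seq, quals in mates:
            hit = align_read(
                idx, seq,
                max_mismatch=max_mismatch,
                mapq_scale=mapq_scale,
                seed_step=seed_step,
            )
            if hit is None:
                out.append(Alignment(rid, mate, paired, False, seq, list(quals)))
            else:
                contig, pos, reverse, mapq, n_best, mism = hit
                out.append(Alignment(
                    rid, mate, paired, True, seq, list(quals),
                    contig=contig, pos=pos + 1, reverse=reverse,
                    mapq=mapq, n_best_hits=n_best, mismatches=mism,
                ))
    return out


def write_sam(
    alignments: Sequence[Alignment],
    ref: Mapping[str, str],
    path: str | Path,
    phred_offset: int = 33,
) -> None:
    """Emit alignments as a valid, name-grouped SAM file."""
    import pysam

    names = list(ref)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted", "GO": "query"},
        "SQ": [{"SN": n, "LN": len(ref[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    by_read: dict[str, list[Alignment]] = {}
    order: list[str] = []
    for a in alignments:
        if a.read_id not in by_read:
            order.append(a.read_id)
        by_read.setdefault(a.read_id, []).append(a)

    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rid in order:
            group = sorted(by_read[rid], key=lambda a: a.mate)
            mate_of = {a.mate: a for a in group}
            for a in group:
                other = mate_of.get(2 if a.mate == 1 else 1)
                seg = pysam.AlignedSegment(fh.header)
                seg.query_name = a.read_id
                seq = revcomp(a.seq) if (a.mapped and a.reverse) else a.seq
                quals = a.quals[::-1] if (a.mapped and a.reverse) else a.quals
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in quals)
                )
                flag = 0
                if a.paired:
                    flag |= 0x1
                    flag |= 0x40 if a.mate == 1 else 0x80
                if not a.mapped:
                    flag |= 0x4
                else:
                    if a.reverse:
                        flag |= 0x10
                if a.paired and other is not None:
                    if not other.mapped:
                        flag |= 0x8
                    elif other.reverse:
                        flag |= 0x20
                proper = (
                    a.paired and other is not None and a.mapped
                    and other.mapped and a.contig == other.contig
                    and a.reverse != other.reverse
                )
                if proper:
                    flag |= 0x2
                seg.flag = flag
                if a.mapped:
                    seg.reference_id = tid[a.contig]
                    seg.reference_start = a.pos - 1
                    seg.mapping_quality = a.mapq
                    seg.cigartuples = [(0, len(a.seq))]
                    seg.set_tag("NH", a.n_best_hits)
                    seg.set_tag("NM", a.mismatches)
                else:
                    seg.reference_id = -1
                    seg.reference_start = -1
                    seg.mapping_quality = 0
                if a.paired and other is not None and other.mapped:
                    seg.next_reference_id = tid[other.contig]
                    seg.next_reference_start = other.pos - 1
                    if proper:
                        left = min(a.pos, other.pos)
                        right = max(a.pos + len(a.seq), other.pos + len(other.seq))
                        tlen = right - left
                        seg.template_length = tlen if a.pos <= other.pos else -tlen
                fh.write(seg)


# ---------------------------------------------------------------------------
# writers for the study artifacts


def write_fasta(ref: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(gene_models: pd.DataFrame, path: str | Path) -> None:
    """One exon feature per single-exon gene, gene_id in the attributes."""
    with open(path, "w") as fh:
        for row in gene_models.itertuples():
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(
                f"{row.contig}\thomeoseq\texon\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def write_fastq_pair(
    pairs: Sequence[ReadPair],
    path1: str | Path,
    path2: str | Path,
    phred_offset: int = 33,
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = "".join(chr(q + phred_offset) for q in p.quals1)
            q2 = "".join(chr(q + phred_offset) for q in p.quals2)
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{q2}\n")
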
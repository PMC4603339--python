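"""End-to-end runner: simulate → trim → align → arbitrate → count → test.

Holds the shared configuration object, stage logging, artifact manifest
with checksums, and the conservation assertions that tie the stages
together (clean fragments = assigned + ties + unmapped).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assign, diffexp, quantify, synth, trim

log = logging.getLogger("homeoseq")


@dataclass
class PipelineConfig:
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    trim_params: trim.TrimParams = field(default_factory=trim.TrimParams)
    unique_only: bool = False
    lfc_threshold: float = diffexp.LFC_THRESHOLD
    alpha: float = diffexp.ALPHA_FDR

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or not (0 < self.alpha < 1):
            raise ValueError("DE thresholds must be positive (alpha in (0,1))")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_block = raw.get("sim", {})
        for key in ("gene_length", "fragment_length", "mean_expression", "groups"):
            if key in sim_block and isinstance(sim_block[key], list):
                sim_block[key] = tuple(sim_block[key])
        trim_block = raw.get("trim", {})
        if "adapters" in trim_block and isinstance(trim_block["adapters"], list):
            trim_block["adapters"] = tuple(trim_block["adapters"])
        return cls(
            sim=synth.SimConfig(**sim_block),
            trim_params=trim.TrimParams(**trim_block),
            unique_only=bool(raw.get("unique_only", False)),
            lfc_threshold=float(raw.get("lfc", diffexp.LFC_THRESHOLD)),
            alpha=float(raw.get("alpha", diffexp.ALPHA_FDR)),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage on a fresh synthetic study; return the run report.

    Artifacts (FASTA/GTF/FASTQ/SAM/TSV) are written under ``outdir`` and
    listed with checksums in ``manifest.json``.  Any stage failure leaves
    a FAILED marker naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    stage = "synth"
    try:
        # --- synth -------------------------------------------------------
        (ref_a, ref_b), gene_models, libraries, counts_truth, design, truth, _ = (
            synth.simulate_study(cfg.sim)
        )
        synth.write_fasta(ref_a, outdir / "ref_A.fa")
        synth.write_fasta(ref_b, outdir / "ref_B.fa")
        synth.write_gtf(gene_models, outdir / "genes.gtf")
        truth.write(outdir)
        for lib, pairs in libraries.items():
            synth.write_fastq_pair(
                pairs, outdir / f"{lib}_1.fastq", outdir / f"{lib}_2.fastq",
                phred_offset=cfg.sim.phred_offset,
            )
        report["stages"]["synth"] = {
            "n_genes": cfg.sim.n_genes,
            "libraries": {lib: len(p) for lib, p in libraries.items()},
        }
        log.info("stage=synth libraries=%d genes=%d", len(libraries),
                 cfg.sim.n_genes)

        # --- trim --------------------------------------------------------
        stage = "trim"
        trimmed: dict[str, list] = {}
        trim_stats = {}
        for lib, pairs in libraries.items():
            results, summary = trim.trim_library(
                ((p.read_id, (p.seq1, p.quals1), (p.seq2, p.quals2))
                 for p in pairs),
                cfg.trim_params,
            )
            frags = []
            for rid, res in results:
                if res.outcome is trim.PairOutcome.PAIR:
                    frags.append(synth.ReadPair(
                        rid, res.mate1[0], res.mate1[1],
                        res.mate2[0], res.mate2[1],
                    ))
                elif res.outcome is trim.PairOutcome.SINGLETON:
                    kept = res.mate1 if res.surviving_mate == 1 else res.mate2
                    frags.append((rid, kept[0], kept[1]))
            trimmed[lib] = frags
            trim_stats[lib] = summary.as_dict()
            total = summary.total_reads
            accounted = (2 * summary.kept_pairs + summary.singletons
                         + summary.dropped_reads)
            assert accounted == total, "trim read-conservation violated"
        report["stages"]["trim"] = trim_stats
        log.info("stage=trim libraries=%d", len(trimmed))

        # --- align + arbitrate -------------------------------------------
        stage = "assign"
        mapping = {}
        assigned_sams = {}
        all_decisions = {}
        for lib, frags in trimmed.items():
            aln_a = synth.fixture_align(frags, ref_a)
            aln_b = synth.fixture_align(frags, ref_b)
            sam_a = outdir / f"{lib}_A.sam"
            sam_b = outdir / f"{lib}_B.sam"
            synth.write_sam(aln_a, ref_a, sam_a)
            synth.write_sam(aln_b, ref_b, sam_b)
            out_a = outdir / f"{lib}_assigned_A.sam"
            out_b = outdir / f"{lib}_assigned_B.sam"
            decisions, stats = assign.partition_library(
                sam_a, sam_b, unique_only=cfg.unique_only,
                out_a=out_a, out_b=out_b,
            )
            assert (stats.assigned + stats.ties + stats.unmapped
                    == stats.total_fragments), "partition not exhaustive"
            mapping[lib] = stats.as_dict()
            assigned_sams[lib] = (out_a, out_b)
            all_decisions[lib] = decisions
            log.info(
                "stage=assign lib=%s fragments=%d A=%d B=%d ties=%d unmapped=%d",
                lib, stats.total_fragments, stats.assigned_a,
                stats.assigned_b, stats.ties, stats.unmapped,
            )
        report["stages"]["assign"] = mapping
        acc, n_assigned = assign.assignment_accuracy(
            {k: v for d in all_decisions.values() for k, v in d.items()},
            truth.read_origin,
        )
        report["assignment_accuracy"] = {"accuracy": acc, "n_assigned": n_assigned}

        # --- quantify ----------------------------------------------------
        stage = "quantify"
        models = quantify.read_gtf(outdir / "genes.gtf")
        models_a = [m for m in models if m.contig.startswith("TaA")]
        models_b = [m for m in models if m.contig.startswith("TaB")]
        columns = {}
        count_summaries = {}
        for lib, (sam_a, sam_b) in assigned_sams.items():
            col_a, sum_a = quantify.count_fragments(sam_a, models_a)
            col_b, sum_b = quantify.count_fragments(sam_b, models_b)
            columns[lib] = pd.concat([col_a, col_b])
            count_summaries[lib] = {
                "A": sum_a.as_dict(), "B": sum_b.as_dict(),
            }
        counts, design_used = quantify.build_count_matrix(
            columns, design.to_dict()
        )
        counts.to_csv(outdir / "counts.tsv", sep="\t")
        design_used.to_csv(outdir / "design.tsv", sep="\t")
        report["stages"]["quantify"] = count_summaries

        # --- diffexp -----------------------------------------------------
        stage = "diffexp"
        thresholds = diffexp.Thresholds(cfg.lfc_threshold, cfg.alpha)
        keep = (counts.sum(axis=1) > 0)
        counts_f = counts[keep]
        table = diffexp.results_table(
            counts_f, design_used, thresholds=thresholds
        )
        table.to_csv(outdir / "de_results.tsv", sep="\t")
        res_c = table[["call_C_W"]].rename(columns={"call_C_W": "call"})
        res_l = table[["call_L_W"]].rename(columns={"call_L_W": "call"})
        inter, regions = diffexp.domesticated_vs_wild(res_c, res_l)
        inter.to_csv(outdir / "domesticated_vs_wild.tsv", sep="\t")
        report["stages"]["diffexp"] = {
            "degs_cultivar_vs_wild": int((table["call_C_W"] != "NS").sum()),
            "degs_landrace_vs_wild": int((table["call_L_W"] != "NS").sum()),
            "domesticated_vs_wild": len(inter),
            "venn": regions,
        }
        log.info("stage=diffexp degs_CW=%d degs_LW=%d intersection=%d",
                 report["stages"]["diffexp"]["degs_cultivar_vs_wild"],
                 report["stages"]["diffexp"]["degs_landrace_vs_wild"],
                 len(inter))

        # --- manifest ----------------------------------------------------
        stage = "manifest"
        manifest = {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name not in ("manifest.json", "report.json")
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        report["ok"] = True
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    except Exception as err:
        (outdir / "FAILED").write_text(f"stage={stage}: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return report
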
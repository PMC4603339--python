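# homeoseq

Homoeolog-aware RNA-seq analysis for allotetraploid genomes.

Allotetraploid species such as tetraploid wheat (AABB) carry two diverged
subgenomes whose gene copies — homoeologs — are often >94 % identical.
When a reference is too large to index as a whole, or when homoeolog-level
expression matters, reads are aligned to each subgenome **separately** and
every read pair must then be arbitrated between the two competing
alignments. `homeoseq` implements that arbitration and the analysis chain
around it:

- **`homeoseq.assign`** — the core algorithm: each fragment is assigned to
  the subgenome with the stronger evidence, compared lexicographically by
  (1) pair status (proper pair ≻ singleton ≻ unmapped), (2) uniqueness
  (single best hit ≻ ambiguous), (3) the sum of mapping quality scores
  (MQS) of its mates. Exact ties are discarded rather than guessed.
- **`homeoseq.trim`** — read cleaning (adapter clip, LEADING:3,
  TRAILING:3, SLIDINGWINDOW:4:20, MINLEN:40) as pure functions, iterated
  to a fixed point so trimming is idempotent.
- **`homeoseq.quantify`** — fragment-per-gene counting against a GTF
  (a fragment counts for a gene iff every aligned base lies in that single
  gene's exon union), expressed-gene sets and Venn regions.
- **`homeoseq.diffexp`** — negative-binomial differential expression in
  the classic DESeq-v1 style: median-of-ratios size factors, pooled
  method-of-moments dispersions smoothed by a gamma-family mean–dispersion
  fit (per-gene maximum of fitted and empirical), a conditioned NB-sum
  two-sided test, Benjamini–Hochberg correction, and calls at
  |log2FC| ≥ 1 with FDR ≤ 0.1. Fold changes are unshrunk log2 ratios of
  per-group normalized means, so genes silent in one group report literal
  ±Inf. A direction-consistent intersection combines the cultivar-vs-wild
  and landrace-vs-wild contrasts into a domesticated-vs-wild call.
- **`homeoseq.qpcr`** — standard-curve efficiencies E = 10^(−1/slope) and
  efficiency-corrected ΔΔCt relative quantification,
  RQ = E_target^(−ΔCt_target) / E_endo^(−ΔCt_endo).
- **`homeoseq.post`** — novel-contig identity filtering (discard when best
  identity > 70 %), N50, variant depth filtering (keep depth < 100), and
  the mapping-ratio vs genetic-distance Pearson correlation.
- **`homeoseq.synth`** — a first-class synthetic study generator: two
  homoeologous subgenomes at a configurable divergence, three genotype
  groups × two replicate libraries with planted up/down-regulated genes,
  2 × 101 bp paired reads with positional quality decay, a deliberately
  simple exact-seed fixture aligner, and a truth table that records each
  read's subgenome of origin and each gene's planted status — so
  assignment accuracy and realized FDR can be measured exactly.

## Worked example

Run the whole chain on a small synthetic study (60 homoeolog pairs, six
libraries of 800 read pairs, 12 planted four-fold expression changes):

```python
from homeoseq import synth
from homeoseq.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(sim=synth.SimConfig(
    n_genes=60, reads_per_library=800, rng_seed=42,
    planted_up={synth.pair_id(i): 2.0 for i in range(6)},
    planted_down={synth.pair_id(i): 2.0 for i in range(6, 12)},
))
report = run_pipeline(cfg, "toy_run")
print(report["assignment_accuracy"])
print(report["stages"]["diffexp"])
```

prints

```
{'accuracy': 1.0, 'n_assigned': 4787}
{'degs_cultivar_vs_wild': 7, 'degs_landrace_vs_wild': 6,
 'domesticated_vs_wild': 4,
 'venn': {'cultivar_only': 3, 'landrace_only': 2, 'both': 4,
          'both_direction_consistent': 4}}
```

Every assigned fragment carries its true subgenome label (`accuracy: 1.0`
of 4787 assigned fragments out of 4800 simulated; the remainder are tie
discards), and the domesticated-vs-wild intersection recovers four of the
planted genes — at this shallow depth only the strongest signals clear the
|log2FC| ≥ 1, FDR ≤ 0.1 gate, and all four are genuinely planted.

The same stages are available from the shell:

```sh
homeoseq synth --config sim.yaml --outdir study/
homeoseq assign --sam-a lib_A.sam --sam-b lib_B.sam --out-prefix lib
homeoseq diffexp --counts counts.tsv --design design.tsv --out de.tsv
homeoseq qpcr --ct ct.tsv --target CesA --treatment cultivar --control wild
```

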
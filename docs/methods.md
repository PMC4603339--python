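# Methods

## The arbitration model

Aligning an allotetraploid library to its A and B subgenome references
separately yields, per read pair, at most one primary alignment per mate
per subgenome. `homeoseq.assign` summarizes each side into a
`FragmentEvidence` record — pair status (PAIR / SINGLETON / UNMAPPED), the
sum of the aligned mates' MAPQ values (MQS), and a uniqueness flag (every
aligned mate has a single best hit) — and compares the two sides
lexicographically: pair status first, uniqueness second, MQS last. A
strict winner at the first differing criterion takes the fragment; a full
tie is discarded; a fragment aligned on one side only is assigned by
presence. The three rules are all stated by the underlying methodology,
but their ordering is a design choice of this package: we order them as
listed because pair status is the coarsest (and least noise-sensitive)
signal and MQS the finest, and because a fixed lexicographic order makes
the tie-discard rule well defined. Every decision records which rule
decided it (`deciding_rule`), so the precedence is auditable from output.

Only primary alignment records contribute MAPQ; ambiguity enters through
the hit-count (NH) tag. With `unique_only`, ambiguous records are removed
before evidence building, emulating a report-unique-only aligner flag.
The tie fraction is reported as a diagnostic, never asserted: on realistic
divergence it is a fraction of a percent, but at divergence 0 symmetry
forces every double-mapped fragment into a tie.

Mapping ratios are percentages of clean fragments, rounded half-up to one
decimal — the convention used when comparing against published
per-library accounting tables.

## Negative-binomial differential expression

The test follows the original DESeq (v1) scheme, deliberately, because
its outputs (unshrunk fold changes, literal ±Inf for group-silent genes)
are what per-group baseMean tables print:

- **Size factors** are median-of-ratios: s_j = median over genes with all
  positive counts of count_gj / geometric-mean_g. No rescaling convention
  is applied, so a doubled library splits geometrically (1/√2, √2).
- **Dispersions**: per-gene method of moments on normalized counts with
  within-condition centering, shot noise q·mean(1/s_j) removed, converted
  to α in var = q + αq². The mean–dispersion trend α(q) = a₁ + a₀/q is
  fitted by a gamma-family GLM with identity link; the per-gene value is
  max(empirical, fitted) ("maximum" sharing). With fewer than 10
  informative genes the trend degenerates to the pooled median — the
  gamma fit is unstable on tiny fixtures. The max rule makes the
  estimated-dispersion path conservative by construction; the
  test-calibration checks therefore supply the known simulation
  dispersion (the `dispersions` argument), which isolates the conditioned
  NB-sum test itself, while FDR control of the full estimated-dispersion
  procedure is checked separately on planted-truth simulations.
- **The test** conditions on the total count of the two contrasted groups
  k_S = k_A + k_B. Group sums are modelled as NB with mean q̂·Σs_j and
  variance Σ(s_j q̂ + α s_j² q̂²), where q̂ is the pooled mean of
  normalized counts; the two-sided p-value sums P(a, k_S − a) over all
  splits no more probable than the observed one, normalized over all
  splits. The sum is evaluated exactly (vectorized over the k_S + 1
  splits), which is comfortably fast at desk scale; all-zero genes return
  p = 1.
- **Multiple testing** uses Benjamini–Hochberg step-up (backed by
  statsmodels), with NaN p-values passed through uncalled.
- **Calls**: UP iff log2FC ≥ 1 and adjusted p ≤ 0.1; DOWN symmetric; ±Inf
  passes the magnitude cut. The magnitude reading of the "log2FC ≥ 1"
  cut-off is deliberate: both directions are reported. The
  domesticated-vs-wild set is the direction-consistent intersection of
  the cultivar-vs-wild and landrace-vs-wild calls.

Dispersion pooling uses the "pooled" mode (all replicated conditions
contribute to one per-gene estimate); a per-condition mode was considered
and rejected as unstable at two replicates.

## The synthetic study generator

`homeoseq.synth` emulates the study design the pipeline targets: three
genotype groups (wild, landrace, cultivar) × two replicate libraries,
2 × 101 bp paired reads. Its defaults are the study conditions, not
tuning knobs:

- **Subgenomes**: each homoeolog pair shares an ancestral random
  transcript (length uniform 600–2000 bp); the B copy substitutes each
  site independently at the divergence rate (default 0.05/site,
  approximating transcript-level homoeolog divergence in a tetraploid of
  ~0.5 My hybrid origin). Genes are single-exon, one per contig — enough
  to exercise all counting and arbitration logic while keeping the
  fixture aligner ungapped.
- **Expression**: per-pair means log-uniform over 20–2000; counts
  NB(mean × group multiplier × library size factor, dispersion 0.1);
  size factors lognormal(0, 0.1). Planted genes scale the landrace and
  cultivar means by 2^(log2FC) relative to wild; each group pool is
  treated as a single expression profile (within-pool heterogeneity of
  the two accessions per pool is not modelled).
- **Reads**: fragments multinomial in the library's expression column;
  each fragment picks the A or B copy uniformly (balanced homoeolog
  expression); fragment length N(300, 30) clamped to the transcript
  (clamps counted as resampling warnings); mate 2 is the reverse
  complement of the fragment's 3′ end. Mean phred declines linearly from
  Q38 at base 1 to Q22 at base 101 with N(0, 3) jitter — chosen so
  SLIDINGWINDOW:4:20 trims a realistic minority of tails. Substitution
  errors are injected at 0.1 %/base, independently of the quality string
  (no quality–error coupling). Phred offset defaults to 33 with a 64
  switch.
- **Determinism**: each stage draws from `default_rng([stage_tag, seed])`,
  so identical configurations give byte-identical FASTQ/SAM/TSV output.

What the generator does **not** emulate — splicing and multi-exon
structure, indels, strand-specific protocols, GC and positional coverage
bias, quality-correlated errors, within-pool genotype mixtures — bounds
what passing tests show: they validate the algorithms' correctness and
calibration under the stated generative model, not performance on real
tissue libraries.

## The fixture aligner

`fixture_align` exists to produce valid, controllable SAM input for the
arbitration stage; it is explicitly not a production aligner. Candidate
loci come from exact 21-mer seeds (both orientations, sampled every 5
positions plus the final window) and are scored by ungapped mismatch
count; loci with more than 10 mismatches are rejected. MAPQ is the score
gap between the best and second-best locus scaled by 6 and capped at 60;
when only one candidate exists the gap is measured against the acceptance
floor (11 mismatches), so MAPQ degrades smoothly with mismatch count —
the property the MQS comparison needs in order to separate subgenomes.
Reads matching two loci equally get MAPQ 0 and hit-count 2; reads shorter
than the seed are unmapped. Ties between equally good loci break
deterministically by (contig, position, orientation).

## Trimming semantics

Rules run in the order adapter clip (longest read suffix matching an
adapter prefix over ≥ 8 bases with ≤ 1 mismatch), LEADING, TRAILING,
SLIDINGWINDOW (cut at the start of the first 4-base window with mean
quality < 20), then MINLEN:40. The printed parameter list fixes the
thresholds but not the order; the order chosen follows the common
convention of the trimming tool family these parameters come from. A
single pass of that order is not idempotent — removing a low-quality tail
can expose a fresh adapter-like suffix — so `trim_read` iterates the rule
pipeline to a fixed point, making idempotence a structural guarantee
(typically one extra no-op pass). Adapter sequences default to the
standard Illumina TruSeq pair bundled as a data file.

## qPCR arithmetic

Standard curves are ordinary least squares of Ct on log10 relative input;
efficiency E = 10^(−1/slope) (E = 2 ⇔ slope −3.3219 ⇔ 100 %); a
non-negative slope flags the curve invalid. Relative quantification
averages replicate Cts arithmetically, then computes
RQ = E_target^(−ΔCt_target) / E_endo^(−ΔCt_endo). Group-specific curve
efficiencies are reconciled into one per-gene E as the geometric mean of
the treatment- and control-group values when both exist (a single group's
value, or the perfect-doubling default E = 2, otherwise): the RQ formula
admits only one E per gene, and the geometric mean is the symmetric
choice on the fold-change scale.

## Post-hoc rules

Novel-contig filtering keeps a contig iff it has no reference hit or its
best identity is ≤ 0.70 (the discard rule is strictly greater-than).
Variant filtering keeps records with site depth strictly below 100; the
"maximum read depth" phrase is read as the per-site DP value. N50 is the
largest L such that contigs of length ≥ L sum to at least half the total.
The mapping-ratio correlation is plain Pearson r with the two-sided
t-based p; zero variance returns NaN rather than a fabricated value.

## Problem sizes

The test suite and acceptance script run at desk scale by choice: the
shared study fixture uses 60 homoeolog pairs × 600 pairs/library, the
acceptance accuracy run 120 pairs × 1500 pairs/library × 6 libraries, and
the count-level simulations 2000 genes at 2 + 2 replicates — large enough
for the binomial error bars the checks rely on, small enough that the
whole suite completes in well under a minute of compute for the
statistical parts and a few tens of seconds for the read-level parts.
Counts-level questions (FDR, power, calibration) are measured directly on
simulated count matrices rather than through read simulation, because the
read stage adds cost but no information to those checks.

## Known limitations

- The arbitration is specified and tested for two subgenomes; the
  evidence comparison would extend N-way but no such mode is exposed.
- The NB test is two-group; multi-factor GLM designs are out of scope.
- ±Inf fold changes are faithful to the v1-style output but make ranking
  by effect size degenerate for group-silent genes; rank by adjusted p
  within the ±Inf stratum instead.
- The fixture aligner's MAPQ model is a documented stand-in (score-gap
  against an acceptance floor); real aligners' MAPQ scales differ, and
  the arbitration consumes whatever MAPQ the input SAM carries.
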
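# Methods

This note records the models, conventions and open design choices behind
`epimem`, in the order data flows through the package.

## Coordinates, annotation and TSS windows

All interval arithmetic is 0-based half-open (BED convention); GTF input
(1-based closed) is converted on read. Each gene carries exactly one TSS:
`body_start` on the + strand, `body_end − 1` on the − strand. Transcript-
level models (multiple TSSs per gene) are out of scope.

TSS windows are **strand-aware by default**: "−2 kb" means 2 kb 5′ of the
gene, so on the − strand the upstream extent points to larger
coordinates. Whether the original −2 kb/+3 kb aggregation window was
strand-oriented or genomic-left/right is not derivable from the method's
description; both behaviours are supported (`strand_aware=False`, CLI
`--no-strand`) and the choice is echoed into every run manifest. Windows
are clipped at coordinate 0; a window falling entirely off-chromosome is
an error.

Gene-set membership matches normalized (uppercased) symbols exactly; no
alias resolution, by design — deterministic and dependency-free.

## ChIP quantification

Counting uses multicov semantics: a read overlapping a target by ≥ 1 bp
counts, a read overlapping two targets counts in both, and half-open
abutment is no overlap. RPKM is computed per library against that
library's own size; the background-adjusted value is ChIP RPKM minus
input RPKM within the same peak, and peaks with adjusted RPKM ≤ 0 are
excluded before any gene-level aggregation.

The per-gene TSS score is the **unweighted mean** of adjusted RPKM over
retained peaks intersecting the window by ≥ 1 bp — no length- or
overlap-proportional weighting. This is the simplest reading of
"averaged across the window"; a weighting variant would require
information the peak tables do not carry, and the ≥ 1 bp rule matches the
counting semantics used upstream.

Genes whose window contains no retained peak get a **missing** score and
drop out of downstream distributions rather than being zero-filled
(`zero_fill=True` restores the other behaviour). Zero-filling would
manufacture a point mass at 0 in every gene-set distribution and distort
the group comparison; the choice is logged per run.

Coverage tracks divide per-bin read counts by millions of uniquely mapped
reads (RPM); bins tile the region left to right and the last bin may be
short.

## Methylation quantification

The sliding-window grid over the −1 kb/+1 kb TSS region uses 300 bp
windows every 30 bp, keeping only windows fully inside the region: 57
windows, the first at offset −1000, the last at +680. Window fractions
**pool calls** (Σ methylated / Σ called over the CpG sites whose start
lies in the window) rather than averaging per-site frequencies; pooling
weights sites by their coverage, which is what "fraction of methylated
CpGs" computes. The per-site-average alternative is available
(`pooled=False`) and tested. Grouped CpG motifs are assigned to the
window containing the group's start and are not split.

The per-gene reduction over the 57 window fractions defaults to the
**mean** (options: median, min — the min tracks the valley floor). The
choice is genuinely open; the mean is the least surprising and most
stable, and the option is surfaced in the CLI (`--window-reduce`).

Sample-to-sample correction subtracts each sample's own mean over all of
its scored genes (not just plotted sets), so per-sample centered means
are 0 to ≤ 1e−9 by construction; the two animal replicates of a group are
then averaged, excluding genes scored in only one replicate
(`keep_single=True` keeps them).

## Group statistics

Genes are the units of replication: each gene set × assay × group yields
a distribution of replicate-averaged per-gene scores. Comparisons use
one-way ANOVA (scipy) and Tukey–Kramer adjusted pairwise p-values
computed directly from the studentized-range distribution,

    q = |mean_i − mean_j| / sqrt(MSE/2 · (1/n_i + 1/n_j)),  p = SR_sf(q; k, N−k),

valid for the unequal group sizes that missing scores produce. When every
group is constant (zero within-group variance) the test is resolved by an
exact-separation rule — p = 0 for pairs with different means, p = 1
otherwise — instead of jitter, keeping results deterministic. Because the
two groups score the *same* genes, the shared gene-to-gene variance
inflates the ANOVA denominator and the test is conservative under the
null; the Monte-Carlo calibration below quantifies this.

No multiple-testing correction is applied across gene sets (each set is
reported as its own test); a Benjamini–Hochberg column is emitted
alongside, clearly labelled as supplementary.

qPCR relative expression is 2^−ΔΔCt against the calibrator group's mean
ΔCt per gene (calibrator mean 1.0 by construction; the method itself is
the standard reading of "expression relative to a calibrator set at
1.0" with a named reference gene). Wells are averaged within each cell
line before testing, so lines — not wells — are the replicates (n = 4 vs
4 by default); testing wells would pseudo-replicate.

## The synthetic cohort

The generator emulates the data shapes the analysis consumes with the
study design it models, and its defaults are the study conditions:

- **ChIP**: 2 groups (PTC, TTF) × 2 lines × 2 replicates × 3 marks, one
  input library per (group, line, replicate) chromatin prep. Genes sit
  every 20 kb on 2 chromosomes (240 genes); each gene is "active" for a
  mark with probability 0.85 (a gene property shared across samples), and
  active genes carry a ~1 kb peak at the TSS. ChIP counts are
  Poisson-distributed around a per-gene log-normal signal mean (75 reads
  per peak, σ = 0.3, shared across samples); a uniform background of
  1 read/kb is added to every library and is all the input library sees.
  Nominal library size is 5 × 10⁶ (the synthetic chromosomes stand in for
  a small slice of a genome, so stored reads ≪ library size).
- **Methylation**: 2 animals per group; CpG sites at 10/kb; per-site
  latent methylation is logit-normal (σ = 0.5, shared across samples)
  around a base mean of 0.75, lowered by the valley factor (depth 0.5)
  within ±1 kb of every TSS — the hypomethylated promoter valley of
  pluripotent cells; calls are binomial at Poisson(30×) coverage with a
  per-sample logit wobble (σ = 0.2).
- **qPCR**: a 14-gene renal panel, 4 lines per group × 3 wells, plus an
  embryonic-kidney-like calibrator; reference Ct ~ N(18, 0.3), per-well
  noise 0.25 cycles.
- **Memory effect**: for a histone assay, the Poisson signal mean at
  target-set genes is multiplied by (1 + effect_size) in one group; for
  the methylation assay, effect_size adds to the valley depth (clipped to
  [0, 1]). Fold changes per gene drive the qPCR layer.

Everything is deterministic under a fixed seed, and the generator returns
its own truth (per-gene expected adjusted RPKM per group) so parameter
recovery can be asserted against the realized configuration rather than a
hand-derived constant.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: mappability and GC bias,
fragment-length structure, peak-calling errors (peaks are placed, not
called), correlated replicate artefacts, haplotype effects, and real
gene-set biology. The validation shows the *quantification and testing
machinery* is correct and calibrated, not that any particular biological
cohort is null.

## Validation studies and problem sizes

`epimem.calibration` runs the Monte-Carlo studies; the suite and
`scripts/acceptance.py` execute them at these sizes, chosen so a full
validation completes in minutes on one CPU:

- **Null calibration**: 20 seeds × (18 sets × 4 assays) with
  effect_size = 0; the fraction of non-significant comparisons at
  α = 0.05 is the statistic (observed ≈ 100%, reflecting the conservative
  paired-gene design). The qPCR t-test's type-I rate is measured over
  1000 simulated null genes (observed ≈ 0.05).
- **Power / recovery**: 50 seeds with a 2× H3K4me3 boost at the
  `kidney_dev` set in PTC; detection requires the target set flagged and
  *no other* (set, assay) pair flagged. The measured difference of group
  medians is compared to the generator-truth difference within 2
  Monte-Carlo standard errors.
- **Determinism**: two full runs at one seed must produce byte-identical
  files (SHA-256 over every output except the manifest itself).

Pipeline-level tests and the determinism runs use a scaled cohort
(1 chromosome × 60 genes, 6 sets × 8 genes, 10⁶ library size); the
statistical studies use the full default cohort.

## Numerical details

- Degenerate inputs: empty read/target lists count to zeros; empty
  gene-set intersections raise naming the set; all-missing methylation
  profiles exclude the gene with a log line; identical zero-variance
  vectors in the t-test return p = 1 by convention.
- Summary tables are sorted lexicographically by (set, assay, pair) with
  a stable mergesort, and floats are serialized at 10 significant digits,
  so reruns are byte-identical.
- Centering tolerance 1e−9 is an invariant check, not an estimate —
  float accumulation sits at ~1e−17 in practice.

## Known limitations

- One TSS per gene; no transcript isoforms.
- Peak calling, alignment and basecalling are consumed, never performed.
- The ANOVA layer models two groups here; more groups work (Tukey–Kramer
  over all pairs) but the generator only emulates the two-group design.
- No spike-in or between-sample ChIP normalization beyond library size;
  the background-adjustment step assumes the input channel shares the
  chromatin background of the ChIP library.
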
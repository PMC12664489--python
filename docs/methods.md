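# Methods

`sedomain` implements a super-enhancer-centric analysis of H3K27ac ChIP-seq
cohorts with matched RNA-seq: it recovers regulatory elements and pooled
domains, asks which transcription factors preferentially bind tumor- versus
normal-specific domains, measures how far super-enhancer domains reach into
the surrounding transcriptome, links enhancer RNA output to proximal mRNA
changes, intersects the evidence into a core gene set, and summarizes the
transcriptional program with gene-set enrichment.  This note documents the
models, the conventions chosen where the procedure was genuinely open, and
what the synthetic benchmark does and does not establish.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention).  GTF import is the
only 1-based arithmetic in the package: a gene spanning `start..end`
(1-based, inclusive) has TSS `start - 1` on `+` and `end - 1` on `-`.
Interval merging bridges gaps of at most `merge_distance` bp transitively;
nearest-point searches break exact ties toward the smaller coordinate so
every result is deterministic.  Strand is carried on genes but ignored by
interval algebra, since H3K27ac peaks and domains are unstranded.

## Elements, the ROSE tangent cutoff, and domains

A peak is a **promoter** when its interval intersects the closed window
`[TSS - w, TSS + w]` of any annotated gene (default `w` = 2,500 bp;
intersection rather than containment is the most inclusive reading and the
window is configurable); all other peaks are **enhancers**.  Each enhancer is
scored by the sum of normalized H3K27ac density times covered bases.  An
optional stitching distance (default 0) merges nearby enhancers before
scoring.

The super-enhancer threshold is the classic rank-ordered tangent rule: sort
scores ascending, scale rank and score to [0, 1], and cut at
`argmax_i (x_i - y_i)` — for a convex curve, the point where the tangent has
slope 1.  Ties break to the largest index (fewest super-enhancers), a
constant score vector yields none, and elements must exceed the cutoff score
strictly.  The rule is applied per sample, so each sample carries its own
cutoff.

Elements of one class are pooled across samples into **domains** (PD/ED/SED)
as the union of overlapping intervals (gap 0 by default, exposed as
`pool_gap`).  A domain is tumor-specific (T) when every supporting sample is
a tumor, normal-specific (N) when every supporter is normal, and common (C)
otherwise.  Pooling is order-independent and domains of one category never
overlap.

## Shade-controlled TF binding-site enrichment

The cistrome (one set of binding regions per TF) is prepared by merging
neighboring regions per TF (default gap 10 kb) and keeping regions of 50 to
10,000 bp.  For a domain set under test, each domain `[s, e)` of length `L`
contributes two length-matched control regions ("shades") at fixed distance
`D`: `[s - D - L, s - D)` and `[e + D, e + D + L)`.  Shades that would cross
a chromosome boundary are dropped whole (clipping would distort the length
matching); overlapping shades within a control set are merged.  Shades are
not excluded when they fall on other test domains — no exclusion rule is
part of the procedure — but construction is deterministic and auditable.

Per TF and per `D` in {10 kb, 100 kb}, a 2x2 table counts test and control
regions with and without a nonempty cistrome overlap (region-level: a domain
hit by three binding regions counts once).  The two-sided Fisher p-value is
computed by exact integer enumeration of all tables with the observed
margins (numerators `C(m1, a) C(m2, k-a)` compared as exact integers over
the common denominator), so it matches a brute-force oracle to round-off.
The odds ratio uses a Haldane-Anscombe +0.5 on every cell whenever a cell is
zero; the correction applies to the OR only, never to the p-value.

Across the two `D` values the *worst case* is kept, componentwise: the lower
odds ratio and the less significant p-value, possibly from different `D`.
This is deliberately conservative — under the null the selected p-values are
stochastically larger than uniform, which the type-I harness confirms.
Selected p-values are Bonferroni-corrected across TFs (significant at
corrected p <= 0.05), and tumor-vs-normal preference is the delta of
continuity-corrected log odds ratios, `ln OR_T - ln OR_N`; a TF is called
tumor-leaning when it is significant in the tumor test and delta > 0.

## Differential expression

The built-in engine normalizes counts with median-of-ratios size factors,
log2-transforms with a pseudocount of 1, and tests each feature with a
two-sided Welch t-test, BH-adjusted per contrast.  This is a deliberately
minimal engine: the downstream stages consume only `log2fc` and `p_adj`, and
an ingest mode accepts externally produced DE tables bit-exactly, so a
negative-binomial GLM engine can be substituted without touching anything
else.  Significance gates are strict: `|log2FC| > 1` for genes, `> 1.5` for
eRNAs, FDR < 0.05; a threshold of 0 reproduces the p-only gates used by the
intersection analyses.  Features with zero counts everywhere are excluded
from testing and from the BH family.

## SED regulatory reach (distance analysis)

Genes with `p_adj < 0.05` are assigned to the nearest SED by
center-to-TSS distance (unsigned; ties to the smaller coordinate; genes
further than 2 Mb excluded).  Within each 100 kb bin out to 2 Mb, the log2
fold changes of T-SED-adjacent and N-SED-adjacent genes are compared with a
two-sided Wilcoxon rank-sum test — exact enumeration when the pooled sample
is at most 12 and tie-free, otherwise the normal approximation with tie and
continuity corrections — and BH adjustment runs across the *testable* bins
only (a bin needs at least 2 genes per group; unstable one-gene bins would
otherwise dilute the family).  Genes whose nearest SED is common are kept in
the assignment table but excluded from the two-group contrast, which is a
T-vs-N comparison.

## eRNA integration

eRNA abundance arrives as a counts matrix over SED intervals (quantification
from reads is an upstream concern).  eRNA DE uses the shared engine with the
eRNA gates.  For annotation, each SED is labelled with the gene whose TSS is
nearest its center.  For integration, an eRNA's fold change is assigned to
every gene whose TSS lies within the eRNA interval expanded by 1.5 Mb per
side (TSS-to-expanded-interval, the concrete reading of a +-1.5 Mb overlap;
window configurable), genes overlapped by several eRNAs take the arithmetic
mean, and gene-level concordance between eRNA and mRNA log2 fold changes is
Kendall's tau-b (tau-b because ties must be defined even if rare; exact p for
n <= 8 without ties, normal approximation otherwise).

## Core gene set and overlap statistics

The core set intersects (1) genes significantly up in tumors (p_adj < 0.05),
(2) genes whose *nearest* SED center is tumor-specific and within a 2 Mb
window of the TSS (a gene nearer to an N- or C-SED is excluded even when a
T-SED is also in range), and (3) genes significantly down after JQ1 in both
cell lines.  Overlap strength is tested with the same exact Fisher test
against a shared background universe of all tested genes; odds ratios carry
the Haldane correction, 95% CIs are Wald on the log OR over the corrected
cells, and BH runs across the three contrasts of one run (each line and
their intersection).

## Pathway enrichment

Preranked GSEA ranks genes by log2 fold change (ties broken by gene id for
determinism).  Hits increment the running sum proportionally to
`|statistic|^weight` normalized within the set (weight 1 by default, the
established preranked convention; weight 0 is retained as the analytically
checkable mode), misses decrement `1/(N - n)`, and the enrichment score is
the maximum deviation from zero.  The null is gene-label permutation at
fixed set size; `p` is the fraction of same-sign null ES at least as
extreme, NES divides ES by the mean |null ES| of the same sign, and FDR is
the standard NES-ratio procedure on the pooled normalized null.  Gene-set
collections are GMT files, filtered to sizes 5-500 after intersection with
the universe.  Over-representation of a fixed query set per term is the
upper-tail hypergeometric test with BH across terms.

## The synthetic cohort

The generator emulates the statistical structure of the study at desk scale,
with every planted quantity recorded in truth tables:

- **Geometry.** 5 chromosomes of 40 Mb, 2,000 genes, and 150 planted SEDs
  (60 T / 60 N / 30 C) of 20-40 kb placed in evenly spaced slots with
  jitter.  The genome is ~65x smaller than human; domain counts are scaled
  so that table margins, not asymptotics, drive the statistics.
- **Peaks.** 2 tumor and 2 normal ChIP samples (the study's design), each
  with promoter peaks at a random gene subset, log-normal background
  enhancers (heavy-tailed, hence a convex rank-score curve), and planted SE
  peak clusters covering each matching-specificity SED with signals drawn
  from a far upper tail, so the tangent cutoff lands between background and
  planted scores.
- **Cistrome.** 40 TFs x 2,000 regions of 0.1-1 kb (~10 regions/Mb, chosen
  by a prospective power analysis so a 3x density enrichment is recoverable
  after Bonferroni).  Enriched TFs place `fold x expected` regions inside
  T-SEDs; the null generator places everything uniformly with lengths in
  [50, 10000] bp.
- **Expression.** 47 tumor / 25 normal mRNA libraries (the study's cohort
  sizes) with negative-binomial counts (Var = m + phi m^2, phi = 0.05),
  gene baselines log-normal around 100, library sizes varying ~+-30% to
  exercise normalization.  A gene's tumor/normal log2FC is a N(0, 0.3)
  background plus the planted effect `effect_lfc * max(0, 1 - d/decay)`
  (effect 2.0, decay range 1 Mb) signed by the nearest planted SED: positive
  for T, mirrored negative for N (so the per-bin T-vs-N contrast has two
  populated groups, emulating the repression of normal lineage programs),
  zero for C.
- **JQ1.** Two cell lines, 8 replicates per arm.  A designated core subset
  (50 genes seeded 26-100 kb from T-SED centers) has its planted effect
  multiplied by `-jq1_reversal_fraction` (0.8) under JQ1; all other genes
  get independent N(0, 0.25) noise.  Restricting the reversal to a subset
  reflects that only a minority of SED-proximal genes is BET-sensitive, and
  it is what makes precision/recall of the three-way intersection
  well-defined.  Eight replicates per arm are more than a typical bench
  experiment because the Welch engine has no dispersion shrinkage; the
  criterion is that the *planted structure* is recoverable, not that three
  replicates suffice.
- **eRNA.** Counts over the planted SED intervals with true log2FC
  `coupling * base + N(0, 0.8)` where base is +-effect_lfc by specificity;
  the noise stream is independent of the coupling value, so tau comparisons
  across coupling levels share their randomness.

All randomness flows from one seed through independent child streams per
component (changing the eRNA coupling leaves peaks, cistrome and mRNA counts
untouched), and a fixed seed reproduces the cohort byte-identically.  The
packaged fixture is the generator at seed 17.

**What the benchmark does not show.**  The generator has no copy-number or
GC artifacts, no read-level noise, no correlated gene programs, no shared
dispersion structure, uniform intergenic background, and planted effects
with a single linear decay shape.  Passing the recovery harnesses
demonstrates that the pipeline's logic recovers effects of the planted form
at the planted magnitudes — not that real cohorts of this size would yield
the same power, and not that the Welch engine matches a negative-binomial
GLM on real overdispersed data.

## Numerical and degenerate-input conventions

Fisher tables with an all-zero or all-one overlap margin return p = 1 with a
Haldane-corrected OR rather than erroring inside a TF scan; zero-variance
features get p = 1; BH families always exclude untestable entries; the ROSE
rule returns the maximum score for constant and linear curves so no
super-enhancer is called; shades are dropped whole (never clipped) at
chromosome bounds; all argmax/nearest ties have documented deterministic
winners.  BH adjustment is *not* idempotent in general (p = [1.0, 0.25]
maps to [1.0, 0.5] and then [1.0, 1.0]); the suite tests monotonicity and
the literal step-up definition instead.

## Problem sizes used by the packaged checks

The validation suite and the reproduction script run the full pipeline on
the default cohort (seconds) and multi-seed harnesses on a reduced cohort
(3 x 30 Mb, 800 genes, 100 SEDs, 15 TFs at preserved cistrome density) —
sizes chosen so the whole suite completes in a couple of minutes while the
planted effects remain comfortably above the recovery thresholds.  The TF
recovery harness keeps the default genome geometry because Fisher power
there is set by the number of tumor-specific domains.
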
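# sedomain

Super-enhancer domain analysis for H3K27ac ChIP-seq cohorts with matched
RNA-seq.  Tumors driven by epigenetic rather than genetic dysregulation —
HPV-positive head-and-neck squamous cell carcinoma is the motivating case —
concentrate their oncogenic transcription under *super-enhancers* (SEs):
clusters of enhancers whose summed H3K27ac signal far exceeds that of
typical enhancers.  `sedomain` is a pipeline for asking, from peak calls and
count matrices, which SE *domains* are tumor-specific, which transcription
factors bind them, how far their regulatory influence reaches, whether their
enhancer RNA output tracks proximal mRNA changes, and which genes form the
SE-driven, BET-inhibitor-sensitive core program.

It is aimed at computational biologists who have per-sample H3K27ac peak
calls (with normalized signal), a gene annotation, a cistrome of TF binding
regions, and mRNA/eRNA count matrices — or who want to exercise the whole
workflow on the built-in synthetic cohort generator first.

## The method in brief

1. **Elements.**  Peaks within 2.5 kb of a TSS are promoters; the rest are
   enhancers, scored by summed H3K27ac density x covered bases.  Per sample,
   the rank-ordered score curve is scaled to the unit square and cut at the
   slope-1 tangent point, `argmax_i (x_i - y_i)` (the ROSE rule): scores
   strictly above the cutoff are super-enhancers.
2. **Domains.**  Per class, overlapping elements across samples are pooled
   into domains (PD/ED/SED) labelled T (tumor-only supporters), N
   (normal-only) or C (both) — one shared geometry for all samples.
3. **TF enrichment.**  For each domain set, length-matched control regions
   ("shades") are placed at distance D up- and downstream of every domain.
   Per TF and D in {10 kb, 100 kb}, a 2x2 Fisher exact test compares
   domain-vs-shade overlap with the TF's binding regions; the lower OR and
   less significant p over the two D are kept (worst case), Bonferroni
   corrected across TFs.  Tumor preference is
   `delta = ln OR_T - ln OR_N > 0`.
4. **Expression.**  Median-of-ratios normalization + per-feature Welch tests
   with BH control (or ingest your own DE tables); gates |log2FC| > 1
   (genes) / 1.5 (eRNAs), FDR < 0.05.
5. **Distance analysis.**  DE genes assigned to the nearest SED center,
   binned at 100 kb out to 2 Mb; per bin, T-adjacent vs N-adjacent log2FC
   compared by two-sided Wilcoxon, BH across bins.
6. **eRNA integration.**  eRNA DE over SED intervals; fold changes assigned
   to genes within +-1.5 Mb (mean over contributors); gene-level
   concordance with mRNA as Kendall's tau-b.
7. **Core set.**  up-in-tumor ∩ near-T-SED ∩ down-after-JQ1-in-both-lines,
   with background-relative Fisher overlap tests (OR, 95% CI, BH).
8. **Pathways.**  Preranked GSEA on log2FC (running-sum ES, gene-label
   permutation null, NES, NES-ratio FDR) and hypergeometric GO-style
   over-representation.

See `docs/methods.md` for conventions, tie rules, and what the synthetic
benchmark does and does not establish.

## Worked example

Run the full workflow on the packaged synthetic fixture (the generator at
seed 17: 5 chromosomes x 40 Mb, 150 planted SEDs, 2 tumor + 2 normal ChIP
samples, 47/25 RNA libraries, two JQ1-treated cell lines):

```bash
sedomain run-all --seed 17 --outdir run17
```

which finishes in a few seconds and prints

```
completed 9 stages -> run17/manifest.json
```

Key outputs (real values from this run):

- `domains_SED.bed` — 160 SED domains (65 T, 65 N, 30 C; all 150 planted
  SEDs recovered inside a domain of matching specificity).
- `erna_mrna_concordance.tsv` —

  ```
  kendall_tau     p_value         n_genes
  0.257702        1.347306e-66    2000
  ```

  a positive gene-level eRNA-mRNA concordance, as planted (the generator's
  coupling is 0.7; tau rises and falls with it).
- `sed_distance_bins.tsv` — T-vs-N fold-change contrasts significant from
  the first bin out to 0.8 Mb and indistinguishable beyond ~1 Mb, matching
  the planted effect that decays to zero at 1 Mb.
- `core_genes.tsv` — 50 genes; exactly the planted SE-driven, JQ1-reversed
  set (precision and recall 1.00 at this seed).  `core_fisher.tsv` reports
  the overlap tests, e.g. for the both-lines contrast `OR = 158.8`
  (95% CI 9.8-2577.6, p < 1e-15) against the 2000-gene background.
- `gsea_tumor_vs_normal.tsv` — the planted up-set at `NES = 3.76`,
  permutation p < 0.001; random sets non-significant.

Every stage is also a standalone subcommand (`simulate`, `call-elements`,
`build-domains`, `tf-enrich`, `de`, `distance`, `erna`, `core-set`, `gsea`,
`go-enrich`) reading and writing plain BED/TSV/GMT, so real cohorts can
enter at any point; `--help` on any subcommand lists its inputs.

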
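# Methods

## Overview

`revex` implements a reversal-gene-expression screen for drug repurposing.
The premise: if a disease dysregulates a set of genes, a drug whose
perturbation signature moves those genes in the *opposite* direction is a
repurposing candidate. The pipeline has five computational stages:

1. **Sample QC** — PCA-based outlier exclusion per omics layer.
2. **Differential expression** — independent DE calls on a case/control
   transcriptome (counts) and proteome (intensities).
3. **Disease profile** — the genes significant in *both* layers, carrying
   their transcript-layer log2 fold changes (LFCs), sorted ascending.
4. **Concordance screen** — Pearson correlation of each perturbagen
   signature with the profile over shared genes; signatures below a
   per-library negative cutoff pass and are median-aggregated per drug.
5. **Prioritization** — Ward/Minkowski clustering of passing signatures,
   two scoring indices per drug, ranking, and candidate filters.

## Scoring indices

For a disease profile with genes k = 1..g and LFCs `p_k`, and a drug
profile with partial LFC map `d_k`:

- **Regulation Score**
  `RS = Σ_k Δ_k·|p_k| / Σ_i |p_i|`, where `Δ_k = |d_k − p_k|` if
  `d_k·p_k < 0` and `Δ_k = 0` otherwise. The numerator sums only over
  reversed genes; the denominator runs over all g profile genes. RS is
  nonnegative and zero exactly when no gene is reversed; for the exact
  mirror drug (`d = −p`) it closes to `2·Σ p² / Σ|p|` (2.0 on a
  unit-magnitude profile), and for a noiseless scaled reverser
  (`d = −α·p`) to `(1+α)·Σ p² / Σ|p|` — both are tested closed forms.

  The gating condition uses the *absolute* difference `|d_k − p_k|`. A
  signed difference under the opposite-sign condition would be
  sign-indefinite and could not deliver a score that is nonnegative and
  monotone in reversal depth, profile importance and gene count — the three
  properties the score is designed around — so the absolute form is the
  implemented definition.

- **Overall Coverage** `OC = a/g` with `a` the number of profile genes with
  `d_k·p_k < 0`. Unmeasured genes and genes with `d_k = 0` are never
  counted in `a` (or in the RS numerator) but stay in the denominators:
  unmeasured is not reversed. RS and OC deliberately measure different
  things — a drug can reverse many genes weakly (high OC, low RS) or few
  genes strongly; the ranking uses RS with OC as tie-break, and the tests
  assert that discordant orderings are representable.

## Differential expression

**Transcripts.** Counts are normalized with median-of-ratios size factors
(the median, per sample, of count/geometric-mean ratios over genes with all
positive counts). The per-gene test is Welch's unequal-variance t on
log2(normalized + 1), with Benjamini–Hochberg adjustment across testable
genes. A gene is significant when adjusted p < 0.05 and |LFC| > 1, with
LFC = log2 of the ratio of pseudocounted normalized group means. This is a
deliberately self-contained procedure with the standard decision semantics
of count-based DE; it does not attempt dispersion or LFC shrinkage, so its
per-gene LFC estimates are plain mean ratios, not shrunken posteriors.

**Proteins.** LFC is the log2 ratio of raw group mean intensities (no
pseudocount in the ratio — intensities are large where detected). The test
is Welch's t on log2(intensity + 1) when both groups have ≥ 2 samples,
with Bonferroni adjustment (`p_adj = min(1, m·p)`, asserted against the
direct formula). Zeros mean "not detected": a protein with nonzero mean in
exactly one group has no finite ratio, so its LFC is imputed to ±L_max —
the maximum finite |LFC| among two-group proteins in the same run (or a
configured override), signed toward the detected group — and it is called
significant on the adjusted p-value alone. Its p-value comes from the same
log-scale Welch test, where the undetected group contributes a constant
log2(0+1) = 0: the detected-vs-undetected contrast is tested on the same
scale as everything else. With single-sample (pooled) groups the test is
undefined; LFCs are still reported but nothing is called significant.

Swapping the group labels negates every finite LFC exactly (tested), and
imputed magnitudes dominate all finite ones by construction.

## Sample QC

PCA on log2(value + 1) with features centered; component signs are fixed by
requiring the largest-|loading| feature to load positively, so scores are
deterministic. A sample is an outlier when its Euclidean distance to its own
group's centroid in the first 2 component scores exceeds
mean + 3·SD of that group's distances. Known limitation of any k·SD rule
computed with the outlier included: a single gross outlier cannot exceed
(n−1)/√n standardized distances, so with k = 3 groups smaller than ~11
samples can never flag a lone outlier. The planted-outlier test therefore
uses a 20-sample group, where the rule has headroom.

## Concordance screen

Plain Pearson correlation over the genes shared by profile and signature —
no rank transform and no imputation of missing genes. Cutoff comparison is
strict (`r < cutoff`), default −0.2 per library, overridable per library
(sparse-overlap libraries warrant tighter cutoffs, e.g. −0.6). Signatures
sharing fewer than `min_overlap = 10` genes with the profile, or constant
on the overlap, are flagged rather than scored; flags never abort a screen.
Drug-level aggregation is the per-gene median over the drug's *passing*
signatures in which the gene is present.

## Clustering

Columns are the passing signatures restricted to profile genes (missing
entries stay missing), plus optionally the profile itself as one reserved
column. The distance between two columns is Minkowski-p (default p = 2)
over their pairwise-complete genes, rescaled by `(g/m)^(1/p)` where m is
the number of complete pairs — an unscaled pairwise-complete distance would
make sparsely-overlapping columns look artificially close. A pair with no
complete gene gets the maximum observed distance. Ward linkage on that
matrix, cut at k clusters (default k = 8 with the profile included, so one
cluster is typically the profile's own). Determinism comes from
lexicographic column ordering; relabeling columns permutes cluster ids but
not the partition (tested).

A *reversal cluster* is one whose member signatures have median concordance
below the default cutoff; a drug is "in a reversal cluster" when any of its
passing signatures is. A drug's reported cluster id is the most common
cluster among its signatures (smallest on ties).

## Ranking and filters

Drugs are ranked by RS descending (ties: OC descending, then id). Filters —
BBB permeation probability ≥ 0.9 (inclusive), zero prior disease trials,
reversal-cluster membership — never reorder: a top-RS drug that fails a
filter keeps its rank and is flagged `passes_filters = false`, mirroring how
a top-scoring but already-trialed drug is excluded from a final candidate
list without pretending it scored lower. Drugs missing from the annotation
table fail filters and are logged, never dropped silently.

## Synthetic data

The generator produces every pipeline input with planted ground truth:

- **Counts**: negative binomial with variance m + φ·m² (default dispersion
  φ = 0.05, typical of bulk tissue cohorts), log-normal baseline means
  (log-mean 5, log-sd 1.5), planted DE genes (default 10%) with |log2FC|
  uniform on [1.5, 4] and random sign, case means shifted by 2^LFC.
- **Intensities**: log-normal around group means with log2-scale
  measurement SD `intensity_noise_sd` (default 0.1 — pooled proteome
  samples have low technical variance, which is what makes 3-vs-3 designs
  informative at all). A `dropout_rate` fraction (default 0.2) of planted
  DE proteins is made structurally one-group-only: every sample of the
  *low-abundance* group is zeroed, exactly the case the imputation rule
  handles.
- **Signatures**: per drug, an archetype — reverser (`−α·p + noise`),
  mimicker (`+α·p + noise`), neutral (pure `N(0, noise_sd)` noise; Pearson
  concordance is scale-free, so the neutral amplitude is irrelevant to
  screening) — with α uniform in [0.6, 1] and a `missing_rate` fraction of
  genes masked per signature. α maps monotonically to expected RS, which is
  what makes recovery testable.
- **Annotations**: BBB ~ Beta(5, 1.5), trials ~ Poisson(0.5), indication
  from a fixed list, with an override map for pinning specific drugs.

A single integer seed is expanded into independent substreams per stage
(planted truth, counts, intensities, signatures, annotations). The
planted-truth stream depends only on (seed, n_genes, frac_de, lfc_range),
so the transcriptome cohort and the smaller proteome cohort generated from
one seed share the same planted genes — without this the two-layer
intersection would be empty by construction.

What the generator does **not** emulate: GC/length bias, batch effects,
library-composition artifacts, cell-line- or dose-dependent signature
structure, correlated gene modules, or identifier mismatch between layers.
Passing recovery tests therefore demonstrates correctness of the method's
logic under its own statistical assumptions, not performance on real
cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale versions of each
experiment: 2 000-gene cohorts at 20–60 samples per group, 300-gene
profiles, 50-drug libraries with 3 signatures per drug, and 50-replicate
null simulations — sizes at which the measured quantities (planted-LFC
recovery, screen recall, cluster purity, DE sensitivity/FDR) are stable
across seeds while the whole suite runs in seconds. Tolerances follow from
the statistics: empirical LFCs within ±0.3 of truth at n ≥ 100 per group
(sampling error of a mean ratio), mean |null concordance| < 0.2 at 300-gene
overlap (Pearson null SD ≈ 0.06), vectorized-vs-loop score agreement at
1e-12 (pure floating-point reassociation).

Degenerate inputs are contracts, not accidents: zero-variance genes are
flagged untestable and never significant; all-zero proteins are excluded
with a logged count; empty drug profiles score RS = OC = 0 with a warning;
an empty two-layer intersection is a hard error carrying both significant-
set sizes; screening never raises on an individual signature.

## Known limitations

- Gene identifiers are matched as exact strings; no alias resolution.
- The proteome test with pooled single samples cannot assign significance.
- The transcript DE procedure trades shrinkage-based LFC stability for
  self-containment; very low counts give noisy LFC estimates.
- Cluster count k is a user choice; no model selection is attempted.
- Scoring treats genes independently; correlated modules inflate neither
  index but are not modeled.
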
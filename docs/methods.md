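# Methods

## 5hmC quantification from paired channels

For probe *g* and sample *s*, bisulfite conversion measures
β_BS = 5mC + 5hmC and oxidative bisulfite measures β_OxBS = 5mC, so the
5hmC estimate is Δβ = β_BS − β_OxBS. Because the two channels are
measured independently, low-5hmC probes frequently yield Δβ < 0; these
strictly negative values are a technical artifact and are set to 1e-7.
Exact zeros are kept at 0 (zero is not negative), so the number of
clamped cells equals the number of BS < OxBS cells exactly. The 5mC
matrix is the OxBS channel relabelled. Wherever BS ≥ OxBS the stored
5hmC value is the bitwise floating-point difference, and
5mC + 5hmC reconstructs BS to within one ulp (IEEE rounding makes exact
re-addition unattainable for roughly 1 cell in 10⁵; the tests assert
the one-ulp bound and the bitwise subtraction identity).

## Moderated t (volcano statistics)

Per probe, the effect is Δβ = mean(MT) − mean(WT) with pooled residual
variance s² on d_g = n₁ + n₂ − 2 df. The empirical-Bayes step shrinks
s² toward a scaled-F prior: s̃² = (d₀s₀² + d_g s²)/(d₀ + d_g), with
(d₀, s₀²) fitted by moment matching on log s² (digamma/trigamma scale;
the trigamma inverse is solved by Newton). t = Δβ/(s̃·√(1/n₁+1/n₂)) is
referred to a t distribution on d₀ + d_g df, and p-values are BH
adjusted. When the spread of log-variances is no larger than chi-square
sampling noise the prior df is infinite and all variances collapse to
s₀². `prior_df_mode=0` disables moderation and reproduces the ordinary
pooled two-sample t exactly, which the tests use as an oracle; on null
data the moderated test's type-I error at α = 0.05 sits within
0.05 ± 0.01.

## Bump hunting (DMR/DHMR detection)

Probes are clustered per chromosome with a 1 kb gap rule (consecutive
probes ≤ max_gap apart share a cluster). Per-probe effects are smoothed
within clusters by a centred running mean of width 3 (truncated at
cluster edges; clusters smaller than the window are left unsmoothed —
a simple, exactly reproducible stand-in for loess smoothing).
Candidates are maximal same-sign runs of |smoothed effect| above a
cutoff with ≥ 7 probes; each is scored by area = |mean smoothed
effect| × n_probes. Cohort labels are permuted (250 draws, or full
enumeration with a warning when fewer distinct assignments exist);
per-region p pools all null areas and the family-wise adjusted p ranks
the observed area against the per-permutation *maximum* null area, both
with the +1 correction so no p is zero. The same engine serves 5mC and
5hmC input.

The cutoff is a genome-wide quantile of |smoothed effect| (an absolute
cutoff is also accepted). The default quantile is 0.99; the analyses and
acceptance runs use 0.95 because the planted regions in the synthetic
study occupy ≈ 1% of probes, and a cutoff must sit in the gap between
the noise scale (≈ 0.008 after smoothing at these sample sizes) and the
effect scale (0.15) — a 0.99 quantile would land inside the effect
distribution whenever the affected fraction is comparable to 1%. Any
value in that gap gives identical recoveries; the choice is recorded in
every run manifest.

## Enrichment statistics

Odds ratios are ad/bc with Woolf log-scale intervals; when any cell is
zero the Haldane–Anscombe 0.5 correction is applied to all cells (or an
error is raised if disabled). The stratified common OR and its test
follow Mantel–Haenszel without continuity correction (strata default to
CpG feature; the choice is recorded). Exact machinery (Fisher,
hypergeometric tail, chi-square) and BH adjustment are delegated to
scipy/statsmodels; the test suite pins them against direct
binomial-coefficient enumeration to 1e-12 relative for population sizes
up to 500 and margins up to 50. Hypergeometric overlaps use a
protein-coding universe of 20,345 genes. Two-sided tests are used
except where the claim is directional by construction (overlap tails).

## Consensus clustering

Each of 1000 resampling steps draws ⌈0.8 · n_probes⌉ probes without
replacement (the 0.8 resampling proportion applied to features),
computes the sample–sample Pearson dissimilarity 1 − r over the drawn
probes, and cuts a Ward dendrogram at each k. With feature-level
resampling every sample pair is co-sampled in every step, so the
consensus entry is simply the co-clustering count over 1000. The final
per-k assignment reclusters 1 − consensus; diagnostics are the
consensus-CDF area and mean silhouette width, and `chosen_k` (advisory,
never hiding the per-k diagnostics) maximizes the silhouette. Ward on
the non-Euclidean Pearson dissimilarity uses scipy's Lance–Williams
ward update applied to the supplied dissimilarities; variants of Ward
differ on non-Euclidean input, so the choice is stated here and fixed.

## Expression integration

Expression is log2 scale and may be quantile normalized (columns forced
onto the mean of sorted columns; ties receive the mean of the quantile
values their positions span). Differential expression is a per-gene
pooled t (equal to one-way ANOVA with two groups), BH adjusted, with
the joint rule adj p < 0.05 AND fold change > 2, where fold change =
2^|mean log2 difference|. Probe–gene matching is by gene symbol; probes
without a symbol are excluded. For each probe of a differentially
expressed gene, Spearman correlations (average-rank ties, t
approximation on n − 2 df) of 5hmC and 5mC against the gene's
expression are computed across the samples present on both platforms;
probes with |r_5hmC| ≥ 0.5 are assigned Group 1–4 by crossing the
correlation sign with the DE direction (Group 1: +r, up in MT; Group 4:
−r, down in MT). The sign × direction table is tested by Fisher's exact
test when any cell is below 5, chi-square otherwise.

The 5hmC contribution of a signature gene is
pct = 100 · mean(5hmC)/(mean(5hmC) + mean(5mC)) over the gene's probes,
at per-cohort, per-sample, or per-gene (all samples pooled) resolution;
genes with total methylation below 0.3 are flagged and excluded from
percentage summaries. Thresholds printed as ≥/≤ are inclusive.

## hMeDIP arithmetic

Windows tile each chromosome from 0 in 100-bp steps. A read is extended
to max(length, 300) from its 5′ end (strand-aware when strand is
present) and increments every window it overlaps by ≥ 1 bp; intervals
beyond chromosome bounds are clipped with a warning. Differential
windows require a raw-count mean ≥ 3 over all samples and
|log₂((CPM_MT + 0.5)/(CPM_WT + 0.5))| > 1 — library-size normalization
before the fold change, pseudocount 0.5, with the coverage filter on
raw counts. Optional exact-duplicate removal stands in for a
uniqueness filter; interval input makes read shifting a no-op. qPCR
enrichment is normalized by the recovery of an exogenous spiked-in 5hmC
control: enrichment = target/spike, invariant under common scaling.

## The synthetic study

Defaults are the study conditions: 12 MT vs 9 WT samples, 20,000 probes
on 4 autosomes plus an intergenic-only chrX, 1,000 genes (each with
1–2 promoter probes and ≥ 3 body/intron probes), β-distributed baseline
5mC per CpG feature class (island 0.15 → open sea 0.70, concentration
30), baseline 5hmC 0.04, and independent clipped-Gaussian technical
noise of sd 0.02 per channel (0.03 in the region-recovery setting),
which produces the negative-Δβ artifact at the empirically expected
rate (half of all cells when true 5hmC is zero). Probe blocks are
internally ≤ 300 bp between neighbours and separated by 5 kb, so 1-kb
gap clustering recovers blocks exactly.

Planted structure, all recorded in a truth object: 20 DHMRs of 10
gene-body probes with MT 5hmC gains of 0.15 on average (per-region
magnitudes jittered ±40%, because a spatially varying gain — not a
uniform offset, which Pearson dissimilarity cannot see — is what real
DHMR sets present to correlation-based clustering); 50 signature genes
with MT promoter hypermethylation of 0.25 ± 40% on island probes; 40
coupled genes (25 Group 1, 3 Group 2, 3 Group 3, 9 Group 4 — exactly
100 Group-1 body probes) whose body 5hmC carries a per-sample latent
signal and a cohort shift, with expression generated at correlation
0.9 to that signal plus a planted fold change of 3; 30 additional DE
genes. Coupled probes draw moderate 5mC (mean 0.35) so the planted
5hmC has headroom under the 5mC + 5hmC ≤ 1 constraint. In the 3-group
clustering scenario an intermediate cluster mixing both cohorts carries
the regional gain in only half the regions, giving it a distinct
regional pattern. hMeDIP reads are Poisson per window with rates
proportional to local true 5hmC (≈ 4.75× inside planted regions for MT
samples), multiplied by a recorded log-normal per-sample spike-in
recovery factor; chromosome-end windows are kept read-free so fragment
extension stays in bounds.

All randomness flows from one seed through per-stage child seeds
(sheet, manifest, betas, expression, reads), so each artifact is
reproducible independently and byte-identical across runs.

**What passing tests do and do not show.** The generator emulates the
statistical structure of the study — effect sizes, noise scales, cohort
imbalance, coupling strength — but not EPIC-manifest probe chemistry,
spatially correlated hybridization noise, cellular heterogeneity, or
sequence-level read features. Recovery results therefore demonstrate
the pipeline's correctness and calibration under the stated model, not
performance guarantees on real arrays.

## Problem sizes and numerical choices

The default analyses run at 20,000 probes × 21 samples with 250
permutations and 1000 clustering resamples — seconds to tens of seconds
on one CPU; the test suite uses a 2,000-probe fixture for unit-level
checks. Ties in top-fraction and top-expression selection break by
identifier order (recorded); boundary thresholds are inclusive as
printed; p-values never reach zero thanks to the +1 permutation
correction and the BH step preserves input order. Degenerate inputs
(zero-variance probes or samples, empty filters, all-flagged matrices)
raise informative errors or are flagged and excluded rather than
silently imputed; missing β cells are rejected at load.

## Known limitations

- The moderated-t contrast assumes a two-group design; no covariate
  adjustment (age, grade) is available in the region or volcano models.
- Permutation counts bound the attainable family-wise p at
  1/(n_perm + 1); with very small cohorts the distinct-assignment
  enumeration bounds it further.
- The 5hmC clamp at 1e-7 introduces a small positive bias at probes
  with near-zero 5hmC; proportion summaries over such probes inherit it.
- Consensus clustering with feature-level resampling cannot estimate
  sample-level stability (every pair is always co-sampled); a
  sample-resampling mode is not implemented.
- hMeDIP modelling is interval arithmetic only: no CpG-coupling
  correction, no enrichment-score QC, no alignment.
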
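# Methods

## The model and what it assumes

The package analyzes longitudinal bulk expression of brain slice cultures as
a two-phase dynamical signature superimposed on a static background. Gene
programs are modeled as blocks sharing a temporal profile on the culture-day
axis (DIV): an **acute** profile — a gamma-shaped pulse `p(t) = t·e^(1−t)`
that is zero at DIV0, peaks (at 1) at DIV1 and decays — and a **chronic**
profile — a logistic sigmoid with midpoint DIV3 and scale 0.6 days, shifted
and rescaled to start at exactly 0 at DIV0 and exceed 0.99 by DIV6. These
functional forms are a modeling choice: the biology they encode is only
"a robust early excursion that resolves, and a state change that is stable
from DIV6 onward". Everything downstream (PCA states, panel AUCs, lag
analysis) is agnostic to the exact parametric form.

Expected counts are `μ_gs = baseline · f_s · 2^(β_g · p_g(t_s))`, where
`f_s` is a log-normal library-size factor, `β_g` the signed peak log2 effect
of gene g's block, and counts are negative binomial with variance
`μ + α·μ²`. The analysis assumes housekeeping genes are genuinely stable:
the per-sample normalization factor is the geometric mean of their counts,
anchored to the arithmetic mean of those geometric means across samples
(the standard digital-counting convention), which makes post-normalization
housekeeping geometric means exactly equal across samples.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| timepoints | 0, 1, 3, 6, 9, 14 | DIV (days) | collection schedule of the culture platform |
| replicates/timepoint | 3 | cultures | typical independent-experiment count for the assay |
| background genes | 2000 | genes | panel-scale transcriptome (~2.3k total) |
| signature blocks | acute-injury 100↑@2; DAM 50↑@2; homeostatic 50↓@2; astrocyte-activation 50↑@1.5; neurotransmitter-receptor 50↓@1.5 | genes, log2 | block sizes and peak effects are free parameters — no quantitative effect sizes exist for these programs, so values were fixed once at magnitudes typical of strong bulk signatures (2- to 4-fold) |
| baseline mean | 200 | counts | mid-range digital-counting expression |
| NB dispersion α | 0.05 | — | biological replicate CV ≈ 22%, typical for bulk tissue |
| library-size SD | 0.1 | log-units | ±10% depth variation after upstream QC |
| FDR q | 0.01 | — | the workflow's stated operating point |
| pseudocount | 1 | counts | required for zero counts before log2; not otherwise specified |
| driver tail fraction | 0.05 | — | extreme-5% reading of the percentile rule (below) |
| Z cap | ±6 | Z | display clamp used by the heatmap conventions |
| k (states) | 3 | clusters | acute / transitional / stable narrative |
| PCA components | 3 | — | see below |
| secretome dilution | 2 | — | 1:2 assay dilution |
| candidate lags | 0–4 | days | brackets the expected 1–3-day transcript lead |

## What the generator emulates — and what it does not

The simulator reproduces the statistical structure the analysis relies on:
block-correlated temporal signal, NB overdispersion, library-size variation,
stable housekeeping genes, an orthologous cohort sharing the chronic
signature at an analytically calibrated Pearson correlation (noise SD
`sd(signature)·√(1/ρ² − 1)` gives expected r = ρ), and secretome
trajectories that are affine transforms of their source block's profile at
`t − lag`, accumulated over media-change intervals and censored below a
detection limit.

It does **not** emulate: gene–gene correlation beyond block membership,
count-depth-dependent dispersion trends, batch structure, partial-volume
carryover of analytes through 50% media exchanges, one-to-many orthology, or
any cell-type deconvolution ground truth. Passing recovery tests therefore
demonstrates the pipeline's correctness under its own assumptions, not
performance on real tissue data, where effect sizes, dispersion and
confounding are less favorable.

## Numerical and procedural choices

- **Adaptive step-up.** Stage 1 is the linear step-up at `q′ = q/(1+q)`
  giving r₁ rejections; r₁ = 0 ⇒ reject none, r₁ = m ⇒ reject all;
  otherwise `m₀ = m − r₁` and stage 2 re-runs the step-up at `q′·m/m₀`.
  Rejection is `p ≤ p_(r)` for the final step-up count r, so tied p-values
  always share a decision. Verified against a brute-force enumerator and
  statsmodels' independent implementation.
- **Significance test.** Welch's unequal-variance t on log2 normalized
  values. This is a deliberately transparent substitute for moderated
  linear-model machinery used upstream on sequencing data; with only three
  replicates it is conservative at q = 0.01 (often zero rejections over
  ~2.3k genes), which is reported honestly — panel scoring and PCA operate
  on fold changes and do not depend on significance calls. Groups with
  zero variance on both sides get p = 1 for equal means (statistic 0) and
  p = 0 otherwise.
- **Driver-gene rule.** Percentile rules on eigenvector waterfalls are
  stated ambiguously in practice: thresholding at the 5th percentile of the
  loading differentials selects 95% of genes, while the evident intent of
  such rules is the extreme tail. The default implements the tail reading:
  the differential is |loading|, the threshold is the (1 − 0.05) linear
  interpolation quantile, and selection is strictly greater (at most 5% of
  genes, with degenerate ties selecting none). The low-percentile reading
  (`mode="literal"`) and a waterfall-gap variant (`mode="gap"`, differential
  = drop to the next ranked loading) are available but not default.
- **PCA.** Samples are observations; genes are centered, not scaled
  (scaling available via flag). Full SVD; each component's sign is fixed by
  making its largest-|loading| gene positive, so waterfalls and driver sets
  are reproducible. Three components are retained by default: the design
  contains two biological axes (acute excursion, chronic shift) and a
  residual technical axis, and state clustering on fewer components
  occasionally lets plateau scatter dominate the partition.
- **Clustering.** Manhattan (city-block) distances with Ward linkage, the
  combination standard in transcriptomic heatmap practice; scipy breaks
  distance ties by input index, giving deterministic leaf orders. k-means
  uses seeded restarts (default 10) keeping the best inertia.
- **Panel scoring.** Z-scores are per gene across timepoints (population
  SD; constant rows → 0; optional ±cap applied after). Per-category AUC is
  the trapezoidal integral of the category's mean Z over the *actual* day
  values (0,1,3,6,9,14), preserving time semantics; the AUC is signed, so
  rising programs integrate positive and falling ones negative. Genes not
  detected are excluded from category means, never imputed as zero.
- **Cross-species.** One-to-many ortholog pairs are dropped (and counted)
  rather than aggregated; correlations use all shared genes by default with
  a significant-only option; missing values are removed pairwise. A
  caveat: correlating *count-estimated* fold changes attenuates r by the
  estimation-noise factor `sd(x)/√(sd(x)² + var(noise))` — at three
  replicates this brings an underlying 0.9 down to ≈ 0.8. Recovery of the
  calibrated target is therefore assessed against the chronic signature
  table, and the pipeline reports both numbers.
- **Secretome.** Rates are `concentration × dilution ÷ days since previous
  media change`; no carryover correction is applied for 50% media
  exchanges (documented simplification). Below-detection values stay
  missing (never zero); analytes need ≥ 2 detected timepoints to be
  Z-scored, and missing Z entries are mean-imputed (→ 0 on the Z scale)
  only inside the clustering distance computation. Lag estimation
  interpolates both series onto a daily grid and maximizes the Pearson
  correlation of transcript(t) with protein(t + d) over candidate lags,
  requiring ≥ 3 overlapping days; ties within 1e-9 of the maximum resolve
  to the smallest lag.

## Problem sizes used in the checks

The recovery checks run at the default design (≈ 2.3k genes × 18 samples),
with 2,000 genes for correlation calibration (20 seeds), 1,000 background
genes + one 50-gene block for driver recovery (10 seeds), 200 × m = 1,000
all-null vectors for FDR control, and 20 seeds × 3 injected lags for the
secretome. These sizes give Monte-Carlo errors comfortably below the
assertion margins while keeping a full run in minutes on one CPU.

## Known limitations

- The Welch-t substitute is underpowered at n = 3 relative to moderated
  tests; users with sequencing-scale data should import externally computed
  fold-change tables (supported everywhere) if they need calibrated
  per-gene significance at low replication.
- The lag estimator's resolution equals the candidate-lag grid (1 day), and
  for smooth chronic trajectories adjacent lags correlate almost equally,
  so single noisy estimates can shift by a day; conclusions should be drawn
  from the modal estimate across analytes or replicates.
- Panel content is user-supplied; the package ships no published gene
  panels, only synthetic fixtures keyed to the generator's blocks.
- Cell-type attribution is a ranked-marker summary, not a deconvolution; it
  assumes the reference expression matrix is on a comparable log2 scale.
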
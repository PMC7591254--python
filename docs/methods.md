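# Methods

`microrepop` re-implements, as a tested pipeline over synthetic data with
planted ground truth, the computational analysis that identifies a
CSF1R-inhibition-resistant, progenitor-like MAC2+/Lgals3-high microglial
subpopulation in single-cell RNA-seq, together with the accompanying
immunofluorescence quantification. This note records the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Synthetic cohort generator (`simulate`)

The generator emulates a three-condition design: untreated controls (Ctrl,
3 samples), the end of a two-week CSF1R-inhibitor course (D0, 3 samples),
and two days of repopulation (D2, 2 samples). Each sample draws
`n_cells_per_sample` cells (default 1,000) from a per-condition mixture
over nine populations: five myeloid states (homeostatic, chemokine-high,
ribosomal/translation, MHC/Cd74-high, proliferative) and four contaminants
(neutrophil, lymphoid, endothelial, astroglial; ~9% of cells in total,
matching the share removed as non-microglial in the real data). Default
mixtures put the proliferative state at 0.12% of Ctrl cells and ~10% of
D0/D2 cells, and enrich Ctrl in the homeostatic state — the condition
shifts the abundance model is meant to detect.

Counts are negative binomial, `var = mu + mu^2 / size` with a single global
`size` (default 8), sampled as a gamma–Poisson mixture. Per-cell means are
built from:

- a per-gene baseline drawn once from a Gamma(0.45, 1) (heavy-tailed
  mean-expression profile);
- population multipliers: each population's marker panel is shifted up by
  `panel_logfc` (default 2.3 nats); the myeloid core markers (Itgam, Aif1,
  Cx3cr1, Csf1r) are strongly expressed in all five myeloid states and
  nearly absent from contaminants; homeostatic markers stay detectable but
  reduced outside the homeostatic state;
- the Lgals3-high immature program: with per-condition probability
  `mac2_frac` (defaults 3.0% / 9.8% / 11.2%, the observed MAC2+
  frequencies), a myeloid cell shifts its program-up genes (Lgals3, Lyz2, a
  yolk-sac slice, an early-embryonic slice) up by `effect_logfc` (default
  1.5 nats) and its program-down genes (Tmem119, P2ry12, Cx3cr1, Csf1r,
  Mafb, Selplg) down by the same amount;
- a per-cell mitochondrial fraction drawn from a beta distribution (mean
  4%), with a small tail (3% of cells, mean 16%) crossing the 10% QC
  cut-off so the filter has work to do;
- a lognormal library size (`meanlog = ln 5000`, `sdlog = 0.35`); per-cell
  gene weights are normalised so the expected total equals the drawn
  library size.

Lgals3 itself has a pinned baseline (2.0 relative units) rather than a
gamma draw: it is the gate-defining marker and must be reliably detected
across cells, as it is in the real data; leaving its baseline to chance
would make gate behaviour an artifact of the gene-level seed.

The seven developmental stage sets (YS, E1, E2, P1, P2, A1, A2) are carved
out as pairwise-disjoint panels; the program-up genes overlap YS/E1 and the
program-down genes sit in A1/A2, so signature scoring sees the qualitative
structure the study reports (up-DEGs enriched in YS/E1, down-DEGs in
A1/A2). What the generator does **not** model: doublets, ambient RNA, batch
effects, read-level noise, or gene–gene correlation beyond the population
mixture — so passing tests show the pipeline recovers planted structure
under NB noise, not that it is robust to those real-data artifacts.

## Quality control (`qc`)

Cells are kept when 500 ≤ total UMI ≤ 20,000, ≥ 200 genes are detected, and
mitochondrial genes account for ≤ 10% of counts; genes are then kept when
detected in ≥ 10 surviving cells. Boundary conventions are the literal
reading of the stated rules ("below 500" → strict `<`, etc.). All cell
rules are evaluated jointly on the input matrix (so their order is
immaterial) and the gene rule runs on the survivors. Percent-mito is
computed before any gene removal. An optional cell blacklist stands in for
the study's manual outlier removal, for which no rule is published.

## Normalisation, reduction, clustering (`preprocess`, `clustering`)

Log-normalisation is `ln(1 + count * 10000 / cell_total)`. Total UMI and
percent-mito are then regressed out per gene by OLS; the residuals feed
variable-gene selection, PCA, and clustering only — detection-based
statistics (the hurdle test, gating) read the log-normalised matrix, whose
zero structure the residuals would destroy.

"Most variable" genes are ranked by variance standardised against a lowess
mean–variance trend (ties broken by gene order); the top 3,000 enter PCA.
Genes are centred and unit-scaled; components 1–10 are retained; component
signs are fixed by making the largest-magnitude loading positive.

Clustering is Leiden modularity optimisation (seeded, deterministic) on a
Jaccard-weighted shared-nearest-neighbour graph (k = 20, prune < 1/15) over
the PC scores. The source analysis names neither algorithm nor resolution,
only the resulting cluster counts (nine, then five after contaminant
removal); resolution is therefore a free parameter (default 0.8; the
analysis scripts use 0.2, which recovers the planted populations with
ARI ≥ 0.9 — modularity methods over-split at high resolution). Clusters are
annotated by marker-panel detection fractions (mean fraction of panel genes
detected per cell); a cluster whose myeloid-core score falls below 0.25 is
labelled with its best contaminant panel and removed. No 2-D embedding is
computed: clustering, not the map, carries every downstream result.

## Hurdle differential expression (`de`)

Each gene is tested with a two-part hurdle model: a binomial component for
detection (expression > 0) and an equal-variance Gaussian component for the
positive log-expression values. For a two-group contrast both components
have closed-form MLEs, so the likelihood-ratio statistic is computed
exactly and vectorised over genes:

- detection: `2 [ll(ka/na) + ll(kb/nb) − ll(k/n)]`, 1 df when the pooled
  detection is neither 0 nor 1;
- continuous: `N ln(SS0 / SS1)` over the positive values, 1 df when both
  groups contain positives and N ≥ 3.

The sum is referred to chi-square with the summed informative df; a gene
zero in both groups is untestable (p = 1). Fold change is the standard
log-normalised-data convention, `ln(mean(exp(x) − 1) + 1)` difference, so
the 0.25 (cluster markers) and 0.5 (MAC2+ vs homeostatic) thresholds keep
their usual meaning. Genes must also be detected in ≥ 10% of either group.
No cellular-detection-rate covariate is included by default (config flag).

Multiple testing: Bonferroni over **all** genes in the matrix (the standard
single-cell convention), with Benjamini–Hochberg available. Adjusting only
over the fold-change-filtered genes would be anti-conservative, because the
filter selects for extreme observed differences. Null simulations (NB
counts, identical parameters in both groups, 200 genes × 200+200 cells)
put the type-I error at ~5–6% at α = 0.05; the chi-square reference is
slightly liberal in the far tail on skewed log-normalised data, which the
matrix-wide Bonferroni absorbs in practice.

## MAC2 gating (`gating`)

A cell is MAC2+ when its log-normalised Lgals3 exceeds the pooled mean plus
`k_sd` sample (n−1) standard deviations, computed over **all** cells, zeros
included, with a strict inequality ("one standard deviation above the
average"). The threshold is global, not per condition, since the study
gates once on the combined object. At the planted defaults (3% carriers,
1.5-nat effect) the gate reaches sensitivity ≥ 0.9 and specificity ≥ 0.9
against ground truth; the residual false positives are the upper tail of
the non-carrier Lgals3 distribution, which is why gated frequencies run a
few points above the planted fractions.

## Signature overlap (`signatures`)

Stage sets load from GMT; disjointness is enforced (a non-strict flag
exists for exploratory sets). A DEG list is scored as the percentage of its
genes in each stage set (two decimals, matching the donut labels), with
unassigned genes making up the remainder — counts always sum to the list
length. Gene matching is case-insensitive. Venn comparisons are plain
two-set partitions, and a hypergeometric upper-tail test replaces the
out-of-scope GSEA/IPA machinery for enrichment questions.

## Differential abundance (`abundance`)

Cells-per-cluster counts per sample are modelled as NB with log link and
`ln(total cells captured in the sample)` as offset, condition as the
covariate (treatment coding, Ctrl reference; default contrasts D0 vs Ctrl
and D2 vs Ctrl). Coefficients are fit by IRLS. With 2–3 samples per
condition, per-cluster dispersion is hopeless, so a common dispersion is
shared across clusters: per-cluster Poisson fits give means, a single alpha
maximises the pooled NB profile likelihood, and one NB refit of the means
stabilises the estimate. Each contrast is tested by a quasi-likelihood
deviance F test — the deviance drop divided by the cluster's residual
deviance per df, referred to F(1, df_resid) — which keeps the null
rejection rate in simulation at ~4–5% with 3+3 samples. With no residual
df (one sample per level) the test falls back to a likelihood-ratio
chi-square with a warning. No correction across clusters by default
(BH by flag).

## Imaging (`imaging`)

Each channel is thresholded adaptively: foreground where intensity exceeds
the local mean over an odd window (default 51 px) plus an offset. The
offset should sit at or above ~1 SD of the background noise; on noiseless
renders any positive offset works. Objects are 8-connected components with
`min_size` ≥ 30 px (defaults; all exposed as CLI flags, since the original
macro parameters are unpublished). Two objects colocalize when their mask
intersection exceeds 10% — strictly — of the **smaller** mask; the
published phrase is ambiguous about the denominator, and the min-mask rule
is symmetric (alternatives are configurable). Pairing is one-to-one by
largest intersection, ties to the lower label, preventing double counting
in dense fields. Phenotypes partition the anchor (IBA1) objects by which
marker channels pair with them; per-object mean intensity uses the anchor
masks. The synthetic renderer plants non-overlapping disks per phenotype
with known intensities and Gaussian noise, so counts are checkable exactly
(noiseless) or within 5% (noise SD = 20% of signal).

## Orchestration and determinism

`run_pipeline` executes simulate/ingest → QC → normalise/regress/HVG/PCA →
cluster → strip → gate → DE (MAC2+ vs the cluster scoring highest on the
homeostatic panel) → signature overlap → abundance, writing per-stage
artifacts and a versioned JSON report. One root seed derives per-stage
seeds through `numpy.random.SeedSequence`; all stages, including Leiden,
are deterministic given the config.

## Problem sizes

The test suite and the reproduction script run everything at desk scale,
chosen to keep sampling error well inside the asserted bands: 30,000 cells
for gating recovery; 500 replicates of 200 genes × 200+200 cells for hurdle
calibration; 1,000 replicates of 5 clusters × 6 samples for abundance
calibration; 3,200–4,800-cell cohorts for the end-to-end runs; 1,000 ×
1,000 px fields with 200 cells for imaging. Full-accession scale (36,391
cells) is supported by the same code paths via the 10x-style reader.

## Known limitations

- The hurdle test's chi-square reference is asymptotic; far-tail p-values
  on heavily skewed genes are mildly liberal.
- The common-dispersion scheme is a deliberate simplification of the
  empirical-Bayes machinery of the named framework; with many samples a
  per-cluster dispersion would be preferable.
- Synthetic data carry no gene–gene correlation within populations, so
  clustering is easier than on real data at matched effect sizes.
- The 2-D embedding of the original figures is intentionally absent.
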
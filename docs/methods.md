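# Methods

This note documents the models, defaults, and numerical choices behind
`coexpnet`, and what the synthetic-data experiments do and do not show.

## Co-expression network model

The network stage assumes expression rows are approximately driven by a
small number of latent factors ("module eigengenes"): genes loading on
the same factor are mutually correlated, and a factor may trend with an
external trait. Concretely:

* **Similarity.** Pearson correlation between gene rows, stored signed.
  Zero-variance genes are a hard error (a correlation is undefined for
  them); they must be removed upstream.
* **Adjacency.** Signed (default): a_ij = ((1 + S_ij)/2)^β, so
  anti-correlated genes become *disconnected* rather than connected;
  unsigned |S_ij|^β is available by flag. The source text for this
  workflow is ambiguous between the two conventions; signed is chosen
  because signed network analysis is what it states was adapted, and
  the absolute value then belongs only inside the unsigned variant.
  β defaults to 3. The scale-free fit scan (`soft_threshold_scan`, R²
  of log-frequency vs log-connectivity over 10 log-spaced bins) is
  advisory and never overrides the configured β.
* **Topological overlap.** The standard unsigned TOM formula applied to
  whichever adjacency was chosen, diagonal fixed at 1. The vectorized
  implementation is checked against a direct triple-loop evaluation of
  the formula (agreement < 1e-12 on random matrices).
* **Module detection.** Average-linkage clustering on 1 − TOM. The full
  published dynamic hybrid tree-cut algorithm is *not* reproduced;
  module extraction is a static cut plus a minimum module size (30) and
  an eigengene-correlation rescue of unassigned genes (|r| ≥ 0.3).
  When no explicit cut height is given, the cut is chosen by a
  deterministic scan over the midpoints between consecutive merge
  heights, keeping the cut that maximizes the number of clusters of at
  least the minimum size (ties resolved toward the highest such cut).
  This adaptive rule exists because TOM dissimilarities between
  *distinct* modules sit well below 1 under signed adjacency at small β
  (a correlation of zero still yields a_ij = 0.5^β), so any fixed cut
  near the dendrogram top collapses everything into one cluster.
* **Eigengenes.** First right-singular vector of the row-standardized
  module matrix, rescaled to unit sample variance and sign-oriented to
  correlate non-negatively with the module's mean standardized profile.
  Variance explained is the leading singular value's share.
* **Merging.** Modules whose eigengenes are closer than 0.25 in 1 − cor
  are unioned iteratively until stable; merging never increases the
  module count.
* **Module–trait correlation.** Pearson r with two-sided p from the
  t-transform with n − 2 degrees of freedom; raw (unadjusted) p-values,
  as conventional for module–trait heatmaps. Constant trait columns
  yield NaN rather than an error.

Colors follow the conventional palette (turquoise, blue, brown, …) in
decreasing module size; grey always means "unassigned".

## Neighborhood enrichment screen

Background N = all genes in the interaction graph; K = co-expressed
genes present in the graph. For each such gene with at least one
neighbor, a = co-expressed neighbors, b = remaining neighbors, and the
p-value is the hypergeometric upper tail P(X ≥ a) with X ~
Hypergeom(N, K, a + b) — equivalent to a one-sided Fisher exact test on
the 2×2 table [[a, K − a], [b, N − K − b]]. `b` counts neighbors *not*
in the co-expressed set, so a + b is the gene's degree; this convention
reproduces the published ratio column (a/(a+b)) and p-values of the
31-gene reference table to printed precision. FDR is Benjamini–Hochberg
across all tested genes; the published FDR column of that table is
internally inconsistent (it matches p × 392 on some rows only), so the
p-value column, not the FDR column, is the reproduction target. The
"tumor-specific" cutoff defaults to FDR < 0.01.

A note on calibration: an exact discrete test is *super-uniform* under
the null — P(p ≤ t) ≤ t with strict deficit set by the hypergeometric
atom sizes. Pooled over many genes the deficit does not average away,
so null p-values from the screen are conservative by construction: the
observed fraction below 0.05 lands near 0.02–0.04 and a
Kolmogorov–Smirnov test against the continuous uniform rejects at any
realistic pooled size. The meaningful calibration property — the screen
is never anti-conservative, and produces essentially no FDR < 0.01
discoveries without planted enrichment — is what the test suite
asserts; the validation script additionally reports the measured KS
p-value and rejection fraction as-is.

## Over-representation analysis

Same hypergeometric core as the screen, applied to GMT gene sets. The
default universe is the analyzed expression matrix's gene set, not the
whole genome — enrichment against an inflated universe is
anti-conservative. Pathway databases are not shipped; tests use
synthetic GMT fixtures, and published pathway q-values (which depend on
the database release) are documented as non-reproducible.

## Survival models

* **Normalization.** FPKM→TPM (column sums 10⁶); reference-gene
  normalization on log2(x + 1) scale (the +1 tolerates RNA-Seq zeros),
  removing the reference row; per-gene z-scores with sample SD. The
  pipeline applies reference normalization then z-scoring in sequence
  when a reference gene is configured.
* **Univariate Cox.** Single-covariate proportional-hazards fit with
  Efron tie handling, Wald p, HR = exp(β̂) per SD of expression (inputs
  are z-scored upstream), normal-theory 95% CI. Non-convergent fits are
  flagged and excluded downstream rather than raised. Screening keeps
  p < 0.05 by default.
* **Kaplan–Meier / log-rank.** Median split with ties assigned to the
  low group; the split depends only on ranks, so the p-value is
  invariant to monotone transforms of expression.
* **LASSO-Cox.** Coordinate-descent L1 path (up to 100 penalties,
  log-spaced down to 0.001 × the smallest penalty that zeroes all
  coefficients; the solver may stop the path early once it saturates).
  Fold assignment is seeded and stratified by event status; folds
  without events are re-drawn from a derived seed. Held-out deviance is
  −2 × Breslow partial log-likelihood of the test fold at the
  train-fold coefficients, and the optimal penalty minimizes its mean
  (`lambda.min`). The minimizer rather than the 1-SE rule is used
  because the workflow this package implements reports a small optimal
  λ with a two-gene signature, which only the minimizer produces.
  Given data, fold count, and seed, the result is deterministic.

## Synthetic cohorts

The generator produces what the analysis assumes, no more:

* **Expression.** Five ordinal stages (normal, CIN1, CIN2, CIN3,
  tumor); default 100 samples split (19, 11, 17, 31, 22), mirroring the
  proportions of a staged cervical lesion series. Module m's latent
  eigengene is e_m = effect_m · z(stage) + N(0, 1) with the ordinal
  stage standardized; member genes are baseline + loading · e_m +
  N(0, noise_sd) with loadings uniform on [0.5, 1] (all positive by
  default so signed and unsigned analyses agree on clean data; a flag
  enables mixed signs) and per-gene abundance baselines uniform on
  [4, 12] (log-scale intensities are positive, which keeps the
  coefficient of variation meaningful). Defaults: three 60-gene modules
  with effects (1.0, −0.8, 0.6) — mixed signs, as in real module–trait
  heatmaps, which also keeps the modules mutually distinguishable — plus
  60 pure-noise background genes, noise SD 0.3. With all-positive
  effects on a shared stage term, eigengenes would correlate ≈ 0.6 with
  each other and modules would not be separable co-expression units.
* **Probes.** 1–3 probes per gene (uniform), Gaussian jitter SD 0.1,
  plus 10 unannotated "idle" probes.
* **PPI.** Barabási–Albert graph (2000 nodes, 10 edges per arrival ⇒
  mean degree ≈ 20, matching large curated human interactomes), with
  co-expressed gene ids scattered uniformly over nodes. Enrichment is
  planted by rewiring each edge of the 30 highest-degree non-planted
  co-expressed genes to a random member of a 40-gene planted set with
  probability 1 − 1/enrichment (default enrichment 4). At enrichment 1
  no edge is touched, giving an exchangeable null for the screen.
* **Survival.** Hazard exp(Σ β_g z(x_g)), exponential event times,
  independent uniform censoring on [0, T_max] with T_max calibrated by
  bisection to the target censoring rate (default 0.2).

All generators are deterministic given the config seed; each generator
draws from an independent child stream, so requesting probe tables or
survival never perturbs the expression draw.

**What passing tests do and do not show.** The synthetic cohorts have
Gaussian noise, linear stage effects, exactly block-structured modules,
uniformly scattered PPI labels, exponential baselines and independent
censoring. Real cohorts violate all of these (batch effects, heavy
tails, overlapping modules, annotation-biased interactomes, informative
censoring), so the recovery results certify the implementation, not
performance on any particular real dataset. Published full-scale
figures (e.g. 25 modules from 10,016 genes on a 128-sample series, a
959-gene module network, a 17,381-node interactome averaging 19.6
neighbors, specific signature λ values) depend on external data
releases and are carried as reference documentation only — with the one
exception of the 31-row screen table, whose statistics are exactly
recomputable from its printed counts.

## Experiment sizes

The validation experiments use 20 seeds for module recovery, 50 for
null calibration, 500 simulated cohorts (n = 300) for Cox
bias/coverage, and 100 cohorts (n = 400, 22 genes) for LASSO selection
recovery — sizes at which the Monte-Carlo error of each reported
quantity is several times smaller than its acceptance margin, while the
whole script stays under a minute on one CPU.

## Known limitations

* No out-of-core or blockwise mode: matrices are dense in memory,
  targeting ≤ ~12,000 genes.
* No robust/bicor correlation, no alternative TOM variants, no missing
  value support in the network stage (impute or drop upstream).
* Symbol matching to the interactome is exact after uppercasing; no
  alias or ortholog expansion.
* The published hybrid dynamic tree-cut is approximated (see above), so
  exact module counts from published full-scale analyses are not
  expected to reproduce.
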
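# Methods

## Model

For gene *g* (of *G*) and cell *i* (of *n*) with counts `Y_gi`, the model is

    Y_gi ~ NB(mu_gi, phi_g),  Var(Y_gi) = mu_gi + phi_g * mu_gi^2
    log mu_gi = sum_{l=1..L} s_gl(T_li) Z_li + U_i alpha_g + offset_i

Cells enter exactly one lineage's smoother: the binary assignment `Z` is
drawn once per dataset from the user-supplied soft lineage weights
(categorical draw on each cell's row-normalized weights, seeded and
recorded; cells with a single positive weight are deterministic). The
`phi -> 0` limit recovers Poisson counts.

### Spline basis

All genes and lineages share one basis: the cardinal natural cubic spline
basis on K knots placed at quantiles of the pooled assigned pseudotimes
(K = 3 puts knots at the minimum, median and maximum). `b_k` is the natural
cubic interpolant of the k-th unit vector, so K knots give exactly K
coefficients per lineage, the basis satisfies partition of unity exactly
(it spans constants, so each lineage carries its own level without a global
intercept), and smoothers are C2. Prediction outside the training range is
clamped to the boundary with a warning. Duplicate quantile knots are
collapsed (with a warning) and fewer distinct pseudotimes than knots is an
error.

### Penalty and fitting

The penalized objective per gene is `deviance + lambda_g * beta' S beta`.
`S` is, by default, the block-diagonal curvature matrix — the integrated
squared second derivative of each lineage smoother, computed exactly
(cubic-spline second derivatives are piecewise linear). Its null space is
the lineage-wise linear trend, so `lambda -> inf` shrinks each smoother to a
straight line on the log scale while leaving levels and slopes free; this
is what lets GCV actually trade off smoothness against fit. A plain ridge
on the spline coefficients (`penalty="ridge"`) is available but shrinks the
expression *level* toward zero counts, so GCV then refuses to smooth
expressed genes and the near-unpenalized smoothers wiggle at the
boundaries; the curvature penalty is the default for that reason.
Covariate coefficients are never penalized. One `lambda_g` is shared across
lineages so the smoothers stay comparable between lineages.

Fitting alternates three seeded, deterministic steps:

1. **IRLS for beta** at fixed `phi` and `lambda`, with working weights
   `W = mu / (1 + phi mu)` (times any observation weights), batched across
   genes on the shared design, and step halving so the penalized deviance
   never increases (a violation beyond 1e-8 marks the gene non-converged).
2. **lambda by GCV** on a log-spaced grid (20 points, 1e-4..1e4 by
   default), score `n * D(lambda) / (n - edf)^2` with
   `edf = tr[(X'WX + lambda S)^{-1} X'WX]`, swept warm-started at the
   moment-initialized dispersion; the per-gene argmin is kept.
3. **phi by profile likelihood**: golden-section search on `log phi` in
   [1e-6, 1e4] at the current means.

Steps 1 and 3 then alternate at the selected lambda until the relative
change of the penalized objective drops below 1e-6 (at most 50 outer
rounds). The coefficient covariance used by all Wald tests is the penalized
(Bayesian) form `Sigma = (X'WX + lambda S)^{-1}`; `aic = -2 loglik +
2 (edf + 1)`, counting the dispersion as one parameter. All-zero genes and
non-finite fits are flagged non-converged and carry NA through every
downstream table; they are never dropped, so gene indexing is stable.

`evaluate_k` refits a random gene subsample over a grid of K and reports
the per-gene AIC matrix and the mean-AIC-optimal K (AIC rather than BIC,
which tends to favour overly rich bases here).

### Offsets

`compute_offsets` defaults to geometric-mean-centred log library size,
which is exact when composition is constant. The model, however, estimates
offsets by positive-count median-of-ratios (DESeq-style) when none are
supplied: when a fifth of the transcriptome is differential between
branches — the benchmark design — library totals carry a composition shift
of more than a log unit between branch tips, and library-size offsets then
make every null gene differential in relative terms. Median-of-ratios is
robust as long as a minority of genes is differential. Users can pass any
offsets.

### Zero-inflation weights

Dropout is handled by observation weights `w_gi` in [0, 1] multiplying both
the log-likelihood terms and the IRLS weights (weights of 1 reproduce the
unweighted fit bitwise). Weights come from a gene-wise two-component EM:
point mass at zero with proportion `pi_g` versus NB with mean
`exp(b0_g + offset_gi)`; the weight is the posterior NB-component
probability, exactly 1 for nonzero counts. With dynamic genes an
intercept-only NB absorbs the mean variation into the dispersion and then
explains dropout zeros as NB zeros, biasing `pi_g` down; `estimate_zinb_weights`
therefore uses the fitted log-means of a first-pass unweighted NB-GAM as
per-observation EM offsets (a uniform dropout rate scales that first-pass
mean by roughly `1 - pi` everywhere, which the free intercept absorbs).
Genes whose EM fails fall back to weights of 1 with a warning.

## Wald tests

Every test is `H0: C' beta_g = 0` with statistic
`(C'b)' (C' Sigma C)^+ (C'b)`, where the pseudo-inverse comes from an
eigendecomposition of `C' Sigma C`; eigenvalues below `eig_tol` (relative
to the largest, default 1e-2) are treated as zero and the chi-squared
degrees of freedom equal the retained rank. The tolerance matters for the
grid-based tests: their contrast covariances span ~6 orders of magnitude,
and the near-null directions are almost deterministic functions of the
fitted smoothers, dominated by smoothing and lineage-range-estimation bias
rather than sampling noise — keeping them inflates the type-I error of a
between-lineage null from ~0.05 to ~0.85. Contrasts:

* **association**: K-1 consecutive coefficient differences per lineage.
* **startVsEnd**: `b(T_l,max) - b(T_l,min)` per lineage (or any two
  user-chosen points inside the lineage range).
* **diffEnd**: all L(L-1)/2 pairwise endpoint differences.
* **pattern**: for each pair, M = 100 columns comparing M equally spaced
  pseudotimes between each lineage's own min and max (the per-lineage grids
  are the length normalization; the M columns have rank at most 2K-1).
* **earlyDE**: the pattern construction restricted to the window between
  two knots of the shared knot vector, clipped to each lineage's range;
  the full-range window reproduces the pattern test exactly.

Within-lineage tests run per lineage or globally (stacked columns);
between-lineage tests run pairwise or globally. p-values are BH-adjusted
across genes within each contrast family; NA genes are excluded from the BH
denominator. Pseudotimes are treated as fixed, so p-values are best read as
ranking summaries rather than exact error probabilities. Reported effect
summaries are the endpoint log fold change (startVsEnd/diffEnd), the mean
absolute grid difference (pattern/earlyDE) and the coefficient range
(association).

`fisher_combine` aggregates p-values as `-2 sum log p ~ chi2(2m)`;
`transient_score` ranks genes by `rk1^2 + (G - rk2)^2` (average ranks on
ties) to find genes significant under one test but not another — a ranking,
not a significance measure.

## Stage-wise testing

Screening BH-adjusts a per-gene global p-value at level `alpha_I`; the R
passing genes have their individual hypotheses tested by Holm at
`alpha_II = (R / G) alpha_I` (G = genes assessed), which controls the
overall FDR — the expected fraction of genes with at least one false
confirmed hypothesis among the declared genes. Holm is used at confirmation
because only FWER control per gene is required and it is assumption-free.

## Pattern clustering

Per gene, the lineage smoothers are evaluated on 100 equally spaced points
per lineage (log-mean scale, where standardization is well behaved for
low-expression genes), concatenated and standardized to zero mean and unit
variance across the grid points of that gene; constant-pattern and
non-converged genes are excluded. Clustering runs in the top 10 PCs with a
resampled consensus around a deterministic k-medoids (maximin
initialization, PAM-style alternation; k chosen from the candidate range by
full-data silhouette): 20 subsamples of 80% of genes are clustered, pairs
co-clustered in at least 70% of their shared resamples form consensus
components, and genes without a stable partner get label -1. The base
clusterer is a pluggable callable.

## Simulator

`simulate_trajectory` emulates the benchmark conditions of trajectory DE
studies: cells uniform along pseudotime in [0, 1]; topologies single,
bifurcating (2 lineages), multifurcating (3) and cyclic (sinusoidal mean
shapes); branch point at 40% of total pseudotime, with pre-branch cells
sharing equal soft weights across lineages and post-branch cells assigned
hard; library sizes log-normal (sd 0.3); baseline log-levels N(log 10,
0.8^2) clipped to [0.5, 100] counts; NB dispersion 0.5; optional uniform
dropout at rate `pi_zero`. Effect sizes are log-uniform on [log 2, log 8]
with random sign. In branching topologies half the genes (configurable)
carry a lineage-shared dynamic base shape (linear, sigmoid or bump); DE
genes add a deviation on one random lineage after the branch — 50%
pattern-type (smooth divergence to the end), 25% endpoint-only (late ramp),
25% transient-only (a bump that vanishes again by the end, invisible to
endpoint tests). Null genes have identical mean functions on every lineage.
The defaults mirror the bifurcating benchmark design (500 cells, 5000
genes, 20% DE); the single/cyclic topologies label dynamic-vs-constant
genes for within-lineage truth. `SimTruth` records every generating
parameter and exposes the true log-mean functions and per-pair DE labels.

What the simulator does **not** emulate: pseudotime estimation error (times
are exact), doublets, batch effects, gene-gene correlation, non-uniform
cell density along lineages, and lineage spans of genuinely different
lengths. Passing tests therefore validate the statistical machinery under
the stated generative model, not robustness to trajectory-inference error.

`fdp_tpr_curve` sweeps a ranking (smaller = more significant; NA genes are
non-discoveries) and reports `FDP = FP / max(1, FP + TP)` and
`TPR = TP / (TP + FN)` at every cutoff; `benchmark_run` chains
simulate-fit-test-curve for named tests.

## Problem sizes and determinism

The validation workloads use deliberately desk-scale designs: oracle
equivalence at n = 400 cells / 50 genes; type-I error on 2000 constant-truth
genes at n = 300; power and ranking on 1000 genes at 300 cells with 20% DE;
knot selection on 60-gene subsamples over 10 seeds; zero-inflation recovery
on 300 genes; OFDR on 20 replicates of the 750-cell multifurcating design;
clustering on 6 planted families of 50 genes. All randomness is routed
through explicit integer seeds; the simulator, the lineage assignment,
clustering resamples and gene subsampling derive per-purpose child streams
from the seed (seeding two different components with the same bare integer
must not replay identical uniforms — that coupling once sent every
pre-branch cell to one lineage). Identical seeds and settings give bitwise
identical fits.

## Known limitations

* The Wald tests use plug-in `phi` and the penalized covariance; with very
  few cells per lineage (a few dozen) the between-lineage tests become
  anti-conservative because lineage ranges are estimated from assigned
  cells and range noise enters the length-normalized grids.
* The pattern test's length normalization treats each lineage's observed
  pseudotime span as comparable; if spans differ for non-biological
  reasons, warping the pseudotimes first is the user's responsibility.
* `pi_g` estimation needs expressed genes; for genes whose NB zeros are
  common everywhere the dropout proportion is weakly identified.
* The EM and the GAM are fitted in two passes, not as a joint ZINB-GAM
  likelihood.
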
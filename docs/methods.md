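# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limits of `ticscore`.  It states nothing
the test suite or `scripts/acceptance.py` does not itself compute.

## The analysis model

The pipeline assumes bulk expression is, on the linear scale, approximately
a nonnegative mixture of cell-type reference profiles plus tumor-intrinsic
programs, observed under multiplicative noise and per-platform (batch)
location/scale distortions.  Its stages and their assumptions:

**Unit conversion.** TPM is used as the common within-sample unit:
`TPM_g = rate_g / Σ rate_g × 10^6`, where the rate is FPKM itself or
count/length.  TPM is compositional — a sample's values sum to a constant —
which matters later (see the α/β split).

**Batch adjustment (ComBat model).** On log2(TPM+1), per-gene batch
location and scale effects are estimated on standardized residuals and
shrunk toward batch-level priors (normal for location, inverse-gamma for
scale, hyperparameters by method of moments, iterated conditional modes).
Our implementation reproduces `sva::ComBat` to ~1e-15 on identical input
(verified in the test suite via `Rscript`).  Two properties users sometimes
expect do **not** hold, by design of the EB model: per-gene batch means are
not forced to agree after adjustment (shrinkage deliberately retains part
of the per-gene sampling noise; only the systematic, cross-gene component
is fully removed), and per-gene grand means move slightly (observed ~5e-3
on typical sizes).  Tests assert removal of the systematic shift and
per-gene F-statistic reduction instead.

**Deconvolution.** Linear-kernel ν-SVR of the z-scored mixture on the
globally z-scored signature, ν grid {0.25, 0.5, 0.75}, lowest-RMSE solution
kept (tie → smaller ν), negatives truncated, renormalized (relative mode:
fractions sum to 1).  An NNLS backend (nonnegative least squares plus a
free intercept) provides a fast independent route; the two agree within
0.03 per fraction on clean mixtures.  Deconvolution consumes linear TPM;
everything downstream consumes log2(TPM+1).  Permutation p-values shuffle
the mixture's gene labels and refit; the add-one estimator
(1 + #{null ≥ obs})/(n_perm + 1) avoids p = 0.  Default 1000 permutations;
they are expensive (a full refit each), so the cohort wrapper computes them
only on request.

**Consensus clustering.** Item resampling only (80% subsamples, default
1000 resamples), PAM with deterministic greedy build + best-improvement
swap so all stochasticity lives in the resampling, consensus entries =
co-clustered / co-sampled.  k selection: relative delta-area of the
consensus CDF, `Δ_k = (A_k − A_{k−1})/A_{k−1}` (Δ at the smallest k is its
own area).  A k qualifies when `Δ_k ≥ 0.1` **and** `Δ_k ≥ 0.5·Δ_{k−1}`; the
selected k is the largest qualifying one, with argmax-Δ as a logged
fallback.  The second (elbow) condition exists because adding one cluster
beyond the true number splits a real cluster semi-stably and reliably
yields Δ just above 0.1 even on ground-truth features, while Δ at the true
k is ~4× larger; an absolute threshold alone therefore over-selects.  On
unstructured data the rule stops early (typically k = 3 with shrinking
gains); no rule can recover a "true" k that does not exist, and the log
notes the fallback when it fires.

**Moderated t.** One-vs-rest contrasts per subtype.  Per-gene pooled
variance s², prior (d₀, s₀²) by method of moments on log s² under the
scaled-F model (trigamma inversion by Newton), posterior
s̃² = (d₀s₀² + d·s²)/(d₀ + d), t = log2FC/(s̃·c), p with d₀ + d df.  d₀ is
clamped to [0.1, 500]; when the log-variance dispersion is at or below its
sampling floor the prior degenerates to the mean variance with d₀ at the
upper clamp (which also makes the equal-variance limit exact).  Zero
variance in both groups → t = 0, p = 1, logged.  Gene filter: BH-adjusted
p < 0.05 (strict) and |log2FC| ≥ 1.5 (inclusive); log2FC is a difference of
group means on the log scale.

**α/β split and ordering.** Samples are consensus-clustered on the DEG
matrix; clusters are mapped to an ordered code by their mean per-sample
z-score over DEG genes (ascending).  This statistic was chosen over the
first principal component because a PC orders only the clusters separated
by the dominant variance axis and carries an arbitrary sign; the mean-z is
sign-free and orders every cluster.  The ordering is anchored only when the
up- and down-programs are unbalanced; with perfectly symmetric programs the
ordering is still deterministic but driven by sampling noise.  A DEG joins
α (positive) or β (negative) only if its Spearman correlation with the code
is significant at 0.05 **and** its per-cluster mean profile is monotone
along the code in the correlation's direction, tolerating counter-direction
wiggles up to 25% of the profile's range.  The monotonicity condition
exists because a gene peaking in an interior cluster has no direction along
the gradient, yet can show a substantial nonzero correlation purely through
TPM compositionality (samples rich in other programs have everything else
scaled down); absorbing such genes corrupts the principal component of
whichever set takes them.

**Boruta.** Per iteration: one shuffled shadow per real feature, a random
forest (80 trees, depth ≤ 5, impurity importances — the choice of the
widely used Python implementation, and ~20× cheaper than permutation
importances at no observed loss on the planted benchmarks), hit = beating
the best shadow.  Cumulative two-sided binomial tests against p = 0.5,
Bonferroni over **all** features (the reference implementation's
multiplicity handling; correcting only over undecided features lets lucky
streaks confirm under the null).  Undecided at max_iter (default 100) →
tentative; the score uses confirmed genes, falling back to the full set if
a feature set confirms nothing.  Boruta's response variable is the
gene-cluster label.

**TIC score.** One PC per feature set on z-scored training expression,
oriented to correlate positively with the set's mean z-score (single-gene
sets reduce exactly to that gene's z-score); TIC = PC1(α) − PC1(β).
Projection onto a new cohort re-standardizes within that cohort (training
moments do not transfer across platforms), drops missing genes (error below
80% coverage), and renormalizes the loadings to unit norm.

**Cutpoint.** Candidates are observed scores between the 10th and 90th
percentiles; the returned cutoff maximizes the two-group log-rank
statistic.  The associated p-value is *not* adjusted for the scan; it is a
maximally selected statistic and anti-conservative under the null, which
the implementation logs and a dedicated null simulation demonstrates.

**Survival and association statistics.** Own vectorized product-limit and
k-group log-rank (events precede censorings at ties; hypergeometric
covariance; cross-checked against lifelines at 1e-9), scipy-backed rank
tests with mid-rank ties (rank-sum: exact for n ≤ 25 without ties,
otherwise normal approximation with continuity and tie correction; a
statistic exactly at its null mean returns p = 1 by symmetry), Pearson
chi-square without continuity correction, Spearman with t-approximation
p-values, AUC by the rank/Mann–Whitney identity with half-credit ties.
Mutation contrasts use Fisher's exact test rather than chi-square because
per-gene 2×2 tables in cohort-sized data have small expected counts; the
sample odds ratio gets a Haldane 0.5 correction at zero cells, and only
genes mutated in ≥ 3 samples are tested (BH over those).  TMB =
nonsynonymous count / capture megabases (default 38 Mb; raw counts also
reported, since the normalizing denominator is a convention).

## Synthetic study conditions

The generator's defaults define the conditions every recovery test runs
under; they were fixed once, for testability, and are not tuned per test.

| parameter | default | why |
|---|---|---|
| batches (samples) | 80 / 28 / 63 | three pooled platforms, 171 samples total |
| cell types | 22 | reference-signature convention |
| subtypes | 3 | planted infiltration subtypes; Dirichlet α = 4.0 on a subtype-specific block of cell types, 0.6 elsewhere |
| genes | 500 = 264 signature + 115 program + 121 background | programs sized (20, 35, 60) |
| program shift | 2³ × baseline in the own subtype | clears the 1.5 log2FC filter with margin |
| noise_sd | 0.2 (log-e) | per-entry multiplicative noise |
| batch shift / scale sd | 0.3 / 0.1 | per-(gene, batch) location and scale distortion |
| hazard | log-hazard = −1.0 × axis, baseline 1/1500 d⁻¹, exponential censoring at 0.43× baseline | ~30% censoring; high axis = good prognosis |
| response | logit = −1.2 + 3.0 × axis | ~35% overall response, strong planted link |
| mutations | BAP1-like 0.55→0.12 and EIF1AX-like 0.08→0.45 across the axis, plus two flat background genes | prognosis-linked mutation contrast |
| drug links | 5 of 12 compounds, strength 0.7 | AUC anticorrelated with the axis via a logistic monotone map |

The **latent prognostic axis** is the standardized subtype code, subtypes
ordered by mean program expression; program sizes are strictly increasing
so the order is strict, and the largest-program subtype is the
good-prognosis end.  The middle subtype's program is non-monotone along the
axis by construction — the α/β monotonicity filter is what keeps it out of
the score, and the end-to-end Spearman recovery (>0.9 observed) depends on
that.

What the generator does **not** emulate: read-level sampling, gene-gene
correlation beyond the planted programs, copy-number structure, dropout,
covariate-linked censoring, or realistic effect sizes (the planted response
link is deliberately strong so that transfer AUC is a sharp test; real
immunotherapy cohorts show far weaker contrasts).  Passing tests therefore
demonstrate correctness of the machinery and recoverability under the
stated conditions, not expected performance on real cohorts.

## Problem sizes in tests

The default test run scales simulations to keep the suite practical on one
CPU: consensus resampling is typically 100–250 (default 1000), Boruta
max_iter 40–50 (default 100), deconvolution permutations 19 in the
calibration test (default 1000; the add-one p-value granularity 1/20 still
makes the uniformity check meaningful), and calibration loops use 300–500
seeds as stated per test.  `scripts/acceptance.py` uses 250 resamples and
completes in well under a minute; the pipeline's `FAST_PRESET` mirrors the
same reductions for interactive use.

## Known limitations

- The α/β orientation chain (cluster code → split → PC signs) is anchored
  by program asymmetry; cohorts whose up- and down-programs are exactly
  balanced get a deterministic but arbitrary score sign.
- The cutpoint p-value is unadjusted for maximal selection (logged); treat
  it as descriptive.
- Permutation p-values for deconvolution refit the full model per
  permutation and are costly at the 1000-permutation default.
- `select_k` answers "which k is most stable under this rule", not "is
  there any clustering at all"; on structureless data it still returns a k
  (with shrinking delta-areas and, when nothing qualifies, a logged
  fallback).
- The mutation module parses minimal MAF columns only and treats every
  nonsynonymous class equally; no variant-level weighting.
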
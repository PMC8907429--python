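# Methods

## The model

`irgpi` implements a rank-based gene-pair signature for predicting response
to immune checkpoint inhibitors (ICI) and survival from bulk tumor
transcriptomes. The primitive is the **gene-pair indicator**: for a pair of
genes written `A|B`, a sample scores 1 when A's expression strictly exceeds
B's within that sample, and 0 otherwise (ties score 0). Because the
indicator depends only on the within-sample ordering of two genes, it is
exactly invariant under any strictly increasing transform applied per
sample — different transforms for different samples included. This is the
property that lets cohorts profiled on different platforms (RNA-seq FPKM,
TPM, counts, arrays) be concatenated into a single "meta cohort" with no
normalization step, and it is enforced by an exact (bitwise) property test.

The **index** of a sample is a weighted sum of pair indicators,

    IRGPI(s) = Σ_i score_i(s) · β_i ,

with Cox-derived weights β. The sign convention is that higher index values
mean higher hazard and a lower probability of responding (CR/PR under
RECIST), so the low-index group is the predicted-responder group.

## Discovery pipeline

1. **Gene universe.** Genes shared by all cohorts, optionally intersected
   with a user-supplied curated immune-gene list (ImmPort-style). Symbols
   are matched case-sensitively after whitespace trimming; duplicate rows
   resolve to the highest-mean row.
2. **Pair enumeration.** Canonical unordered pairs (n(n−1)/2, smaller
   symbol first). The reverse orientation `B|A` is the exact complement of
   `A|B` and carries identical information with flipped coefficient sign,
   so only one orientation is enumerated by default (`both` is available
   for fidelity experiments).
3. **Constant-pair filter.** A pair whose score is 0 or 1 in strictly more
   than 80% of the samples of *any* cohort carries almost no
   survival-splitting information and is removed. The filter streams over
   pair blocks so the full pair×sample matrix (≈650k pairs for ~1100 genes)
   is never resident; output is independent of block size by contract.
4. **Univariate screening.** Each surviving pair splits the meta cohort
   into its score-0/score-1 groups; a two-group log-rank test against
   overall survival is computed from the standard risk-table recursion
   (O−E and hypergeometric variance per distinct event time, χ² on 1 df).
   Pairs constant after subsetting are reported with p = 1 and flagged
   rather than dropped, keeping the result aligned with the pair list.
   Benjamini–Hochberg step-up q-values control the FDR; candidates are the
   pairs with q strictly below 0.001. An optional univariate-Cox Wald mode
   is provided and agrees with the log-rank p within 0.02 on moderate
   samples (they are asymptotically equivalent score tests for a binary
   covariate).
5. **Multivariate fit.** Candidate sets are typically far larger than the
   event count, so the default fit is two-stage: an L1-penalized Cox
   partial likelihood (lasso path via coordinate descent) with the penalty
   chosen by k-fold (k = 10, seeded) cross-validated partial-likelihood
   deviance selects a sparse pair set; an unpenalized multivariate Cox
   refit on the selected pairs gives the final coefficients. When the
   candidate count is at most events/5 a single-stage unpenalized fit is
   used (`auto` mode). Monotone-likelihood pairs (|coef| > 10 after refit)
   are dropped with a warning and the model refitted. The CV fold seed is a
   required configuration field, so fitted signatures are reproducible.

A published 31-pair melanoma signature (53 distinct gene symbols; several
genes recur across pairs) ships with the package at full printed precision
behind a checksum, so cohorts can be scored without refitting.

## Evaluation

* **ROC / Youden.** Thresholds are midpoints between consecutive distinct
  scores plus ±∞ sentinels; with the default direction a sample is
  predicted responder when score ≤ threshold. AUC is the trapezoidal area
  and equals the tie-corrected Mann–Whitney statistic (tested to 1e-12).
  The operating cutoff maximizes Youden's J = sensitivity + specificity − 1,
  with ties broken toward higher sensitivity and then the lower threshold
  (a deterministic rule; any choice on the tie set attains the same J).
* **Confusion summary.** Counts plus sensitivity/specificity/accuracy as
  percentages rounded to one decimal, and the observed responder fraction
  in the low and high score groups.
* **Survival comparison.** Kaplan–Meier curves per group (product-limit,
  via lifelines), the same log-rank implementation used in screening, and a
  hazard ratio from an in-package one-parameter Newton–Raphson Cox fit with
  Breslow tie handling (Wald 95% CI). When the partial likelihood is
  monotone (e.g. a perfect split of early vs late deaths) the log-HR is
  clamped at ±20 and flagged — the HR is then a bound, not an estimate.
  Median survival is the first time the curve reaches 0.5, reported as
  undefined when it never does.
* **OS-driven cutpoint.** For cohorts without response labels, an
  exhaustive log-rank scan over all admissible splits (each group at least
  ⌈10%·n⌉ by default) returns the minimal-p cutoff plus the full scan
  table. The minimal p is optimism-biased (no Miller–Siegmund correction);
  it is a cutpoint chooser, not a significance level, and the log says so.
* **Meta-analysis.** Per-cohort log hazard ratios pooled by fixed-effect
  inverse variance: w = 1/se², pooled = Σwx/Σw, SE = 1/√Σw, Cochran's Q on
  k−1 df, I² = max(0,(Q−df)/Q)·100. Fixed effect is appropriate here
  because the pooling is over cohorts scored by one shared signature.

## Tumor-microenvironment scoring

Single-sample enrichment uses the rank-weighted running-sum integral:
within a sample, genes get average ranks (N = highest expression); walking
the list from the top, the cumulative in-set weight fraction (weights
|rank|^α, α = 0.25 by convention) minus the uniform out-of-set fraction is
accumulated, and the score is the sum of the running differences. Scores
depend only on within-sample ranks, so they inherit the same platform
robustness as the pair indicators (tested for α = 0 and α = 0.25).
Optional normalization divides the whole score matrix by its global range.
Gene sets come from user-supplied GMT files; no biological gene lists are
packaged. Group comparisons use the two-sided Wilcoxon rank-sum test
(normal approximation, tie-corrected), BH-adjusted across features in
batch mode.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes and
is itself first-class, tested code:

1. latent expression g ~ lognormal(μ_gene, σ), gene means drawn once;
2. a latent binary "responder-like" class per sample orients every planted
   pair: with probability 1 − flip the two genes' values are swapped (if
   needed) so that the indicator takes its class-consistent value —
   planting the signal at the *order* level keeps the indicator
   distribution exactly controlled whatever the marginal expression model;
3. latent index L = Σ β_i·indicator_i, centered at its median;
4. OS ~ exponential with hazard λ₀·exp(β_surv·L); independent exponential
   censoring with its rate calibrated by bisection so the expected censored
   fraction matches the target; PFS at twice the OS hazard;
5. reported RECIST labels: responder with probability logistic(−β_resp·L),
   responders split CR/PR and non-responders SD/PD;
6. per-cohort strictly increasing platform transforms (identity, square,
   log1p, positive-slope affine) applied last, which provably leave every
   indicator unchanged.

All randomness flows from one root seed through named substreams
(expression, class, swaps, survival, censoring, response), making the full
simulate→build→score→evaluate chain bit-reproducible.

**Default study conditions** (chosen once, documented here): three cohorts
of 41/28/51 samples mirroring a three-cohort anti-PD-1 discovery setting;
a 200-gene universe with ten planted pairs on disjoint genes (coefficients
±0.6…±1.0); responder fraction 0.44; flip probability 0.05 and β_surv = 1
as the strong-signal condition; baseline hazard ln(2)/25 per month (median
OS ≈ 25 months at the index median); 40% censoring; β_resp = 2.

**What the generator does not emulate:** RNA-seq count noise (negative
binomial overdispersion), batch effects beyond monotone distortions,
correlation structure among non-planted genes, and real melanoma biology.
Passing tests therefore demonstrate the pipeline's statistical correctness
and its rank-invariance guarantees, not clinical performance on real
cohorts.

**A known statistical limit.** Because every planted pair is oriented by
the same latent class, planted indicators are mutually correlated at
roughly (1−2·flip)² ≈ 0.81 under the default conditions. In the
multivariate Cox fit this inflates per-coefficient standard errors to ≈0.3
at ~300 events, so the weakest planted coefficients (|β| = 0.6) sit near
Wald z ≈ 2 and recover their sign in roughly 94% of replicates — individual
signs of near-collinear covariates are intrinsically hard to pin down even
when the fitted index itself is highly predictive (per-coefficient sign
accuracy across replicates is >99%).

## Numerical choices

* Ties in pair scoring go to 0 (strict ">"); "over 80%" in the constant
  filter is a strict inequality; FDR selection is strictly below threshold.
* The log-rank statistic uses the (n−d)/(n−1) hypergeometric variance
  correction for tied events; zero-variance, single-group and zero-event
  splits are defined errors (flagged p = 1 inside the screening loop).
* The binary Cox Newton step is clamped to ±1 per iteration (the partial
  likelihood is concave but a full step can overshoot on strong effects);
  convergence tolerance 1e-10, coefficient cap ±20 for monotone
  likelihoods.
* Index scoring forces a canonical (C-contiguous) memory layout before the
  dot product so BLAS rounding cannot differ between two frames holding
  identical indicators — the exact invariance property depends on it.
* Expression TSVs are written with `repr` floats and parsed with Python
  `float()`, so write→read round-trips are bit-identical.
* Scales used by the shipped checks: the simulation-based tests run at
  40–500 samples and 30–200 genes, sizes at which every guarantee they
  assert (calibration bands, recall, reproducibility) is already binding.

## Limitations

* The OS-driven cutpoint scan reports an uncorrected minimal p.
* The lasso stage's penalty grid and fold count are defaults, not tuned;
  elastic-net mixing is out of scope.
* No covariate adjustment in screening or evaluation; no time-dependent
  ROC; no competing risks.
* Deconvolution scores (ESTIMATE/CIBERSORT-style) are not computed; such
  per-sample features can be fed to the group-comparison operation.
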
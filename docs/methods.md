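# Methods

`gwasprio` implements pathway-knowledge-guided prioritization of GWAS
results: it estimates, from the data themselves, how strongly each
user-supplied gene set (pathway, ontology term, transcription-factor target
list, ...) is enriched for association signal, converts those enrichments
into per-SNP prior probabilities of association, and turns the priors into
p-value weights that preserve the family-wise error rate.  The weighted
p-values can be compared to the conventional genome-wide threshold
(5e-8) exactly like ordinary GWAS p-values.

## Model

Each SNP j contributes a one-sided Z-score, `Z_j = Phi^{-1}(1 - P_j)`.
Marginally,

    Z_j ~ (1 - delta_j) N(0,1) + delta_j f1,
    delta_j ~ Bernoulli(pi_j),
    logit(pi_j) = kappa + beta' V_j,

where `V_j` is the binary row of pathway annotations of SNP j (a SNP maps to
a pathway when it lies in, or within a configurable flank of, any gene of
that pathway), `kappa` is the log-odds of association for an unannotated
SNP, and `beta_k` is the log-odds-ratio contributed by annotation k.  The
alternative `f1` is parameterized as `N(mu, 1 + tau^2)`.

## Two-step enrichment estimation

Full maximum likelihood in this mixture is expensive and fragile with
hundreds or thousands of annotations.  The package instead uses a two-step
estimator:

1. **Marginal posteriors.**  Ignoring annotations, each SNP's marginal
   posterior probability of association (mPPA) is `psi_j = 1 - lfdr(z_j)`,
   with the local false discovery rate computed against a theoretical N(0,1)
   null: the marginal Z density is estimated by a Lindsey-type fit (120
   equal-width histogram bins; Poisson regression of bin counts on a natural
   cubic spline of the bin midpoints with 7 degrees of freedom), the null
   proportion by central matching `pi0 = min(1, fhat(0)/phi(0))`, and
   `lfdr = min(1, pi0 phi(z)/fhat(z))` is made monotone non-increasing in z
   over the upper tail by isotonic regression.

2. **Penalized logistic regression.**  SNPs with bit-identical annotation
   rows are merged into equivalence classes (sizes `n_i`), and the
   class-mean mPPA `psibar_i` (clipped into `[1e-6, 1 - 1e-6]`) is regressed
   on the class annotation row with the elastic-net-penalized binomial
   deviance

       -2 loglik(kappa, beta) + lambda (alpha |beta|_1 + (1-alpha) |beta|_2^2),

   each class carrying prior weight `n_i`, so the collapse is exactly
   information-preserving.  The default `alpha = 1` (LASSO).  Fitted values
   `pihat_i = logistic(kappa + beta' V_i)` are the shrunken class priors.
   This two-step fit is a single EM step from a valid initial estimate, so
   on well-specified data a further EM refinement barely moves the
   estimates (monitored in the test suite).

The optimizer is a damped IRLS with cyclic coordinate descent on the
working weighted least-squares problem, in covariance (Gram-matrix) form so
a sweep costs O(K^2) independent of the number of classes; steps are
accepted by backtracking halving so the penalized objective decreases
monotonically, and convergence is declared on the KKT subgradient
conditions (tolerance `1e-9 * sum(n_i)`).  Fits along a penalty path are
warm-started.  The default path has 100 geometrically spaced values from
`lambda_max` (the smallest penalty with all coefficients zero, available in
closed form) down to `0.001 lambda_max`.

### Accuracy of the two-step estimates

With exact posteriors as the response, the regression recovers the
generative parameters essentially exactly (verified in tests).  With
estimated mPPA, two biases propagate: central matching slightly
over-estimates `pi0` when the alternative contributes density near zero,
which multiplies all `psi` down and attenuates the fitted log-odds; and
density smoothing leaks posterior mass onto moderate null Z-scores, which
inflates the mPPA-weighted variance of the alternative.  At M = 50,000 with
a well-separated alternative (mean 4), the attenuation of a true
log-odds-ratio of 1.5 is about 0.2; with a weaker alternative (mean 3) it
can reach 0.35.  These are biases of the posterior-estimation stage, not of
the regression; they shrink the weights toward 1 and are therefore
conservative for error control.

## Prioritized testing

Given class priors, weights `w_i > 0` with class-size-weighted mean one
(`sum_i n_i w_i / M = 1`) preserve the expected number of false positives
under the global null at per-SNP thresholds `alpha w_i / M` — the analytic
identity `sum_i n_i (alpha w_i / M) = alpha` holds exactly by the
constraint.  Each SNP's weighted p-value is `min(1, p_j / w_i)` (weights
floored at 1e-6 before division).

Weights are parameterized through the class prior log-odds
`b_i = logit(pihat_i)`:

* **Simple weighting (SPW):** `w_i proportional to exp(b_i)` — weights
  proportional to prior odds.
* **Cubic weighting (CPW):** `w_i proportional to
  exp(g1 b_i + g2 b_i^2 + g3 b_i^3)`, with `(g1, g2, g3)` chosen by
  Nelder-Mead (start `(1,0,0)`, at most 500 iterations, objective and
  parameter tolerance 1e-8) to maximize the expected number of true
  positives

      E[TP] = sum_i n_i pihat_i F1bar( Phibar^{-1}( alpha w_i / M ) ),

  where `F1bar` is the upper tail of the alternative `N(mu, 1 + tau^2)` and
  `Phibar` the standard normal upper tail.  SPW is the `(1, 0, 0)` special
  case and the optimizer's starting point, so the CPW objective never falls
  below the SPW objective; if the optimizer fails or ends below the start,
  the SPW weights are returned.  `(mu, tau^2)` are estimated by
  mPPA-weighted moments of the Z-scores, `tau^2` floored at 0, with a
  fallback to `(2, 0)` if all posteriors vanish.  All weight normalization
  is computed in log space; equal log-odds short-circuit to exactly unit
  weights so a fully shrunk model reproduces unweighted analysis bit for
  bit.

## Penalty choice by cross-validation

The LASSO penalty is chosen by 10 half-split replicates.  SNPs are cut into
genome-contiguous segments (default 100 SNPs, roughly sub-megabase at GWAS
density) and whole segments are assigned to the training half with
probability 1/2, so local LD blocks stay together.  For each replicate and
each candidate penalty, the prior model is fitted on the training half and
Simple weights are formed on the held-out half (class sizes recomputed
there); the held-out E[TP] is evaluated **with the held-out half's own
class-mean mPPA standing in for the class priors**.  The selected penalty
maximizes the replicate-mean score, ties going to the larger penalty (more
shrinkage).

Scoring with held-out posteriors, rather than the trained model's own
priors, is what makes the criterion honest: if the model's priors were
reused, the same fit would supply both the weights and the payoff and the
score would grow monotonically with weight spread, so a pure-null dataset
would select the most overfit penalty.  With held-out scoring a pure-null
dataset yields a flat score curve and the tie-break returns the largest
penalty (weights identically 1), and over-fitted penalties score below the
optimum because weights aligned with training noise find no matching signal
in the test half — both behaviors are asserted in the test suite.

## Whole-genome simulation design

The simulator reproduces a retrospective case/control design at summary
level:

* **Causal loci.**  Each locus has a control-population allele frequency
  `p0` and per-allele odds ratio `OR`; the case frequency is
  `p1 = OR p0 / (1 - p0 + OR p0)`.  Allele counts are drawn binomially
  (Hardy-Weinberg within each group) for `n1` cases and `n0` controls and
  summarized by the signed allelic test `Z = (phat1 - phat0)/SE` with
  pooled-frequency SE.  The large-sample mean of this Z (the square root of
  the allelic-test noncentrality) is available in closed form and used as a
  test oracle.  A bundled illustrative set of 25 synthetic loci spans MAF
  0.1-0.4 and OR 1.2-1.6 — the range of suggestive GWAS hits for a common
  complex disease; the values are invented, not taken from any catalog.
* **Associated regions.**  Each causal SNP carries a +/- 1 Mb window of
  SNPs whose Z-scores are correlated with the causal Z as
  `r(d) = exp(-d / ld_decay)` (default decay 50 kb): at distance d,
  `Z = r Z_c + sqrt(1 - r^2) eps`.  All remaining SNPs are independent
  N(0,1).  One-sided p-values are `1 - Phi(Z)`.
* **Gene layout.**  Every simulated SNP is hosted by exactly one gene:
  causal-region SNPs by the causal gene, null SNPs by null genes tiled in
  disjoint blocks (default 50 SNPs per null gene at 1 kb spacing) placed at
  least 10 Mb from every causal window.  Gene intervals exactly cover their
  SNPs, so positional mapping at flank 0 reproduces the host-gene
  assignment — asserted in tests.
* **Synthetic pathway lists.**  `Tp` enriched pathways each receive `Tg`
  causal genes (sampled without replacement within a pathway, with
  replacement across pathways) padded with null genes to a fixed pathway
  size (default 20 genes out of 100 pathways).  Raising `Tg` while lowering
  `Tp` increases the connectivity of causal genes and should increase the
  power of weighted analysis.
* **Evaluation.**  Type-1 error at level t is the replicate-averaged
  fraction of null SNPs (outside all +/- 1 Mb windows) with (weighted)
  p <= t; power is the fraction of causal SNPs rejected, pooled over
  replicates, and per causal SNP.

What the simulator does *not* emulate: realistic genome-wide LD from a
reference panel (regions are exponential-decay blocks around single causal
SNPs), allele-frequency spectra, overlapping genes, gene-length variation,
or annotation noise (every SNP maps cleanly to one host gene).  Passing
simulation tests therefore demonstrates the statistical mechanics of the
method — error-rate preservation, enrichment learning, shrinkage control —
not robustness to misannotation or complex LD.

## Problem sizes and numerical choices

Desk-scale defaults keep studies reproducible on one CPU: simulation
studies in the test suite use 15-25 replicates of 20,000 null SNPs plus 25
causal loci at 1,500/1,500 cases/controls; the acceptance script's Type-1
run uses 100 replicates of 50,000 null SNPs; cross-validation inside
simulation studies uses a 20-point penalty path down to `0.01 lambda_max`.
Monte-Carlo tolerances in tests are derived from the binomial standard
errors of the quantities at the sizes actually run.

Other numerical constants: Z-scores are clamped to |z| <= 38 (the probit
transform of the smallest representable p-values); p = 1 inputs are pulled
to `1 - 1e-16`; p = 0 inputs are dropped; class-mean mPPA is clipped into
`[1e-6, 1 - 1e-6]`; per-class rejection thresholds `alpha w_i / M` are
clipped below 1.  Reruns with identical inputs and seeds are bit-identical;
all simulation randomness descends from a single seed through spawned
generator streams.

## Known limitations

* mPPA estimation treats SNPs as independent; LD induces correlated
  Z-scores that the local FDR ignores (class means average over correlated
  neighbors).  Segment-preserving cross-validation mitigates, but does not
  remove, the resulting optimism.
* The `pi0`/smoothing biases above make enrichment estimates conservative;
  very weak genome-wide signal can shrink all weights to 1.
* The alternative is a single Gaussian; strongly multimodal signal
  (e.g. a few enormous hits plus many weak ones) inflates `tau^2` and can
  make the cubic-weight optimization flatten.
* Gene symbols are matched case-insensitively with no alias resolution;
  supplying coordinate and pathway files built on different symbol
  vocabularies silently reduces overlap (logged per pathway).
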
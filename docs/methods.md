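# Methods

## Problem and model

In a case-control GWAS with `G` SNPs, `n_x` cases and `n_y` controls, the
question for each SNP is whether its minor-allele frequency (MAF) differs
between the two groups. `gwasmix` treats this as a clustering problem with
three pre-specified clusters:

* **cluster 0** — same MAF in cases and controls (no association),
* **cluster +** — MAF higher in cases,
* **cluster −** — MAF lower in cases.

Genotypes are coded as minor-allele dosages `S ∈ {0, 1, 2}`. Under
Hardy-Weinberg equilibrium a subject's genotype at a SNP with MAF θ is
trinomial with probabilities ((1−θ)², 2θ(1−θ), θ²), i.e. the dosage is
Binomial(2, θ). The genotype profile of SNP `g` is therefore fully
summarized per group `d ∈ {x, y}` by the sufficient statistics
`(n_d, m_d, h_d)`: non-missing subject count, minor-allele count, and
heterozygote count.

The per-SNP likelihood given the MAFs is

```
L(θ_x, θ_y) = 2^(h_x + h_y) · θ_x^{m_x} (1−θ_x)^{2n_x − m_x}
                           · θ_y^{m_y} (1−θ_y)^{2n_y − m_y}.
```

A conjugate Beta(α, β) prior is placed on the MAF scale. The three cluster
priors are:

* cluster 0: one shared θ ~ Beta(α, β), so the marginal likelihood is a
  Beta-multinomial: `ξ_0 = 2^h · B(α + m, β + 2N − m) / B(α, β)` with
  `m = m_x + m_y`, `N = n_x + n_y`;
* cluster +: a *half-flat* bivariate prior `2 h(θ_x) h(θ_y) 1{θ_x > θ_y}`
  (h the Beta(α, β) density), giving
  `ξ_+ = 2^h · 2 · [B(a_x, b_x) B(a_y, b_y) / B(α, β)²] · P(U > V)`
  where `a_d = α + m_d`, `b_d = β + 2n_d − m_d`, and `U ~ Beta(a_x, b_x)`,
  `V ~ Beta(a_y, b_y)` are the per-group posterior laws of the MAF;
* cluster −: the mirror image with `P(U < V)`.

The factor 2 makes the restricted prior proper; the shared `2^h` multinomial
coefficient cancels between clusters and is dropped in production (a flag on
`LogMarginals` records this; it is kept when the marginals are checked to sum
to one over the genotype sample space).

SNP cluster membership is a latent trinomial with proportions
π = (π_0, π_+, π_−) carrying a Dirichlet(b_0, b_+, b_−) prior, the
pseudo-counts acting as prior SNPs per cluster.

## Ordering probability P(U > V)

`ξ_±` needs `P(U > V)` for two Beta laws with real-valued (moment-matched)
parameters, for which no finite closed form applies. It is computed by
256-node Gauss-Legendre quadrature of `∫ f_V(v) [1 − I_v(a_x, b_x)] dv`
(`I` the regularized incomplete beta), evaluated in log space with
log-sum-exp so that strongly separated groups give accurate tiny
probabilities rather than underflow. The integration interval is the union
of the two distributions' `[1e-14, 1 − 1e-14]` quantile ranges: at GWAS
sample sizes both posteriors are sharply concentrated, and a fixed-order
rule on all of [0, 1] would waste its resolution on regions of negligible
mass. The quadrature is validated in the test suite against adaptive 2-D
quadrature of the defining double integral (abs. tolerance 1e-7) and
against the exact identity `P(U>V) + P(U<V) = 1`, which it reproduces to
~1e-12. Results for the two signs use the same interval, so exchanging the
case and control blocks swaps `log ξ_+` and `log ξ_−` bit-for-bit.

SNPs sharing `(n_x, m_x, n_y, m_y)` have identical marginals up to the
separable `2^h` factor and are computed once; at `G = 20,000`, `n = 200`
this cuts the work by roughly 5×.

## EM over mixture proportions

Because the MAFs are integrated out, π is the only free parameter. The
E-step computes responsibilities `γ_gk = π_k ξ_k / Σ_j π_j ξ_j` in log
space; the M-step is the Dirichlet MAP update
`π_k ← (Σ_g γ_gk + b_k − 1) / (G + Σ_j (b_j − 1))`. The log posterior
(mixture log likelihood plus Dirichlet log prior) is tracked and must be
non-decreasing; convergence is declared when it changes by less than
`tol = 1e-8` (default `max_iter = 1000`; with precomputed marginals an
iteration is O(G)).

Initial π comes from the SNP-wise tests: SNPs with raw p < 0.05 are
provisionally labelled +/− by the sign of the observed MAF difference and
π⁰ is the label proportions, floored at 1/G per component.

## Calling rules and FDR

Two rules produce calls from γ:

* **max posterior** — argmax over clusters, ties resolved to cluster 0;
* **FDR threshold** (default) — call SNPs with `max(γ_+, γ_−) > τ`; the
  model-based FDR estimate of a called set is the mean null responsibility
  `γ_0` over the set. Because this estimate is not monotone in τ, the rule
  returns the *largest* threshold-defined set whose estimate is ≤ the
  nominal level (exhaustive over the G candidate thresholds via a sorted
  prefix scan; semantics pinned by a brute-force oracle test). The FDR of
  an empty called set is defined as 0.

## Hyper-parameters

* **α, β (MAF prior).** Two elicitation routes, both by moment matching —
  the untruncated Beta with the same mean and variance as the target, kept
  untruncated because only the untruncated Beta is conjugate:
  * *reference*: Beta(2, 5) truncated to (min observed post-QC MAF, 0.5).
    At lower bound 0.05 this gives α ≈ 3.29, β ≈ 9.56.
  * *empirical*: moment match the observed pooled per-SNP MAF estimates.
  Truncated moments use exact incomplete-beta ratios, not quadrature.
* **Pseudo counts (b_0, b_+, b_−).** Default (3, 3, 3), a weak prior;
  (5, 5, 5) and (20, 20, 20) are exposed as presets. Values must be ≥ 1 so
  the MAP M-step stays well defined.
* **Nominal FDR.** Default 0.05.

## SNP-wise baseline

The comparator is the traditional per-SNP test plus Benjamini-Hochberg.
The default test is the Cochran-Armitage trend test with scores (0, 1, 2)
and the margin-conditional variance (vectorized over SNPs; degenerate
tables get p = 1 and a flag). Per-SNP logistic regression (Wald test,
two- or one-sided, odds ratios with 95% intervals, separation flagged) is
available and agrees with the trend test asymptotically; the trend test is
the simulation default purely because fitting 2 × 10⁶ logistic models per
benchmark would dominate runtime. A permutation validation procedure
recomputes the one-sided logistic statistic under shared phenotype
permutations and reports add-one permutation p-values with BH over the
candidate list only.

## Synthetic data generator

The generator emulates the benchmark design: per-SNP MAFs drawn i.i.d.
from Beta(α, β) truncated to (0.05, 0.5) (default Beta(2, 5); three
misspecified laws Beta(2, 4), Beta(1.5, 3.5), Beta(1.5, 5.5) are in the
scenario grid), HWE trinomial genotypes, independent SNPs, and a balanced
case/control split. Null SNPs share one MAF draw between groups. Effective
SNPs draw *two* i.i.d. truncated-Beta values assigned by order statistics —
the larger to cases for cluster +, to controls for cluster −. This is the
generative counterpart of the half-flat prior; the source design does not
print its effect-size mechanism, so this construction is this package's
own choice and is what the recovery tests assume. Effective SNPs default
to an even +/− split. Truncated-Beta sampling is exact inverse-CDF (no
rejection), so datasets are bit-reproducible from the config seed.

The scenario grid crosses the four MAF laws with G ∈ {1,000; 20,000;
500,000} and n ∈ {200; 1,000} (half cases). The G ≥ 20,000 scenarios carry
200 effective SNPs; G = 1,000 is scaled to 20.

What the generator does **not** emulate: linkage disequilibrium, population
stratification, genotyping error, informative missingness, covariates.
Passing benchmarks therefore demonstrate correctness of the method under
its own modelling assumptions (independent SNPs, HWE, shared MAF scale),
not robustness to those real-data complications.

## Evaluation harness

`run_comparison` simulates fresh replicates (per-replicate seeds spawned
deterministically from one master seed) and runs each analysis arm
end-to-end at the same nominal FDR: the SNP-wise baseline, the mixture with
the reference prior, and the mixture with the empirical prior. Scoring
follows the standard definitions: realized FDR = proportion of truly
non-effective SNPs among called SNPs (0 for an empty set), sensitivity =
proportion of truly effective SNPs called. A call with the wrong sign still
counts as a detection for these headline metrics; directional correctness
is reported separately (`sign_agreement`). Specificity is intentionally not
reported. Paired per-replicate differences are compared with a one-sided
Wilcoxon signed-rank test (zeros dropped; exact null for n ≤ 25 without
ties, otherwise normal approximation with tie correction).

The shipped acceptance script uses the G = 20,000 / 200-effective /
n = 200 / truncated-Beta(2, 5) scenario with 100 replicates for the
Wilcoxon comparison and the first 20 replicates for mean/median summaries —
a desk-scale rendition of the flagship G = 500,000 benchmark that preserves
its effective-SNP count and sample size.

## Numerical and design notes

* Missing genotypes are handled complete-case per SNP (`n_d` varies by
  SNP), keeping the likelihood exact without imputation.
* Minor-allele orientation is decided once at load on the pooled sample, so
  every stored pooled MAF is ≤ 0.5 and cluster definitions refer to the
  same allele in both groups.
* Default QC: call rate ≥ 0.95, pooled MAF ≥ 0.05, HWE exact-test p ≥ 1e-6
  in controls (conventional GWAS thresholds, all configurable). The HWE
  test conditions on allele counts and sums probabilities of heterozygote
  counts no more likely than the observed one.
* The trend statistic is discrete: in a balanced design an exact score tie
  (Z = 0, p = 1) has probability ~2% at n = 1,000, which places a visible
  atom at p = 1 in null p-value distributions. Calibration below p ≈ 0.99
  is unaffected; tests therefore check tail quantiles where rejection
  happens.
* EM π-recovery is verified under a well-specified generator (MAF law =
  analysis prior) with a flat Dirichlet (b = 1), because informative pseudo
  counts shrink the MAP estimate by (b−1)/G by design.
* All simulation seeds are spawned from a single master seed via
  `numpy.random.SeedSequence`; no global RNG state is used anywhere.

## Known limitations

* No covariate adjustment or population-structure correction; SNPs whose
  effect direction flips across strata violate the cluster definitions.
* SNPs are modelled as independent given cluster; LD is ignored.
* α, β are fixed before the EM (moment matching); re-estimating them inside
  the EM loop is not implemented.
* The FDR estimate is model-based (mean γ_0); its agreement with realized
  FDR degrades if the MAF prior is badly misspecified, although the
  benchmark shows the ordering versus the baseline is robust to the
  misspecified MAF laws in the scenario grid.
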
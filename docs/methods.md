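# Methods

This note records the statistical model the package implements, the
numerical conventions chosen where several were possible, and what the
synthetic evaluation does and does not demonstrate.

## Model and transformation

Observations follow `y = X β + ε` with `cov(ε) = Σ = σ²·S`, a single
covariate of interest (column *k*) and `q` nuisance columns (at least an
intercept).  The scale split is pinned by the normalization
`1' S⁻¹ 1 = 1`, i.e. `σ² = 1/Σᵢⱼ(Σ⁻¹)ᵢⱼ`; this makes the GLS intercept
estimate the S-weighted mean `1' S⁻¹ y` and gives the centering operator
`I − J S⁻¹` its simple form.

The covariance itself is modelled as `Σ = W^{-1/2}·Cor·W^{-1/2}`: a diagonal
matrix of known inverse-variance weights (for RNA-seq, sequencing depth in
million reads) around a block-exchangeable correlation — every subject/block
of size `n_l` has within-block correlation `ρ`, blocks are independent.
`Cor_l(ρ) = (1−ρ)I + ρJ` is positive definite for
`ρ ∈ (−1/(n_l−1), 1)`; estimates are clamped to that interval shrunk by
1e-6 on each side so downstream decompositions stay well posed.

The PB operators are computed once per (design, covariance):

* `C = I − X₋ₖ(X₋ₖ' S⁻¹ X₋ₖ)⁻¹ X₋ₖ' S⁻¹` residualizes the nuisance columns.
  The structure of the residual space is taken as `M = C S C'`, which for an
  intercept-only nuisance equals `S − J` exactly.
* `B = Λ^{-1/2} T' C` from the eigen-pairs of `M` (descending eigenvalues,
  rank cut at `1e-10 ×` the largest; the null space must have dimension
  exactly `q`, otherwise a conditioning error is raised).  This form makes
  `B S B' = I` and `B X₋ₖ = 0` hold by construction; both are asserted in
  the test suite rather than trusted.  Any whitening of `M` differs from
  this one only by an orthogonal row mixing, which provably leaves the final
  statistic unchanged (the suite checks the sign-flip case explicitly).
* `P = I − Q(I₂ − Rot)Q'` with `QR` of `(1 | z)`, `z = B xₖ`.  QR signs are
  fixed by requiring a positive diagonal of `R`, which pins `P` uniquely.
  Degenerate alignment (`z` numerically collinear with `1`) falls back to
  the identity (positive multiple) or a Householder reflection (negative
  multiple); the generic path never divides by `1 − ξ²` at ξ near ±1.

`Ỹ = P B y` then has mean `ζ β 1` and covariance `σ² I`, with
`ζ = ‖z‖/√(n−q)`, and the effect estimate is `mean(Ỹ)/ζ`.

### Eigenvector conventions

Eigenvectors returned by the symmetric eigensolver have arbitrary sign, and
under repeated eigenvalues an arbitrary basis.  Signs are fixed by making
each eigenvector's largest-magnitude entry positive.  Quantities that depend
on the basis within a degenerate eigenspace — notably the alignment cosine
`ξ` — are therefore reproducible but not canonical; every test statistic,
p-value and `ζ` is basis-invariant and is what the package treats as
contract.  (For `S ∝ I` the whole spectrum of `S − J` is degenerate, so
"`ξ = 0` for a balanced two-group design" holds only for particular bases
and is deliberately not asserted.)

## Correlation estimation

With weighted residuals `ε̂ᵢ = √wᵢ (y − X β̂_W)ᵢ` (diagonal-weight least
squares on the full design), `cov(ε̂)` is proportional to the block-diagonal
correlation alone, and with

`SS₁ = Σ_l ε̂_l' ε̂_l`,  `SS₂ = Σ_l (Σᵢ ε̂_{li})²`

the moment estimator is
`ρ̂ = (SS₂ − SS₁) / ((1/n) Σ_l n_l(n_l−1) · SS₁)`.  On balanced designs this
equals the Gaussian MLE `(SS₂ − SS₁)/((n₁−1)SS₁)`, an identity the tests
check to machine precision.  Singleton blocks contribute identically to both
sums (cancelling in the numerator) and are excluded from the block count
`L_used`; estimation requires at least one block of size ≥ 2.  The
Olkin–Pratt multiplier `1 + (1−ρ̂²)/(2(L_used−3))` is applied only when
`L_used > 3` (it divides by `L_used − 3`); otherwise the raw estimate is
returned with a warning.

## Effective degrees of freedom

The one-sample t statistic on `Ỹ` is referred to a t distribution whose df
reflects the information actually carried by correlated, unequally weighted
observations.  Writing the covariance as the linear structure
`Σ(θ) = θ_ε W⁻¹ + θ_γ W^{-1/2} G W^{-1/2}` (G the block-membership pattern;
`ρ = θ_γ/(θ_γ + θ_ε)`), the implementation computes the GLS contrast
variance `v(θ)`, its gradient, and the REML expected information of `θ`, and
matches the first two moments of the scaled Wald statistic to `F(1, df)`.
For a single contrast this two-moment match reduces algebraically to the
Satterthwaite form `df = 2 v² / var(v̂)`.  Guarantees, all exercised by the
suite: i.i.d. equal-weight two-group data give `df = n − 2`; perfectly
paired equal-weight data give `df = n_pairs − 1` for any `ρ ∈ (0,1)`;
`df ≤ n − 1 − q` (enforced as a cap); higher `ρ` does not increase df for
paired designs with random unequal weights.  With near-equal weights the df
surface is flat near `n_pairs − 1` and sub-0.05 non-monotone wiggles across
`ρ` can occur; they are numerical properties of the plug-in information, not
errors.  `ρ = 0` or all-singleton blocks collapse to the single-variance
model and `df = n − rank(X)`.  A numerically singular information matrix
triggers a first-order fallback on the residual-variance component alone,
flagged on the context object.

## Tests on the transformed data

* `pb_ttest`: `t = mean(Ỹ)·√m/sd(Ỹ)` with sample sd (divisor m−1);
  two-sided p from the t distribution with the supplied, possibly
  non-integer, df.
* `pb_wilcoxon`: signed-rank statistic standardized by its exact null
  moments, zeros dropped, midranks for ties with the usual variance
  correction, referred to the same adjusted-df t distribution (a t reference
  is preferable to a normal one when the effective sample size is small).
* `b_spearman`: comparator for continuous covariates — Spearman correlation
  between `B y` and `B x` through the `r√((m−2)/(1−r²))` t approximation.
* `bh_adjust`: Benjamini–Hochberg step-up (via statsmodels).

Two classical limits tie the method to textbook tests and are enforced at
1e-8 in the suite: with `S ∝ I` and a two-group covariate the PB t statistic
*is* the pooled two-sample t; on complete pairs with equal weights and the
**uncorrected** plug-in moment estimate of ρ it *is* the paired t statistic.
The second identity is exact only for that plug-in: with an oracle ρ or the
Olkin–Pratt-corrected estimate, the pooled GLS variance also draws on
between-pair contrasts and the statistics differ slightly (while the df
limit `n_pairs − 1` continues to hold for any ρ).  This is how the package
reads the claim that the procedure generalizes both classical tests.

## Synthetic data

`generate_semiparametric` draws `n−1` i.i.d. variables from a symmetric base
density (normal, double-exponential, or logistic, rescaled to variance σ²)
plus one independent grand-mean variable, and maps them through
`D = S·(PB)'`, which satisfies `D D' = S − J` and `(PB)·D = I`.  The output
has exactly the target mean `1μ + xβ` and covariance `σ²S`; with a normal
base it is exactly multivariate normal.  Because the generator inverts the
transform on the signal component, a noise-free draw maps back to `ζβ·1`
identically — the package's core oracle, checked both algebraically and by
Monte Carlo moments.

The evaluation harness runs two designs of n = 40: a paired two-group
comparison (20 subject pairs, one observation per group within pair) and a
regression-type test (standard-normal covariate on 20 subject blocks of
size 2).  Per replicate, weights are drawn Uniform(0.5, 2) and treated as
known, and `spec.sigma2 = 1` scales the natural covariance
`W^{-1/2}·Cor·W^{-1/2}` (so a unit-weight observation has unit variance).
Effect sizes for the power/ROC summaries default to β = 0.6 (paired) and
β = 0.3 (regression), chosen once from the design to give mid-range power at
the 5% level.  Type-I error and power are reported as mean ± SD over
replicate sets; ROC curves pool p-values over all replicates and AUC is the
trapezoid rule over the swept threshold.

What passing these simulations shows — and does not.  The generator matches
first and second moments and block-exchangeable correlation with a shared ρ
and known weights; it does not emulate count noise, library-size-dependent
mean–variance trends, unbalanced block sizes, missingness, or correlation
structures beyond a single random intercept (AR(1), random slopes).
Calibration and power results therefore speak to the method's behavior under
its stated model, not to arbitrary real data.

## High-throughput runner

`run_pbtest` drops zero-variance features (logged), optionally estimates a
single shared ρ as the **median** of per-feature corrected estimates (the
IQR is logged as a dispersion diagnostic; the median resists boundary
estimates from low-variance features), builds one plan, transforms the whole
matrix in one product, and appends BH-FDR.  Per-feature cost beyond the
shared transform is O(n); the suite asserts the per-feature time is flat
between 10³ and 10⁴ features.  Input matrices are assumed already
variance-stabilized/normalized; sequencing depths given in raw reads are
converted to weights by ×10⁻⁶ (million reads).  Fold-change filtering is
deliberately not part of the test and not applied.

## Known limitations

* Only one covariate can be tested per plan; joint (F-type) tests of several
  covariates have no P-map counterpart.
* The correlation estimator covers a single random intercept with a common
  ρ across blocks.
* The Wilcoxon variant matches moments only to second order for non-normal
  data; higher moments of the transformed values are not controlled.
* p-values are always two-sided.
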
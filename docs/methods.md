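# Methods

## Model

`prenetmirt` fits the two-parameter multidimensional item response
(2-PL MIRT) model for binary responses.  Subject *i* (of *N*) holds a
latent trait vector θᵢ ∈ ℝᴷ with prior N(0, I_K); the probability of a
correct response to item *j* (of *J*) is

    P(y_ij = 1 | θ_i) = σ(a_jᵀ θ_i + b_j),      σ(x) = 1 / (1 + e^{−x}),

with discrimination loadings a_j ∈ ℝᴷ and intercept b_j.  Responses are
conditionally independent given θ (local independence), and the latent
covariance is fixed at the identity — correlated traits, guessing
(3-PL) parameters, polytomous items and missing responses are out of
scope.

The estimand is the J×K loading matrix A (rows a_jᵀ) and intercept
vector b, obtained by maximizing the penalized marginal log-likelihood

    (1/N) ℓ(A, b | Y) − ρ P(A),
    ℓ(A, b | Y) = Σ_i log ∫ φ(θ) Π_j P(y_ij | θ) dθ.

Two penalties are implemented:

* **prenet** (product-based elastic net):
  P(A) = Σ_j Σ_{k<k′} [ γ|a_jk||a_jk′| + ½(1−γ) a_jk² a_jk′² ].
  It penalizes only *pairs of entries within a row*, so it is exactly
  zero on any perfect simple structure (≤ 1 nonzero per row) and, as
  ρ → ∞, its minimizers have at most one nonzero loading per row.  Each
  item is thereby attached to a single latent trait — a clustering of
  items by traits — without the global shrinkage toward A = O that an
  entrywise penalty imposes.  P is non-convex but multi-convex: fixing
  all other entries, the restriction to one coordinate is an elastic
  net γ s |a| + ½(1−γ) q a² with s = Σ_{k′≠k}|a_jk′|, q = Σ_{k′≠k}a_jk′².
* **l1**: P(A) = ‖A‖₁, the comparison method.

## Estimation: stochastic EM with Pólya–Gamma Gibbs sampling

The marginal likelihood integral has no closed form.  Each stochastic
EM iteration replaces the E-step expectation by a *single* draw of the
latent variables from their posterior at the current parameters, via
one sweep of a Pólya–Gamma Gibbs sampler:

1. w_ij ~ PG(1, a_jᵀθ_i + b_j) independently over (i, j);
2. θ_i ~ N(μ_i, V_i) with V_i = (AᵀΩ_iA + I_K)⁻¹,
   μ_i = V_i Aᵀ Ω_i z_i, Ω_i = diag(w_i), z_ij = (y_ij − ½)/w_ij − b_j.

The product AᵀΩ_i z_i is evaluated as Aᵀ(κ_i − Ω_i b) with
κ_ij = y_ij − ½, cancelling the 1/w_ij analytically so tiny
auxiliaries cannot amplify roundoff.  The N Gaussian draws use batched
Cholesky factors of the K×K precisions.

**PG sampler.**  Two seedable backends:

* `devroye` (default): an exact alternating-series rejection sampler
  for the tilted Jacobi density (PG(1,c) = J*(1, |c|/2)/4), vectorized
  over the whole N×J array.  The proposal mixes a truncated exponential
  (x > 0.64) with a truncated inverse Gaussian (x ≤ 0.64); acceptance
  uses the partial alternating sums of the series coefficients.
* `series`: direct truncation of the defining weighted sum of 200
  exponential variates, with the expected value of the dropped tail
  added back.  Slower, but transparent enough to serve as the
  independent distributional cross-check of the exact sampler in the
  test suite.

**M-step.**  Given the drawn Θ, the objective separates into J
penalized logistic regressions sharing the design Θ.  The solver is
cyclic coordinate descent over loading columns and intercepts,
vectorized across items.  Each step is the exact closed-form prox of a
local quadratic model,

    a ← soft(g, ργs) / (h + ρ(1−γ)q),   g = h·a_old + ∂(mean loglik)/∂a,

with actual Newton curvature h for speed; any sweep that would decrease
the objective is rolled back and redone with the majorization bound
p(1−p) ≤ ¼, so the penalized objective never decreases across inner
iterations (monotone ascent is guaranteed, and is asserted in the
tests).  Soft-thresholding makes zeros bit-exact.  Intercepts are never
penalized.  The L1 path uses the same machinery with threshold ρ and no
ridge term.

**Stabilization.**  A finite Θ draw can separate an item perfectly,
sending its logistic MLE to infinity and feeding back through the trait
posterior.  The parameter space is therefore a box: |a_jk| ≤ 6,
|b_j| ≤ 10 (configurable).  Clipping the 1-D prox output is the exact
constrained coordinate minimizer, so monotonicity is unaffected.  True
loadings in realistic item banks are far inside this box.

**Finalization.**  The chain does not converge pointwise, so after T
burn-in iterations the last m snapshots are summarized: Â is the
entrywise *median* (if an entry is zero in more than m/2 snapshots both
middle order statistics are zero, so the median is exactly zero and the
sparsity survives averaging) and b̂ the entrywise mean.  For even m the
median is the standard average of the two middle values.

## Model selection

The penalty strength is chosen by BIC,

    BIC(ρ) = −2 ℓ(Â, b̂ | Y) + p₀ log N,

with p₀ the number of exactly nonzero loadings.  ℓ is approximated by
tensor-product Gauss–Hermite quadrature with 11 probabilists' nodes per
dimension (deterministic and reproducible; limited to K ≤ 4, with a
seeded Monte-Carlo fallback above that).  The path is fitted from the
largest ρ downward with warm starts — each fit initialized at the
previous finalized estimate — and ties in BIC go to the larger ρ
(sparser model).  Warm starts reuse parameters only, not the Gibbs
state.

## Defaults

| parameter | default | meaning |
|---|---|---|
| γ | 0.1 | prenet mixing weight (the benchmark's value) |
| ρ grid (prenet) | 3·0.8^t, t = 0..20 | geometric path |
| ρ grid (l1) | 0.1·0.8^t, t = 0..20 | geometric path |
| T (`n_burnin`) | 300 | discarded iterations |
| m (`n_average`) | 100 | retained iterations |
| `n_burnin_warm` | None (= T) | shorter burn-in for warm-started path fits |
| `inner_tol`, `inner_max_iter` | 1e-6, 200 | M-step stopping rule |
| A(0) | i.i.d. N(0, 0.1²) | initialization; b(0) = 0, θ(0) ~ prior |
| box bounds | 6 (loadings), 10 (intercepts) | stabilization |
| GH nodes | 11 per dimension | BIC likelihood |

T and m trade accuracy for time; the chains mix quickly for N ≥ 100,
J = 15, and the reduced settings used in the shipped experiments
(T = 150/m = 50 at N = 100 with `n_burnin_warm` = 60 along paths;
T = 100/m = 50 at N ≥ 500) give replicate-level results
indistinguishable from longer chains in spot checks.  Multiple restarts
are available through the seed because the prenet objective is
non-convex and fits can stop at local optima.

## Synthetic benchmark and evaluation

The generator draws θ_i ~ N(0, I_K) and Bernoulli responses from the
model.  The benchmark truth is a 15×3 perfect simple structure — items
1–5 load (0.4, 0.7, 1.0, 1.3, 1.6) on trait 1, items 6–10 the same on
trait 2, items 11–15 on trait 3 — with b = 0.  What this emulates is a
well-designed test whose items each measure exactly one ability with
graded discriminations; it does *not* emulate cross-loading items,
correlated traits, guessing behaviour or item nonresponse, so passing
recovery tests here says nothing about robustness to those features.

Estimates are identified only up to column permutation and sign, so
both metrics minimize over all 2ᴷ·K! alignments (exhaustive, K ≤ 8),
independently for each metric:

* MSE = min ‖A − Â‖_F² / (JK) — loading recovery;
* CER = 1 − min #{support mismatches} / (JK) — structure recovery.

`run_experiment` simulates replicate s with seed `base_seed + s`, fits
the BIC path, and reports per-replicate MSE/CER plus aggregates.  At
the benchmark's conditions the expected picture, which the test suite
asserts at reduced replicate counts (20 at N = 100, 10 at N = 500, 5 at
N = 1000), is: prenet mean CER ≈ 0.85 at N = 100 while the lasso path
collapses to Â = O for most replicates; at N = 500 prenet reaches
CER = 1 in a majority of replicates; at N = 1000 recovery is
near-perfect.

## Numerical choices and edge cases

* All likelihoods are computed in the log domain with log-sum-exp;
  σ and log(1 + eˣ) via `scipy.special` stable forms.
* p₀ counts bit-exact zeros only; this is valid because thresholding
  and the median finalization produce exact zeros.
* Exact zeros serialize as `0` in CSV output.
* Column-permutation equivariance of a full stochastic EM run holds
  only in distribution, not bitwise: the batched Cholesky draw and the
  coordinate sweep order both depend on column labels.  The converged
  M-step is equivariant to 1e-6 and is tested as such.
* Degenerate inputs: empty response files, non-binary cells (reported
  with their row/column labels), non-positive PG auxiliaries, empty
  trajectories and empty ρ grids all raise informative errors; a
  non-converged M-step warns and returns its best iterate rather than
  failing a whole chain.

## Limitations

* Σ = I_K is fixed; rotational indeterminacy is resolved only by the
  penalty itself (no zero-constraint identification is imposed).
* γ is fixed (0.1 by default) rather than selected.
* The stochastic EM estimate inherits Monte-Carlo noise of order
  m^{−1/2}; report-level reproducibility is by seed, not by chain
  convergence.
* Exhaustive alignment limits evaluation to K ≤ 8.
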
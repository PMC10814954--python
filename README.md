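# prenetmirt

Simple-structure estimation for multidimensional item response theory
(MIRT) models of binary test data.

## The problem

When a test measures several abilities at once, the two-parameter MIRT
model describes the probability that subject *i* answers item *j*
correctly as

    P(y_ij = 1 | θ_i) = σ(a_jᵀ θ_i + b_j),        θ_i ~ N(0, I_K),

with a K-dimensional latent trait θ_i, item discriminations a_j ∈ ℝᴷ
(rows of the J×K loading matrix A) and intercept b_j.  Unconstrained
estimates of A are hard to interpret: every item loads a little on
every trait.  Test developers usually want the opposite — a *simple
structure* in which each item measures exactly one ability, so the
loading pattern clusters items by trait.

`prenetmirt` estimates such structures by maximizing the penalized
marginal likelihood

    (Â, b̂) = argmax (1/N) ℓ(A, b | Y) − ρ P(A)

with the **prenet** (product-based elastic net) penalty

    P(A) = Σ_j Σ_{k<k′} [ γ|a_jk||a_jk′| + ½(1−γ) a_jk² a_jk′² ],

which punishes *pairs of nonzero entries within a row* — it is exactly
zero on simple structures and, as ρ grows, forces at most one nonzero
loading per row without shrinking everything to zero the way an
entrywise L1 penalty does.  The entrywise L1 (lasso) penalty is also
implemented as the comparison method.

Estimation uses a stochastic EM algorithm: the E-step is a single sweep
of a Pólya–Gamma-augmented Gibbs sampler (which makes the latent-trait
conditional exactly Gaussian), the M-step is penalized coordinate
descent over J independent logistic regressions, and final estimates
are the entrywise median (A) / mean (b) of the post-burn-in iterates,
so exact zeros survive.  The penalty strength ρ is selected by BIC
(−2ℓ + p₀ log N, p₀ = number of nonzero loadings) along a warm-started
geometric path.  See `docs/methods.md` for the full account.

Intended users: psychometricians and statisticians fitting item banks
of modest size (tens of items, K ≤ 4) who want interpretable item/trait
assignments from binary response matrices.

## Worked example

```python
import prenetmirt as pm

# simulate the 15-item, 3-trait benchmark at N = 500
Y = pm.simulate_responses(pm.benchmark_true_model(500), rng=0)

model = pm.PenalizedMIRT(Y, n_factors=3, penalty="prenet", gamma=0.1)
path = model.fit_path(config=pm.StemConfig(n_burnin=150, n_average=50,
                                           n_burnin_warm=60, seed=0))
res = path.selected_results
print(res.summary())
```

```
Penalized MIRT (stochastic EM, Polya-Gamma Gibbs)
  penalty: prenet (gamma=0.1)
  N = 500 subjects, J = 15 items, K = 3
  rho = 1.2288   nonzero loadings p0 = 15
  marginal loglik = -5036.746   BIC = 10166.711
        trait1  trait2  trait3  intercept
item1    0.000   0.000   0.468     -0.271
item2    0.000   0.000   0.595     -0.138
item3    0.000   0.000   0.873     -0.104
item4    0.000   0.000   1.091     -0.082
item5    0.000   0.000   1.213     -0.327
item6    0.000   0.000   0.368      0.174
item7    0.000   0.708   0.000      0.163
item8    0.000   1.161   0.000      0.070
item9    0.000   1.473   0.000      0.241
item10   0.000   1.492   0.000      0.207
item11  -0.444   0.000   0.000     -0.098
item12  -0.536   0.000   0.000     -0.043
item13  -0.916   0.000   0.000     -0.032
item14  -1.243   0.000   0.000     -0.027
item15  -1.655   0.000   0.000      0.202
```

Reading the output: BIC picked ρ = 1.23 out of the 21-value path; the
selected loading matrix has exactly 15 nonzero entries, one per row —
a perfect simple structure.  Items 11–15 form one cluster (the overall
column sign is not identified; −1.655 and +1.655 are the same fit),
items 7–10 a second, items 1–6 a third.  Against the generating matrix
this run's correct estimate rate (CER, support agreement minimized over
column permutations and signs) is 0.956: 43 of 45 support entries
match, item 6 having been attached to the wrong trait.

The same pipeline is scriptable from the shell:

```sh
prenetmirt simulate -N 500 --seed 0 -o responses.csv
prenetmirt path responses.csv -K 3 --penalty prenet --seed 0 -o out/
prenetmirt experiment --method lasso -N 100 --replicates 10 -o exp/
```

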
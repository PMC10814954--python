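"""Polya-Gamma augmentation and Gibbs sampling of latent traits.

A PG(b, c) random variable is the weighted infinite sum of gammas

    X ~ sum_{k>=1} G(b, 1) / (2 pi^2 (k - 1/2)^2 + c^2 / 2),

and the augmentation identity

    exp(psi)^a / (1 + exp(psi)) = 2^{-1} exp(kappa psi)
        * E_w[ exp(-w psi^2 / 2) ],   w ~ PG(1, 0),  kappa = a - 1/2,

turns the logistic item-response likelihood into a conditionally
Gaussian one: given auxiliaries w_ij ~ PG(1, a_j^T theta_i + b_j), the
latent trait posterior is N(mu_i, V_i) with

    V_i = (A^T Omega_i A + I_K)^{-1},
    mu_i = V_i A^T Omega_i z_i,    Omega_i = diag(w_i),
    z_ij = kappa_ij / w_ij - b_j,  kappa_ij = y_ij - 1/2.

Two PG(1, c) samplers are provided:

* ``devroye`` (default) — an exact alternating-series rejection sampler
  for the Jacobi-type density, vectorized over the whole N×J array of
  auxiliaries.  PG(1, c) = J*(1, |c|/2) / 4.
* ``series`` — direct truncation of the defining gamma sum (with the
  expected value of the dropped tail added back), slower but transparent;
  it serves as an independent cross-check of the Devroye backend.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr

from .model_core import ModelParams, ResponseMatrix

__all__ = [
    "sample_pg",
    "sample_pg_series",
    "pg_mean",
    "sample_w",
    "posterior_normal_params",
    "sample_theta",
    "gibbs_sweep",
]

# Devroye's crossover point between the small-x (inverse-Gaussian-like)
# and large-x (exponential) pieces of the Jacobi density.
_TRUNC = 0.64
_MAX_SERIES_TERMS = 200


def pg_mean(c):
    """E[PG(1, c)] = tanh(c/2) / (2c), with the limit 1/4 at c = 0."""
    c = np.asarray(c, dtype=float)
    out = np.where(c == 0.0, 0.25, np.tanh(c / 2.0) / np.where(c == 0.0, 1.0, 2.0 * c))
    return float(out) if out.ndim == 0 else out


def sample_pg(c, rng: np.random.Generator, method: str = "devroye"):
    """Draw PG(1, c) variates elementwise for an array (or scalar) of tilts c.

    The distribution depends on c only through c^2, hence is symmetric
    in the sign of c.
    """
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("PG tilt c must be finite")
    if method == "devroye":
        z = np.abs(c) / 2.0
        draws = 0.25 * _sample_jstar(np.ravel(z), rng)
        draws = draws.reshape(c.shape)
    elif method == "series":
        draws = sample_pg_series(c, rng)
    else:
        raise ValueError(f"unknown PG sampling method {method!r}")
    return float(draws) if draws.ndim == 0 else draws


def sample_pg_series(c, rng: np.random.Generator, n_terms: int = _MAX_SERIES_TERMS):
    """PG(1, c) by truncating the defining sum of exponentials.

    The first ``n_terms`` terms are sampled exactly; the dropped tail is
    replaced by its expectation (an integral of the term weights), which
    keeps the mean exact to O(n^-3) variance error.
    """
    c = np.asarray(c, dtype=float)
    shape = c.shape
    k = np.arange(1, n_terms + 1, dtype=float)
    denom = 2.0 * np.pi ** 2 * (k - 0.5) ** 2 + (c[..., None] ** 2) / 2.0
    g = rng.standard_exponential(size=shape + (n_terms,))
    x = (g / denom).sum(axis=-1)
    x = x + _series_tail_mean(c, n_terms)
    return float(x) if x.ndim == 0 else x


def _series_tail_mean(c, n_terms: int):
    # sum_{k>n} 1/(2 pi^2 (k-1/2)^2 + c^2/2) ~= integral_{u=n}^inf du/(2 pi^2 u^2 + c^2/2)
    c = np.abs(np.asarray(c, dtype=float))
    small = c < 1e-8
    c_safe = np.where(small, 1.0, c)
    tail = (np.pi / 2.0 - np.arctan(2.0 * np.pi * n_terms / c_safe)) / (np.pi * c_safe)
    tail_zero = 1.0 / (2.0 * np.pi ** 2 * n_terms)
    return np.where(small, tail_zero, tail)


# ---------------------------------------------------------------------------
# Devroye sampler for J*(1, z): alternating-series rejection.
# ---------------------------------------------------------------------------

def _jstar_coef(x: np.ndarray, n) -> np.ndarray:
    """Coefficient a_n(x) of the alternating-series bound for the Jacobi density."""
    half = n + 0.5
    small = x <= _TRUNC
    x_safe = np.where(x > 0, x, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        a_small = np.pi * half * (2.0 / (np.pi * x_safe)) ** 1.5 * np.exp(
            -2.0 * half ** 2 / x_safe
        )
        a_large = np.pi * half * np.exp(-(half ** 2) * np.pi ** 2 * x_safe / 2.0)
    return np.where(small, a_small, a_large)


def _pigauss(t: float, z: np.ndarray) -> np.ndarray:
    """P(X <= t) for X ~ inverse-Gaussian(mean 1/z, shape 1), z >= 0.

    Written in terms of z so that z = 0 (infinite mean) is the
    continuous limit; the exp(2z) factor is fused with the normal CDF in
    log space to stay finite for large z.
    """
    rt = np.sqrt(t)
    return ndtr((t * z - 1.0) / rt) + np.exp(2.0 * z + log_ndtr(-(t * z + 1.0) / rt))


def _sample_trunc_invgauss(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-Gaussian(1/z, 1) conditioned on (0, TRUNC], elementwise."""
    t = _TRUNC
    out = np.empty_like(z)
    todo = np.arange(z.size)
    z_flat = z
    while todo.size:
        zz = z_flat[todo]
        big_mean = t * zz < 1.0  # mean 1/z above the truncation point (incl. z=0)
        x = np.empty(todo.size)
        u_acc = rng.uniform(size=todo.size)
        ok = np.zeros(todo.size, dtype=bool)

        if np.any(big_mean):
            # Devroye: propose X = t/(1+tE)^2 from the z=0 truncated law,
            # accept with the Gaussian tilt exp(-z^2 X / 2).
            n_b = int(big_mean.sum())
            e1 = rng.standard_exponential(n_b)
            e2 = rng.standard_exponential(n_b)
            xb = t / (1.0 + t * e1) ** 2
            good = (e1 * e1 <= 2.0 * e2 / t) & (
                u_acc[big_mean] <= np.exp(-0.5 * zz[big_mean] ** 2 * xb)
            )
            x[big_mean] = xb
            ok[big_mean] = good

        small_mean = ~big_mean
        if np.any(small_mean):
            zs = zz[small_mean]
            mu = 1.0 / zs
            y = rng.standard_normal(int(small_mean.sum())) ** 2
            muy = mu * y
            xs = mu + 0.5 * mu * muy - 0.5 * mu * np.sqrt(4.0 * muy + muy * muy)
            flip = u_acc[small_mean] > mu / (mu + xs)
            xs = np.where(flip, mu * mu / xs, xs)
            x[small_mean] = xs
            ok[small_mean] = xs <= t

        done = todo[ok]
        out[done] = x[ok]
        todo = todo[~ok]
    return out


def _sample_jstar(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exact draws from the tilted Jacobi law J*(1, z), vectorized; z >= 0."""
    t = _TRUNC
    z = np.asarray(z, dtype=float)
    out = np.empty(z.shape)
    todo = np.arange(z.size)
    z_flat = z.ravel()
    while todo.size:
        zz = z_flat[todo]
        fz = np.pi ** 2 / 8.0 + zz ** 2 / 2.0
        p = (np.pi / (2.0 * fz)) * np.exp(-fz * t)
        q = 2.0 * np.exp(-zz) * _pigauss(t, zz)
        take_exp = rng.uniform(size=todo.size) < p / (p + q)

        x = np.empty(todo.size)
        if np.any(take_exp):
            x[take_exp] = t + rng.standard_exponential(int(take_exp.sum())) / fz[take_exp]
        if np.any(~take_exp):
            x[~take_exp] = _sample_trunc_invgauss(zz[~take_exp], rng)

        # Alternating-series accept/reject against the exact density.
        s = _jstar_coef(x, 0)
        y = rng.uniform(size=todo.size) * s
        accept = np.zeros(todo.size, dtype=bool)
        undecided = np.ones(todo.size, dtype=bool)
        n = 0
        while np.any(undecided) and n < 1000:
            n += 1
            coef = _jstar_coef(x, n)
            if n % 2 == 1:
                s = np.where(undecided, s - coef, s)
                newly = undecided & (y <= s)
                accept |= newly
            else:
                s = np.where(undecided, s + coef, s)
                newly = undecided & (y > s)
            undecided &= ~newly
        done = todo[accept]
        out.ravel()[done] = x[accept]
        todo = todo[~accept]
    return out


# ---------------------------------------------------------------------------
# Gibbs conditionals.
# ---------------------------------------------------------------------------

def sample_w(
    Y: ResponseMatrix,
    params: ModelParams,
    Theta: np.ndarray,
    rng: np.random.Generator,
    method: str = "devroye",
) -> np.ndarray:
    """Draw the N×J auxiliary matrix, w_ij ~ PG(1, a_j^T theta_i + b_j).

    The conditional of w given theta does not involve the observed
    responses; Y only fixes the shape contract.
    """
    Theta = np.asarray(Theta, dtype=float)
    if Theta.shape != (Y.n_subjects, params.n_factors):
        raise ValueError(
            f"Theta shape {Theta.shape} does not match "
            f"(N={Y.n_subjects}, K={params.n_factors})"
        )
    psi = Theta @ params.A.T + params.b
    return sample_pg(psi, rng, method=method)


def posterior_normal_params(
    y_i: np.ndarray, params: ModelParams, w_i: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior Gaussian (V, mu) of one subject's latent trait.

    V = (A^T Omega A + I_K)^{-1} and mu = V A^T Omega z with
    Omega = diag(w_i) and z_j = (y_j - 1/2)/w_j - b_j.  The product
    A^T Omega z is evaluated as A^T (kappa - Omega b), which is the same
    quantity with the 1/w_j cancellation done analytically so that tiny
    auxiliaries cannot amplify roundoff.
    """
    y_i = np.asarray(y_i, dtype=float)
    w_i = np.asarray(w_i, dtype=float)
    if np.any(w_i <= 0):
        raise ValueError("PG auxiliaries must be positive")
    A, b = params.A, params.b
    if y_i.shape != (A.shape[0],) or w_i.shape != (A.shape[0],):
        raise ValueError("y_i and w_i must be length-J vectors")
    kappa = y_i - 0.5
    prec = A.T @ (w_i[:, None] * A) + np.eye(params.n_factors)
    V = np.linalg.inv(prec)
    V = 0.5 * (V + V.T)
    mu = V @ (A.T @ (kappa - w_i * b))
    return V, mu


def sample_theta(
    Y: ResponseMatrix,
    params: ModelParams,
    W: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw all N latent-trait vectors from their Gaussian full conditional.

    Row i is N(mu_i, V_i) with the precision I_K + A^T Omega_i A; the
    draws use batched Cholesky factors of the precisions, so the cost is
    O(N K^3) with K small.
    """
    A, b = params.A, params.b
    N, J = Y.shape
    K = params.n_factors
    W = np.asarray(W, dtype=float)
    if W.shape != (N, J):
        raise ValueError(f"W shape {W.shape} does not match responses {Y.shape}")
    if np.any(W <= 0):
        raise ValueError("PG auxiliaries must be positive")
    kappa = Y.values - 0.5
    # precision_i = I + sum_j w_ij a_j a_j^T, batched over i
    prec = np.eye(K) + np.einsum("ij,jk,jl->ikl", W, A, A, optimize=True)
    rhs = (kappa - W * b) @ A  # (N, K) = A^T Omega_i z_i stacked
    L = np.linalg.cholesky(prec)
    mu = np.linalg.solve(prec, rhs[..., None])[..., 0]
    eps = rng.standard_normal((N, K))
    # prec = L L^T  =>  cov = L^{-T} L^{-1}; theta = mu + L^{-T} eps
    theta = mu + np.linalg.solve(np.transpose(L, (0, 2, 1)), eps[..., None])[..., 0]
    return theta


def gibbs_sweep(
    Y: ResponseMatrix,
    params: ModelParams,
    Theta: np.ndarray,
    rng: np.random.Generator,
    method: str = "devroye",
) -> tuple[np.ndarray, np.ndarray]:
    """One full Gibbs sweep (W then Theta); returns the new (W, Theta)."""
    W = sample_w(Y, params, Theta, rng, method=method)
    Theta = sample_theta(Y, params, W, rng)
    return W, Theta
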
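"""Two-parameter multidimensional IRT model: containers and likelihoods.

The model: subject i with latent trait theta_i ~ N(0, I_K) answers item
j correctly with probability

    p(y_ij = 1 | theta_i, a_j, b_j) = sigma(a_j^T theta_i + b_j),

sigma the standard logistic function, a_j the item's K-vector of
discrimination loadings and b_j its intercept (easiness).  Responses are
conditionally independent given theta (local independence).  The latent
covariance is fixed at the identity; correlated traits are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, roots_hermitenorm
from scipy.special import logsumexp

__all__ = [
    "ResponseMatrix",
    "ModelParams",
    "QuadratureSpec",
    "irf_prob",
    "log_bernoulli_matrix",
    "complete_loglik",
    "marginal_loglik",
]

_LOG_2PI = np.log(2.0 * np.pi)


class ResponseMatrix:
    """N×J matrix of binary item responses with optional row/column labels.

    Entries must be exactly 0 or 1; missing responses are not supported.
    """

    def __init__(self, values, item_ids=None, subject_ids=None):
        arr = np.asarray(values)
        if arr.ndim != 2:
            raise ValueError("responses must form a 2-D matrix (subjects × items)")
        if arr.size == 0:
            raise ValueError("response matrix must be non-empty")
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary response {arr[i, j]!r} at subject row {i}, item column {j}"
            )
        self._values = arr.astype(np.int8)
        n, j = self._values.shape
        self.item_ids = (
            list(item_ids) if item_ids is not None else [f"item{t + 1}" for t in range(j)]
        )
        self.subject_ids = (
            list(subject_ids) if subject_ids is not None else list(range(1, n + 1))
        )
        if len(self.item_ids) != j:
            raise ValueError("item_ids length does not match number of columns")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match number of rows")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResponseMatrix":
        return cls(df.to_numpy(), item_ids=df.columns.tolist(), subject_ids=df.index.tolist())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._values.copy(), index=self.subject_ids, columns=self.item_ids)

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape

    @property
    def n_subjects(self) -> int:
        return self._values.shape[0]

    @property
    def n_items(self) -> int:
        return self._values.shape[1]

    def __repr__(self) -> str:
        n, j = self.shape
        return f"ResponseMatrix({n} subjects × {j} items)"


@dataclass(frozen=True)
class ModelParams:
    """Item parameters: loading matrix A (J×K) and intercepts b (J,)."""

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if A.ndim != 2:
            raise ValueError("A must be a J×K matrix")
        if b.shape != (A.shape[0],):
            raise ValueError(f"b must be a length-{A.shape[0]} vector, got shape {b.shape}")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
            raise ValueError("model parameters must be finite")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)

    @property
    def n_items(self) -> int:
        return self.A.shape[0]

    @property
    def n_factors(self) -> int:
        return self.A.shape[1]

    @property
    def n_nonzero(self) -> int:
        """Number of exactly nonzero loadings (the BIC's p0)."""
        return int(np.count_nonzero(self.A))


@dataclass(frozen=True)
class QuadratureSpec:
    """How to approximate the integral over the latent trait.

    ``gauss-hermite`` builds a tensor-product rule with ``n_nodes``
    probabilists' Hermite nodes per dimension (deterministic; only
    sensible for K <= 4).  ``mc`` averages over ``n_samples`` standard
    normal draws with a fixed ``seed``.
    """

    method: str = "gauss-hermite"
    n_nodes: int = 11
    n_samples: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("gauss-hermite", "mc"):
            raise ValueError("quadrature method must be 'gauss-hermite' or 'mc'")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")


def irf_prob(theta, a, b):
    """Item response probability sigma(a^T theta + b).

    Stable for linear predictors anywhere in the double range; ``theta``
    and ``a`` must have matching length K.
    """
    theta = np.asarray(theta, dtype=float)
    a = np.asarray(a, dtype=float)
    if theta.shape != a.shape:
        raise ValueError(f"theta shape {theta.shape} != a shape {a.shape}")
    return float(expit(theta @ a + b))


def log_bernoulli_matrix(Y_values: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Elementwise log p(y | eta) = y*eta - log(1 + e^eta) for a 0/1 array."""
    # y*eta - log1pexp(eta), with log1pexp via logaddexp for stability
    return Y_values * eta - np.logaddexp(0.0, eta)


def complete_loglik(Y: ResponseMatrix, Theta: np.ndarray, params: ModelParams) -> float:
    """Log of the complete-data likelihood, prior times response terms:

    sum_i [ log phi(theta_i) + sum_j log p(y_ij | theta_i, a_j, b_j) ].
    """
    Theta = np.asarray(Theta, dtype=float)
    N, J = Y.shape
    K = params.n_factors
    if Theta.shape != (N, K):
        raise ValueError(f"Theta shape {Theta.shape} does not match (N={N}, K={K})")
    eta = Theta @ params.A.T + params.b
    ll_resp = log_bernoulli_matrix(Y.values, eta).sum()
    ll_prior = -0.5 * N * K * _LOG_2PI - 0.5 * float((Theta * Theta).sum())
    return float(ll_resp + ll_prior)


def _gh_grid(K: int, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product probabilists' Gauss-Hermite grid and log-weights."""
    x, w = roots_hermitenorm(n_nodes)
    logw = np.log(w) - 0.5 * _LOG_2PI  # normalize: weights of N(0,1) expectation
    grids = np.meshgrid(*([x] * K), indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)
    logws = np.zeros(nodes.shape[0])
    lw = np.meshgrid(*([logw] * K), indexing="ij")
    for g in lw:
        logws += g.ravel()
    return nodes, logws


def marginal_loglik(
    Y: ResponseMatrix, params: ModelParams, quad: QuadratureSpec | None = None
) -> float:
    """Marginal log-likelihood sum_i log ∫ phi(theta) prod_j p(y_ij|theta) dtheta.

    Computed entirely in the log domain; with Gauss-Hermite quadrature
    the result is deterministic given the node count.
    """
    if quad is None:
        quad = QuadratureSpec()
    K = params.n_factors
    if quad.method == "gauss-hermite":
        if K > 4:
            raise ValueError(
                "tensor Gauss-Hermite quadrature is limited to K <= 4; "
                "use QuadratureSpec(method='mc') for higher dimensions"
            )
        nodes, logws = _gh_grid(K, quad.n_nodes)
    else:
        rng = np.random.default_rng(quad.seed)
        nodes = rng.standard_normal((quad.n_samples, K))
        logws = np.full(quad.n_samples, -np.log(quad.n_samples))

    eta = nodes @ params.A.T + params.b  # (G, J)
    logp1 = -np.logaddexp(0.0, -eta)  # log sigma(eta)
    logp0 = -np.logaddexp(0.0, eta)  # log sigma(-eta)
    # subject i, node g: sum_j [ y_ij logp1 + (1-y_ij) logp0 ]
    Yv = Y.values.astype(float)
    per_subject_node = Yv @ (logp1 - logp0).T + logp0.sum(axis=1)  # (N, G)
    return float(logsumexp(per_subject_node + logws, axis=1).sum())
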
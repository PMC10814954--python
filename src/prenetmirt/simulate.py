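"""Synthetic response generation from a known 2-PL MIRT model.

The benchmark truth is a 15-item, 3-trait loading matrix in perfect
simple structure: items 1-5 load on trait 1, items 6-10 on trait 2 and
items 11-15 on trait 3, with loadings (0.4, 0.7, 1.0, 1.3, 1.6) within
each block and all intercepts zero.  Every row has exactly one nonzero
entry, so the prenet penalty of the truth is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelParams, ResponseMatrix

__all__ = ["TrueModel", "benchmark_loading_matrix", "benchmark_true_model", "simulate_responses"]

_BLOCK = np.array([0.4, 0.7, 1.0, 1.3, 1.6])


def benchmark_loading_matrix() -> np.ndarray:
    """The 15×3 block simple-structure loading matrix of the benchmark."""
    A = np.zeros((15, 3))
    for k in range(3):
        A[5 * k : 5 * (k + 1), k] = _BLOCK
    return A


@dataclass(frozen=True)
class TrueModel:
    """A generating model: loadings, intercepts and a sample size."""

    A: np.ndarray
    b: np.ndarray
    n_subjects: int

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if b.shape != (A.shape[0],):
            raise ValueError("b must have one entry per row of A")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)

    @property
    def params(self) -> ModelParams:
        return ModelParams(A=self.A, b=self.b)


def benchmark_true_model(n_subjects: int) -> TrueModel:
    """The benchmark truth (J=15, K=3, b=0) at a given sample size."""
    A = benchmark_loading_matrix()
    return TrueModel(A=A, b=np.zeros(A.shape[0]), n_subjects=n_subjects)


def simulate_responses(
    model: TrueModel,
    rng: np.random.Generator | int | None = None,
    return_theta: bool = False,
):
    """Draw binary responses: theta_i ~ N(0, I_K), y_ij ~ Bern(sigma(a_j^T theta_i + b_j)).

    Returns a :class:`ResponseMatrix` (and the latent traits if
    ``return_theta``); fully determined by the generator state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    A, b, N = model.A, model.b, model.n_subjects
    K = A.shape[1]
    Theta = rng.standard_normal((N, K))
    eta = Theta @ A.T + b
    prob = 1.0 / (1.0 + np.exp(-eta))
    Y = (rng.uniform(size=eta.shape) < prob).astype(np.int8)
    resp = ResponseMatrix(Y)
    if return_theta:
        return resp, Theta
    return resp
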
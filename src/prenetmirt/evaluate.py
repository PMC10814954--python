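"""Alignment-aware evaluation of estimated loading matrices.

A loading matrix is identified only up to column permutation and column
sign flips, so both metrics search all 2^K * K! alignments of the
estimate and keep the most favourable one:

* MSE  = min over alignments of ||A - A_hat||_F^2 / (J K)
* CER  = 1 - min over alignments of #{(j,k): I(a_jk != 0) != I(a_hat_jk != 0)} / (J K)

CER measures structure (support) recovery only; MSE measures the
loadings themselves.  The two minimizations are carried out
independently — the permutation best for the values need not be best
for the support.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selection import default_rho_grid, fit_path
from .simulate import TrueModel, benchmark_true_model, simulate_responses
from .stem import StemConfig

__all__ = ["align_columns", "mse", "cer", "EvalReport", "run_experiment"]

_MAX_K_EXHAUSTIVE = 8


def _alignments(K: int):
    """Yield (permutation, signs) over all 2^K * K! column alignments."""
    if K > _MAX_K_EXHAUSTIVE:
        raise ValueError(
            f"exhaustive alignment search over 2^K K! combinations is limited to "
            f"K <= {_MAX_K_EXHAUSTIVE}; got K={K}"
        )
    for perm in itertools.permutations(range(K)):
        for signs in itertools.product((1.0, -1.0), repeat=K):
            yield np.array(perm), np.array(signs)


def align_columns(A_true: np.ndarray, A_hat: np.ndarray):
    """Best sign/permutation of A_hat's columns for squared error vs A_true.

    Returns (A_aligned, permutation, signs) with
    A_aligned[:, k] = signs[k] * A_hat[:, permutation[k]].
    """
    A_true = np.asarray(A_true, dtype=float)
    A_hat = np.asarray(A_hat, dtype=float)
    if A_true.shape != A_hat.shape:
        raise ValueError(f"shape mismatch {A_true.shape} vs {A_hat.shape}")
    K = A_true.shape[1]
    best = (np.inf, None, None)
    for perm, signs in _alignments(K):
        cand = A_hat[:, perm] * signs
        err = float(((A_true - cand) ** 2).sum())
        if err < best[0]:
            best = (err, perm, signs)
    _, perm, signs = best
    return A_hat[:, perm] * signs, perm, signs


def mse(A_true: np.ndarray, A_hat: np.ndarray) -> float:
    """Alignment-minimized mean squared error ||A - A_hat||_F^2 / (J K)."""
    A_true = np.asarray(A_true, dtype=float)
    aligned, _, _ = align_columns(A_true, A_hat)
    return float(((A_true - aligned) ** 2).sum() / A_true.size)


def cer(A_true: np.ndarray, A_hat: np.ndarray) -> float:
    """Correct estimate rate of the support, in [0, 1].

    1 - (minimum support mismatch over alignments) / (J K).  Sign flips
    cannot change a support, but the minimizing permutation is searched
    independently of the MSE one.
    """
    S_true = (np.asarray(A_true) != 0).astype(int)
    S_hat = (np.asarray(A_hat) != 0).astype(int)
    if S_true.shape != S_hat.shape:
        raise ValueError(f"shape mismatch {S_true.shape} vs {S_hat.shape}")
    K = S_true.shape[1]
    best = np.inf
    for perm in itertools.permutations(range(K)):
        mism = int(np.abs(S_true - S_hat[:, perm]).sum())
        best = min(best, mism)
    if K > _MAX_K_EXHAUSTIVE:
        raise ValueError(f"alignment search limited to K <= {_MAX_K_EXHAUSTIVE}")
    return float(1.0 - best / S_true.size)


@dataclass
class EvalReport:
    """Replicate-level results of a Monte-Carlo recovery experiment."""

    method: str
    n_subjects: int
    results: pd.DataFrame  # columns: replicate, seed, rho_selected, p0, mse, cer

    @property
    def mean_mse(self) -> float:
        return float(self.results["mse"].mean())

    @property
    def mean_cer(self) -> float:
        return float(self.results["cer"].mean())

    @property
    def frac_all_zero(self) -> float:
        """Fraction of replicates whose selected loading matrix is exactly O."""
        return float((self.results["p0"] == 0).mean())

    @property
    def frac_perfect_structure(self) -> float:
        """Fraction of replicates with CER exactly 1."""
        return float((self.results["cer"] == 1.0).mean())

    def summary(self) -> str:
        lines = [
            f"Recovery experiment: method={self.method}, N={self.n_subjects}, "
            f"replicates={len(self.results)}",
            f"  mean MSE          : {self.mean_mse:.4f}",
            f"  mean CER          : {self.mean_cer:.4f}",
            f"  CER = 1 fraction  : {self.frac_perfect_structure:.2f}",
            f"  A = O fraction    : {self.frac_all_zero:.2f}",
        ]
        return "\n".join(lines)

    def plot_box(self, metric: str = "cer", ax=None):
        """Boxplot of a per-replicate metric ('mse' or 'cer')."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(3, 4))
        ax.boxplot(self.results[metric].to_numpy(), tick_labels=[self.method])
        ax.set_ylabel(metric.upper())
        ax.set_title(f"N = {self.n_subjects}")
        return ax


def run_experiment(
    method: str,
    n_subjects: int,
    replicates: int,
    base_seed: int,
    cfg: StemConfig | None = None,
    rho_grid=None,
    gamma: float = 0.1,
    true_model: TrueModel | None = None,
    n_factors: int | None = None,
) -> EvalReport:
    """Monte-Carlo recovery experiment against a known generating model.

    For replicate s: simulate responses with seed ``base_seed + s``, fit
    the BIC path (penalty ``method``: "prenet" or "lasso"/"l1"), and
    score the selected estimate by alignment-minimized MSE and CER.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    kind = {"lasso": "l1"}.get(method, method)
    if kind not in ("prenet", "l1"):
        raise ValueError(f"method must be 'prenet' or 'lasso'/'l1', got {method!r}")
    if true_model is None:
        true_model = benchmark_true_model(n_subjects)
    else:
        true_model = TrueModel(A=true_model.A, b=true_model.b, n_subjects=n_subjects)
    if rho_grid is None:
        rho_grid = default_rho_grid(kind)
    if cfg is None:
        cfg = StemConfig()
    K = n_factors if n_factors is not None else true_model.A.shape[1]

    rows = []
    for s in range(replicates):
        seed = base_seed + s
        Y = simulate_responses(true_model, rng=seed)
        cfg_s = StemConfig(**{**cfg.__dict__, "seed": seed})
        path = fit_path(Y, K, kind, gamma, rho_grid, cfg_s)
        sel = path.selected
        rows.append(
            {
                "replicate": s,
                "seed": seed,
                "rho_selected": sel.rho,
                "p0": sel.p0,
                "mse": mse(true_model.A, sel.params.A),
                "cer": cer(true_model.A, sel.params.A),
            }
        )
    return EvalReport(method=method, n_subjects=n_subjects, results=pd.DataFrame(rows))
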
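"""BIC model selection along a regularization path with warm starts.

BIC = -2 * l(A, b | Y) + p0 * log N, with l the quadrature-approximated
marginal log-likelihood and p0 the number of exactly nonzero loadings.
The path is fitted from the largest rho downward; each fit starts from
the finalized parameters of the previous one, and the rho with the
smallest BIC is selected (ties go to the larger rho, i.e. the sparser
model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ModelParams, QuadratureSpec, ResponseMatrix, marginal_loglik
from .penalties import PenaltySpec
from .stem import StemConfig, StemTrajectory, run_stem

__all__ = [
    "PathRecord",
    "PathResult",
    "compute_bic",
    "default_rho_grid",
    "fit_path",
]


def compute_bic(
    Y: ResponseMatrix, params: ModelParams, quad: QuadratureSpec | None = None
) -> tuple[float, int, float]:
    """Return (bic, p0, loglik) for finalized parameters.

    p0 counts exact nonzeros of A; finalization produces bit-exact zeros
    so no epsilon threshold is applied.
    """
    loglik = marginal_loglik(Y, params, quad)
    p0 = params.n_nonzero
    bic = -2.0 * loglik + p0 * np.log(Y.n_subjects)
    return float(bic), p0, float(loglik)


def default_rho_grid(penalty_kind: str, n: int = 21, factor: float = 0.8) -> np.ndarray:
    """Geometric rho grid: 3 * 0.8^t for prenet, 0.1 * 0.8^t for l1 (t = 0..n-1)."""
    start = {"prenet": 3.0, "l1": 0.1}.get(penalty_kind)
    if start is None:
        raise ValueError(f"no default grid for penalty kind {penalty_kind!r}")
    return start * factor ** np.arange(n)


@dataclass
class PathRecord:
    rho: float
    params: ModelParams
    bic: float
    p0: int
    loglik: float
    trajectory: StemTrajectory | None = None


@dataclass
class PathResult:
    """Fitted path records (in decreasing-rho fitting order) and the pick."""

    records: list[PathRecord]
    selected_index: int
    penalty_kind: str
    gamma: float

    @property
    def selected(self) -> PathRecord:
        return self.records[self.selected_index]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rho": r.rho,
                "loglik": r.loglik,
                "p0": r.p0,
                "bic": r.bic,
                "selected": i == self.selected_index,
            }
            for i, r in enumerate(self.records)
        ]
        return pd.DataFrame(rows)


def fit_path(
    Y: ResponseMatrix,
    K: int,
    penalty_kind: str,
    gamma: float,
    rho_grid,
    cfg: StemConfig | None = None,
    quad: QuadratureSpec | None = None,
    keep_trajectories: bool = False,
) -> PathResult:
    """Fit the stochastic EM at every rho, warm-starting down the grid.

    The first (largest-rho) fit uses the default random initialization;
    every later fit is initialized at the finalized parameters of the
    preceding rho.  Each fit draws its randomness from an independent
    stream spawned from ``cfg.seed`` so the whole path is reproducible.
    Single-rho failures are recorded and skipped with a warning; if all
    fits fail the error is raised.
    """
    if cfg is None:
        cfg = StemConfig()
    rho_grid = np.sort(np.asarray(rho_grid, dtype=float))[::-1]
    if rho_grid.size == 0:
        raise ValueError("rho_grid must be non-empty")
    streams = np.random.SeedSequence(cfg.seed).spawn(rho_grid.size)
    records: list[PathRecord] = []
    params_prev: ModelParams | None = None
    last_error: Exception | None = None
    for i, rho in enumerate(rho_grid):
        penalty = PenaltySpec(kind=penalty_kind, rho=float(rho), gamma=gamma)
        rng = np.random.default_rng(streams[i])
        try:
            traj, params = run_stem(
                Y, K, penalty, cfg,
                params_init=params_prev,
                rng=rng,
                warm=params_prev is not None,
            )
        except Exception as err:  # pragma: no cover - defensive path
            warnings.warn(f"fit at rho={rho:.5g} failed: {err}", RuntimeWarning, stacklevel=2)
            last_error = err
            continue
        bic, p0, loglik = compute_bic(Y, params, quad)
        records.append(
            PathRecord(
                rho=float(rho), params=params, bic=bic, p0=p0, loglik=loglik,
                trajectory=traj if keep_trajectories else None,
            )
        )
        params_prev = params
    if not records:
        raise RuntimeError("every fit along the regularization path failed") from last_error
    # strict '<' while scanning from large to small rho: ties keep the sparser fit
    best = 0
    for i in range(1, len(records)):
        if records[i].bic < records[best].bic:
            best = i
    return PathResult(records=records, selected_index=best, penalty_kind=penalty_kind, gamma=gamma)
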
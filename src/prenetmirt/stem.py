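"""Stochastic EM for penalized marginal-likelihood estimation.

Each iteration alternates one Gibbs sweep through the Polya-Gamma
augmented posterior (the stochastic E-step: a single draw of the
auxiliaries W and the latent traits Theta) with a penalized M-step that
maximizes

    (1/N) sum_i log p(y_i | theta_i, A, b) - rho * P(A)

over (A, b) at the drawn Theta.  Because the chain never settles, the
final estimate is formed from the last ``m`` iterates: entrywise median
for A (so loadings that are zero in most retained iterates come out
exactly zero) and entrywise mean for b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .model_core import ModelParams, ResponseMatrix, log_bernoulli_matrix
from .penalties import PenaltySpec, column_weights, penalized_coordinate_update, penalty_value
from . import polya_gamma as pg

__all__ = [
    "StemConfig",
    "StemTrajectory",
    "penalized_objective",
    "m_step",
    "run_stem",
    "finalize",
]


@dataclass(frozen=True)
class StemConfig:
    """Controls for the stochastic EM run.

    Parameters
    ----------
    n_burnin : int
        Iterations discarded before averaging (the chain's burn-in, T).
    n_average : int
        Iterations retained and summarized into the final estimate (m).
    n_burnin_warm : int or None
        Burn-in used for warm-started fits along a regularization path;
        None reuses ``n_burnin``.  A warm start begins near the target
        region, so a shorter re-burn-in is usually enough.
    inner_max_iter, inner_tol : int, float
        M-step coordinate-descent sweep limit and max-change stopping
        tolerance.
    seed : int or None
        Seed for all randomness of the run.
    theta_init : {"prior", "zeros"}
        Initial latent traits: a standard-normal draw or all zeros.
    init_scale : float
        Standard deviation of the random normal initialization of A.
    pg_method : {"devroye", "series"}
        Backend for the Polya-Gamma draws.
    max_abs_loading, max_abs_intercept : float
        Box bounds on the parameter space.  A drawn Theta can separate
        an item perfectly, sending that item's logistic MLE to infinity
        and feeding back through the trait posterior; bounding |a_jk|
        and |b_j| (as IRT software routinely does) removes the runaway
        while leaving realistic estimates untouched.
    """

    n_burnin: int = 300
    n_average: int = 100
    n_burnin_warm: int | None = None
    inner_max_iter: int = 200
    inner_tol: float = 1e-6
    seed: int | None = None
    theta_init: str = "prior"
    init_scale: float = 0.1
    pg_method: str = "devroye"
    max_abs_loading: float = 6.0
    max_abs_intercept: float = 10.0

    def __post_init__(self):
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be >= 0")
        if self.n_average < 1:
            raise ValueError("n_average must be >= 1")
        if self.theta_init not in ("prior", "zeros"):
            raise ValueError("theta_init must be 'prior' or 'zeros'")


@dataclass
class StemTrajectory:
    """The retained tail of the chain: m snapshots of (A, b), plus a log."""

    A_snapshots: np.ndarray  # (m, J, K)
    b_snapshots: np.ndarray  # (m, J)
    history: list = field(default_factory=list)  # per-iteration (objective, nnz)

    @property
    def n_snapshots(self) -> int:
        return self.A_snapshots.shape[0]


def penalized_objective(
    Y: ResponseMatrix, Theta: np.ndarray, params: ModelParams, penalty: PenaltySpec
) -> float:
    """(1/N) sum_ij log p(y_ij | theta_i, a_j, b_j) - rho P(A)."""
    eta = Theta @ params.A.T + params.b
    ll = log_bernoulli_matrix(Y.values, eta).sum() / Y.n_subjects
    return float(ll - penalty.rho * penalty_value(params.A, penalty))


def _coordinate_sweep(Yv, Theta, A, b, eta, penalty, cfg, newton: bool):
    """One Gauss-Seidel sweep over loading columns then intercepts.

    Items are independent given Theta, so each column update is done for
    all J items at once.  Every step is the exact prox of a local
    quadratic model; with ``newton=True`` the curvature is the actual
    per-coordinate Hessian (fast, may overshoot), otherwise the
    majorization bound p(1-p) <= 1/4 (each step then provably cannot
    decrease the objective; clipping to the box is the constrained
    minimizer of the same convex 1-D subproblem).  Returns the max
    absolute parameter change; A, b, eta are updated in place.
    """
    N, K = Theta.shape
    a_max, b_max = cfg.max_abs_loading, cfg.max_abs_intercept
    Th_sq = Theta * Theta
    delta = 0.0
    for k in range(K):
        p = expit(eta)
        grad = Theta[:, k] @ (Yv - p) / N  # d/d a_jk of the mean loglik, (J,)
        if newton:
            h = np.maximum(Th_sq[:, k] @ (p * (1.0 - p)) / N, 1e-8)  # (J,)
        else:
            h = max(0.25 * Th_sq[:, k].mean(), 1e-12)
        g = h * A[:, k] + grad
        if penalty.kind == "prenet":
            s, q = column_weights(A, k)
            a_new = penalized_coordinate_update(g, h, penalty.rho, penalty.gamma, s, q)
        elif penalty.kind == "l1":
            a_new = penalized_coordinate_update(g, h, penalty.rho, 1.0, 1.0, 0.0)
        else:
            a_new = g / h
        a_new = np.clip(a_new, -a_max, a_max)
        step = a_new - A[:, k]
        delta = max(delta, float(np.abs(step).max()))
        eta += np.outer(Theta[:, k], step)
        A[:, k] = a_new
    p = expit(eta)
    grad_b = (Yv - p).mean(axis=0)
    h_b = np.maximum((p * (1.0 - p)).mean(axis=0), 1e-8) if newton else 0.25
    b_new = np.clip(b + grad_b / h_b, -b_max, b_max)
    step_b = b_new - b
    delta = max(delta, float(np.abs(step_b).max()))
    eta += step_b
    b += step_b
    return delta


def m_step(
    Y: ResponseMatrix,
    Theta: np.ndarray,
    params_init: ModelParams,
    penalty: PenaltySpec,
    cfg: StemConfig | None = None,
) -> ModelParams:
    """Penalized M-step: J independent penalized logistic regressions.

    Maximizes the mean conditional log-likelihood at the drawn Theta
    minus rho P(A); intercepts are never penalized.  Sweeps use
    Newton-curvature prox steps for speed, and any sweep that would
    decrease the objective is rolled back and redone with the majorized
    (provably ascending) curvature — so the objective never decreases
    across inner iterations.
    """
    if cfg is None:
        cfg = StemConfig()
    Theta = np.asarray(Theta, dtype=float)
    Yv = Y.values.astype(float)
    N = Y.n_subjects
    A = params_init.A.copy()
    b = params_init.b.copy()
    eta = Theta @ A.T + b

    def _objective(eta_, A_):
        ll = log_bernoulli_matrix(Yv, eta_).sum() / N
        return ll - penalty.rho * penalty_value(A_, penalty)

    obj = _objective(eta, A)
    converged = False
    for _ in range(cfg.inner_max_iter):
        A_old, b_old, eta_old = A.copy(), b.copy(), eta.copy()
        delta = _coordinate_sweep(Yv, Theta, A, b, eta, penalty, cfg, newton=True)
        new_obj = _objective(eta, A)
        if new_obj < obj - 1e-12:
            # Newton curvature overshot: redo this sweep with the safe bound
            A, b, eta = A_old, b_old, eta_old
            delta = _coordinate_sweep(Yv, Theta, A, b, eta, penalty, cfg, newton=False)
            new_obj = _objective(eta, A)
        obj = new_obj
        if delta < cfg.inner_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"M-step stopped after {cfg.inner_max_iter} sweeps before reaching "
            "inner_tol; returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return ModelParams(A=A, b=b)


def _init_params(Y: ResponseMatrix, K: int, cfg: StemConfig, rng: np.random.Generator):
    A0 = cfg.init_scale * rng.standard_normal((Y.n_items, K))
    b0 = np.zeros(Y.n_items)
    return ModelParams(A=A0, b=b0)


def run_stem(
    Y: ResponseMatrix,
    K: int,
    penalty: PenaltySpec,
    cfg: StemConfig | None = None,
    params_init: ModelParams | None = None,
    rng: np.random.Generator | None = None,
    warm: bool = False,
) -> tuple[StemTrajectory, ModelParams]:
    """Run the stochastic EM chain and return (trajectory, final params).

    Iterates [draw W | Theta, params] -> [draw Theta | W, params] ->
    [penalized M-step] for T + m iterations, retains the last m
    parameter snapshots, and finalizes by median (A) / mean (b).  With
    ``warm=True`` the shorter ``n_burnin_warm`` burn-in is used, meant
    for path fits initialized at a neighbouring solution.
    """
    if cfg is None:
        cfg = StemConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_burnin = cfg.n_burnin
    if warm and cfg.n_burnin_warm is not None:
        n_burnin = cfg.n_burnin_warm
    m = cfg.n_average
    params = params_init if params_init is not None else _init_params(Y, K, cfg, rng)
    if params.A.shape != (Y.n_items, K):
        raise ValueError(
            f"params_init A shape {params.A.shape} does not match (J={Y.n_items}, K={K})"
        )
    if cfg.theta_init == "prior":
        Theta = rng.standard_normal((Y.n_subjects, K))
    else:
        Theta = np.zeros((Y.n_subjects, K))

    A_snap = np.empty((m, Y.n_items, K))
    b_snap = np.empty((m, Y.n_items))
    history = []
    total = n_burnin + m
    for t in range(total):
        W = pg.sample_w(Y, params, Theta, rng, method=cfg.pg_method)
        Theta = pg.sample_theta(Y, params, W, rng)
        params = m_step(Y, Theta, params, penalty, cfg)
        if not (np.all(np.isfinite(params.A)) and np.all(np.isfinite(params.b))):
            raise RuntimeError(f"stochastic EM diverged at iteration {t}: non-finite parameters")
        history.append(
            (t, penalized_objective(Y, Theta, params, penalty), params.n_nonzero)
        )
        if t >= n_burnin:
            A_snap[t - n_burnin] = params.A
            b_snap[t - n_burnin] = params.b
    traj = StemTrajectory(A_snapshots=A_snap, b_snapshots=b_snap, history=history)
    return traj, finalize(traj)


def finalize(traj: StemTrajectory) -> ModelParams:
    """Entrywise median of the retained A iterates, mean of the b iterates.

    When more than half the retained iterates have a loading at exactly
    zero, the two middle order statistics are both zero, so the median
    (average of the middle pair for even m) is exactly zero — soft
    thresholding's bit-exact zeros survive finalization.
    """
    if traj.n_snapshots < 1:
        raise ValueError("trajectory holds no snapshots")
    A_hat = np.median(traj.A_snapshots, axis=0)
    b_hat = traj.b_snapshots.mean(axis=0)
    return ModelParams(A=A_hat, b=b_hat)
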
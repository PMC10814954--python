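"""Model / results front-end for penalized MIRT estimation.

`PenalizedMIRT` is constructed from a binary response matrix and a
latent dimension; ``fit(rho)`` runs the stochastic EM at one penalty
strength and returns a :class:`MIRTResults`, while ``fit_path()`` fits a
whole regularization path with warm starts and BIC selection and
returns a :class:`MIRTPathResults` whose ``selected`` attribute is the
chosen fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .model_core import ModelParams, QuadratureSpec, ResponseMatrix, marginal_loglik
from .penalties import PenaltySpec
from .selection import PathResult, compute_bic, default_rho_grid, fit_path
from .stem import StemConfig, StemTrajectory, run_stem

__all__ = ["PenalizedMIRT", "MIRTResults", "MIRTPathResults"]


class PenalizedMIRT:
    """Two-parameter MIRT model with a structure penalty on the loadings.

    Parameters
    ----------
    responses : ResponseMatrix, DataFrame or 0/1 array (subjects × items)
    n_factors : int
        Latent dimension K.
    penalty : {"prenet", "l1", "none"}
        Penalty applied to the loading matrix ("lasso" is accepted as an
        alias of "l1").
    gamma : float
        Prenet mixing weight in [0, 1]; ignored for l1/none.

    Examples
    --------
    >>> model = PenalizedMIRT(Y, n_factors=3, penalty="prenet", gamma=0.1)
    >>> res = model.fit_path(config=StemConfig(seed=0)).selected_results
    >>> print(res.summary())
    """

    def __init__(self, responses, n_factors: int, penalty: str = "prenet", gamma: float = 0.1):
        if isinstance(responses, ResponseMatrix):
            self.responses = responses
        elif isinstance(responses, pd.DataFrame):
            self.responses = ResponseMatrix.from_dataframe(responses)
        else:
            self.responses = ResponseMatrix(np.asarray(responses))
        if n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        self.n_factors = int(n_factors)
        self.penalty_kind = {"lasso": "l1"}.get(penalty, penalty)
        if self.penalty_kind not in ("prenet", "l1", "none"):
            raise ValueError(f"unknown penalty {penalty!r}")
        self.gamma = float(gamma)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_factors: int, **kwargs) -> "PenalizedMIRT":
        return cls(ResponseMatrix.from_dataframe(df), n_factors, **kwargs)

    def fit(
        self,
        rho: float,
        config: StemConfig | None = None,
        params_init: ModelParams | None = None,
        quad: QuadratureSpec | None = None,
    ) -> "MIRTResults":
        """Stochastic EM fit at a single penalty strength rho."""
        cfg = config if config is not None else StemConfig()
        spec = PenaltySpec(kind=self.penalty_kind, rho=float(rho), gamma=self.gamma)
        traj, params = run_stem(
            self.responses, self.n_factors, spec, cfg, params_init=params_init
        )
        bic, p0, loglik = compute_bic(self.responses, params, quad)
        return MIRTResults(
            model=self, params=params, rho=float(rho), bic=bic, p0=p0,
            loglik=loglik, config=cfg, trajectory=traj,
        )

    def fit_path(
        self,
        rho_grid=None,
        config: StemConfig | None = None,
        quad: QuadratureSpec | None = None,
    ) -> "MIRTPathResults":
        """Warm-started path fit over a rho grid with BIC selection.

        Default grids follow the benchmark design: 3 * 0.8^t for prenet
        and 0.1 * 0.8^t for l1, t = 0..20.
        """
        if self.penalty_kind == "none":
            raise ValueError("a path requires a penalized model ('prenet' or 'l1')")
        if rho_grid is None:
            rho_grid = default_rho_grid(self.penalty_kind)
        cfg = config if config is not None else StemConfig()
        path = fit_path(
            self.responses, self.n_factors, self.penalty_kind, self.gamma,
            rho_grid, cfg, quad=quad,
        )
        return MIRTPathResults(model=self, path=path, config=cfg)

    def loglike(self, params: ModelParams, quad: QuadratureSpec | None = None) -> float:
        """Quadrature-approximated marginal log-likelihood at given parameters."""
        return marginal_loglik(self.responses, params, quad)


class MIRTResults:
    """Finalized estimates from one stochastic EM run, with BIC diagnostics."""

    def __init__(self, model, params, rho, bic, p0, loglik, config, trajectory=None):
        self.model = model
        self.params: ModelParams = params
        self.rho = rho
        self.bic = bic
        self.p0 = p0
        self.loglik = loglik
        self.config: StemConfig = config
        self.trajectory: StemTrajectory | None = trajectory

    @property
    def loadings(self) -> pd.DataFrame:
        cols = [f"trait{k + 1}" for k in range(self.model.n_factors)]
        return pd.DataFrame(self.params.A, index=self.model.responses.item_ids, columns=cols)

    @property
    def intercepts(self) -> pd.Series:
        return pd.Series(self.params.b, index=self.model.responses.item_ids, name="intercept")

    @property
    def item_clusters(self) -> pd.Series:
        """Trait index (1-based) of each item's largest-|loading| column; 0 if the row is all zero."""
        A = self.params.A
        cluster = np.where(np.any(A != 0, axis=1), np.abs(A).argmax(axis=1) + 1, 0)
        return pd.Series(cluster, index=self.model.responses.item_ids, name="cluster")

    def predict_proba(self, theta: np.ndarray) -> np.ndarray:
        """Response probabilities sigma(Theta A^T + b) for given latent traits."""
        theta = np.asarray(theta, dtype=float)
        one_d = theta.ndim == 1
        p = expit(np.atleast_2d(theta) @ self.params.A.T + self.params.b)
        return p[0] if one_d else p

    def summary(self) -> str:
        Y = self.model.responses
        head = [
            "Penalized MIRT (stochastic EM, Polya-Gamma Gibbs)",
            f"  penalty: {self.model.penalty_kind}"
            + (f" (gamma={self.model.gamma})" if self.model.penalty_kind == "prenet" else ""),
            f"  N = {Y.n_subjects} subjects, J = {Y.n_items} items, K = {self.model.n_factors}",
            f"  rho = {self.rho:.6g}   nonzero loadings p0 = {self.p0}",
            f"  marginal loglik = {self.loglik:.3f}   BIC = {self.bic:.3f}",
            "",
        ]
        table = self.loadings.round(3).copy()
        table["intercept"] = self.intercepts.round(3)
        return "\n".join(head) + table.to_string()


class MIRTPathResults:
    """A fitted regularization path; ``selected_results`` is the BIC pick."""

    def __init__(self, model, path: PathResult, config: StemConfig):
        self.model = model
        self.path = path
        self.config = config

    @property
    def frame(self) -> pd.DataFrame:
        return self.path.to_frame()

    @property
    def selected_results(self) -> MIRTResults:
        rec = self.path.selected
        return MIRTResults(
            model=self.model, params=rec.params, rho=rec.rho, bic=rec.bic,
            p0=rec.p0, loglik=rec.loglik, config=self.config, trajectory=rec.trajectory,
        )

    def summary(self) -> str:
        lines = [
            f"Regularization path ({self.path.penalty_kind}, {len(self.path.records)} fits)",
            self.frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            f"selected rho = {self.path.selected.rho:.6g} "
            f"(BIC = {self.path.selected.bic:.3f}, p0 = {self.path.selected.p0})",
        ]
        return "\n".join(lines)

    def plot_bic(self, ax=None):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.frame
        ax.plot(df["rho"], df["bic"], marker="o")
        ax.axvline(self.path.selected.rho, ls="--", color="grey")
        ax.set_xscale("log")
        ax.set_xlabel(r"$\rho$")
        ax.set_ylabel("BIC")
        return ax
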
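"""Row-product (prenet) and L1 penalties on a loading matrix.

The prenet penalty acts on pairs of entries within the same row of the
J×K loading matrix A:

    P(A) = sum_j sum_{k<k'} [ gamma |a_jk||a_jk'| + (1-gamma)/2 a_jk^2 a_jk'^2 ]

It is zero exactly when every row has at most one nonzero entry (a
perfect simple structure), and for gamma in (0, 1] its minimizers under
increasing strength rho have at most one nonzero per row.  The penalty
is non-convex but multi-convex: with all other entries fixed, the
restriction to a single coordinate a_jk is an elastic net

    gamma*s |a_jk| + (1-gamma)/2 * q * a_jk^2 + const,

with s = sum_{k'!=k} |a_jk'| and q = sum_{k'!=k} a_jk'^2, which is what
makes coordinate descent exact per coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PenaltySpec",
    "prenet_value",
    "l1_value",
    "penalty_value",
    "coordinate_weights",
    "column_weights",
    "penalized_coordinate_update",
    "soft_threshold",
]

_KINDS = ("prenet", "l1", "none")


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty configuration: kind, strength rho, and mixing gamma.

    Parameters
    ----------
    kind : {"prenet", "l1", "none"}
    rho : float
        Nonnegative regularization strength.
    gamma : float
        Prenet mixing weight in [0, 1] between the |a||a'| product term
        (gamma) and the squared-product ridge term (1-gamma).  Ignored
        for ``l1`` and ``none``.
    """

    kind: str
    rho: float = 0.0
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"penalty kind must be one of {_KINDS}, got {self.kind!r}")
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")

    def value(self, A: np.ndarray) -> float:
        """Evaluate P(A) for this penalty (without the rho factor)."""
        return penalty_value(A, self)


def prenet_value(A: np.ndarray, gamma: float) -> float:
    """Prenet penalty of a J×K matrix.

    Uses the identities sum_{k<k'} x_k x_k' = ((sum x)^2 - sum x^2)/2
    applied to |a| and a^2 so the cost is O(JK) rather than O(JK^2).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("A must be a 2-D matrix")
    absA = np.abs(A)
    sq = A * A
    s1 = absA.sum(axis=1)
    s2 = sq.sum(axis=1)
    # (A^2)^2, not A**4: keeps the k = k' cancellation bit-exact so a
    # perfect simple structure yields exactly zero
    s4 = (sq * sq).sum(axis=1)
    cross_abs = 0.5 * (s1 * s1 - s2)
    cross_sq = 0.5 * (s2 * s2 - s4)
    return float(gamma * cross_abs.sum() + 0.5 * (1.0 - gamma) * cross_sq.sum())


def l1_value(A: np.ndarray) -> float:
    """Entrywise L1 norm ||A||_1 = sum |a_jk|."""
    return float(np.abs(np.asarray(A, dtype=float)).sum())


def penalty_value(A: np.ndarray, spec: PenaltySpec) -> float:
    """P(A) for the given spec; the objective uses rho * P(A)."""
    if spec.kind == "prenet":
        return prenet_value(A, spec.gamma)
    if spec.kind == "l1":
        return l1_value(A)
    return 0.0


def coordinate_weights(A: np.ndarray, j: int, k: int) -> tuple[float, float]:
    """Elastic-net weights (s, q) of the prenet penalty at coordinate (j, k).

    With the other entries of row j fixed, the prenet penalty as a
    function of a_jk alone is  gamma*s*|a_jk| + (1-gamma)/2 * q * a_jk^2
    plus a constant, where s = sum_{k'!=k} |a_jk'| and
    q = sum_{k'!=k} a_jk'^2.
    """
    A = np.asarray(A, dtype=float)
    row = A[j]
    s = float(np.abs(row).sum() - abs(row[k]))
    q = float((row * row).sum() - row[k] ** 2)
    return s, q


def column_weights(A: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ``coordinate_weights`` for a whole column k: (s_j, q_j) over j."""
    A = np.asarray(A, dtype=float)
    s = np.abs(A).sum(axis=1) - np.abs(A[:, k])
    q = (A * A).sum(axis=1) - A[:, k] ** 2
    return s, q


def soft_threshold(x, t):
    """sign(x) * max(|x| - t, 0), elementwise."""
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def penalized_coordinate_update(g, h, rho: float, gamma: float, s, q):
    """Exact minimizer of the local coordinate problem.

    Minimizes  (h/2) (x - g/h)^2 + rho*gamma*s*|x| + (rho*(1-gamma)*q/2) x^2
    in closed form:  soft(g, rho*gamma*s) / (h + rho*(1-gamma)*q).

    ``g`` is the quadratic model's slope point (h*x0 + gradient of the
    data log-likelihood term), ``h`` its positive curvature.  Accepts
    scalars or arrays broadcasting over (g, s, q); ``h`` may be scalar.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("curvature h must be > 0")
    num = soft_threshold(np.asarray(g, dtype=float), rho * gamma * np.asarray(s, dtype=float))
    den = h + rho * (1.0 - gamma) * np.asarray(q, dtype=float)
    out = num / den
    return float(out) if np.ndim(out) == 0 else out
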
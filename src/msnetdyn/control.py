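"""Network controllability and pinning control.

Average controllability of node k is the trace of the infinite-horizon
controllability Gramian of the continuous linear system dx/dt = A x + B_k u
with single-node input B_k = e_k,

    W_k = int_0^inf exp(A t) B_k B_k' exp(A' t) dt,

which exists only for a Hurwitz A; the raw connectivity matrix is therefore
normalized first as A_s = A/(1 + lambda_max(A)) - I, the convention of the
network-controllability literature.  With the symmetric eigendecomposition
A_s = V diag(mu) V', the trace reduces to

    trace(W_k) = sum_i V_ki^2 / (-2 mu_i),

so one eigendecomposition yields every node's value; a per-node Lyapunov
solve is kept as an alternative code path for cross-checking.

Modal controllability of node i aggregates its eigenvector loadings on the
system's fast modes: phi_i = sum_j (1 - lambda_j^2) v_ij^2, evaluated on
the spectrum scaled into (-1, 1).

Pinning control ranks nodes by the diagonal feedback gain they receive in
the convex program

    minimize    lambda_max(A - K),  K = diag(k), 0 <= k_i <= cs,
    subject to  cs - eps <= sum_i d_i^2 k_i <= cs + eps,

where d_i = p_i^a q_i^b weights node importance (p strength, q betweenness
by default, a = b = -1/2).  The spectral objective is minimized through a
smoothed log-sum-exp surrogate with analytic gradient under SLSQP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from scipy.linalg import solve_continuous_lyapunov
from scipy.optimize import minimize


@dataclass
class ControlProfile:
    ac: np.ndarray
    mc: np.ndarray
    stabilization: dict = field(default_factory=dict)


@dataclass
class PinningSpec:
    """Parameters of the pinning-gain program.

    cs is the control strength (upper bound of every gain and center of the
    importance-weighted budget), epsilon the budget slack, and a, b the
    importance exponents in [-1, 0] (negative: wasting gain on
    high-importance nodes is cheap in budget, so the optimizer must earn
    its spectral improvement).
    """

    cs: float = 2.0
    epsilon: float = 0.2
    a: float = -0.5
    b: float = -0.5
    importance_p: Optional[np.ndarray] = None
    importance_q: Optional[np.ndarray] = None
    top_n: int = 10

    def validate(self) -> None:
        if self.cs <= 0:
            raise ValueError("control strength cs must be positive")
        if not (0 < self.epsilon < self.cs):
            raise ValueError("need 0 < epsilon < cs")
        for name, v in (("a", self.a), ("b", self.b)):
            if not (-1.0 <= v <= 0.0):
                raise ValueError(f"exponent {name} must lie in [-1, 0]")
        if self.top_n < 1:
            raise ValueError("top_n must be at least 1")


@dataclass
class PinningResult:
    gains: np.ndarray
    ranking: np.ndarray          # node indices, descending gain (ties: index)
    pinned_set: np.ndarray       # top_n of the ranking
    achieved_bound: float        # lambda_max(A - K) at the optimum
    tiers: dict = field(default_factory=dict)
    budget_used: float = np.nan
    margin: float = np.nan       # lambda_min(A) - achieved_bound, reported post hoc
    converged: bool = True


def _check_symmetric(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    return A


def stabilize(A: np.ndarray) -> tuple:
    """Hurwitz normalization A_s = A/(1 + lambda_max(A)) - I.

    Returns ``(A_s, record)`` where the record documents the applied
    transform for downstream reporting.
    """
    A = _check_symmetric(A)
    lam_max = float(np.linalg.eigvalsh(A)[-1])
    A_s = A / (1.0 + lam_max) - np.eye(A.shape[0])
    return A_s, {"lambda_max": lam_max, "scale": 1.0 / (1.0 + lam_max), "shift": -1.0}


def average_controllability(
    A: np.ndarray, stabilized: bool = False, method: str = "eig"
) -> np.ndarray:
    """Per-node Gramian trace of the stabilized system.

    ``method="eig"`` uses the closed form over the symmetric
    eigendecomposition; ``method="lyap"`` solves one continuous Lyapunov
    equation per node (slow; retained as an independent route).
    """
    A = _check_symmetric(A)
    A_s = A if stabilized else stabilize(A)[0]
    evals = np.linalg.eigvalsh(A_s)
    if evals[-1] >= 0:
        raise ValueError("system matrix is not Hurwitz after stabilization")
    n = A_s.shape[0]
    if method == "eig":
        evals, V = np.linalg.eigh(A_s)
        return (V**2 / (-2.0 * evals)[None, :]).sum(axis=1)
    if method == "lyap":
        ac = np.empty(n)
        for k in range(n):
            Q = np.zeros((n, n))
            Q[k, k] = -1.0
            W = solve_continuous_lyapunov(A_s, Q)
            ac[k] = np.trace(W)
        return ac
    raise ValueError(f"unknown method {method!r}")


def modal_controllability(A: np.ndarray) -> np.ndarray:
    """phi_i = sum_j (1 - lambda_j^2) v_ij^2 on the spectrum scaled into (-1, 1)."""
    A = _check_symmetric(A)
    evals = np.linalg.eigvalsh(A)
    scale = 1.0 + float(np.max(np.abs(evals))) if evals.size else 1.0
    evals, V = np.linalg.eigh(A / scale)
    return ((1.0 - evals**2)[None, :] * V**2).sum(axis=1)


def control_profile(A: np.ndarray) -> ControlProfile:
    A = _check_symmetric(A)
    A_s, record = stabilize(A)
    return ControlProfile(
        ac=average_controllability(A_s, stabilized=True),
        mc=modal_controllability(A),
        stabilization=record,
    )


def _betweenness(A: np.ndarray) -> np.ndarray:
    """Weighted betweenness on the distance graph d = 1/w, offset by 1/n.

    The offset keeps the importance strictly positive (complete similarity
    graphs leave many nodes with zero betweenness, which negative exponents
    could not absorb).
    """
    n = A.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] > 0:
                G.add_edge(i, j, distance=1.0 / A[i, j])
    bc = nx.betweenness_centrality(G, weight="distance", normalized=True)
    return np.array([bc[i] for i in range(n)]) + 1.0 / n


def _lse_lambda_max(A: np.ndarray, k: np.ndarray, beta: float) -> tuple:
    """Smoothed spectral radius of A - diag(k) and its gradient in k."""
    evals, V = np.linalg.eigh(A - np.diag(k))
    m = evals[-1]
    z = np.exp(beta * (evals - m))
    w = z / z.sum()
    f = m + np.log(z.sum()) / beta
    grad = -(V**2) @ w
    return f, grad


def pinning_gains(A: np.ndarray, spec: Optional[PinningSpec] = None) -> PinningResult:
    """Optimal diagonal feedback gains minimizing lambda_max(A - K).

    Raises ``ValueError`` with the feasible budget interval when the
    importance-weighted budget window cannot be met under the gain bounds.
    """
    A = _check_symmetric(A)
    spec = spec if spec is not None else PinningSpec()
    spec.validate()
    n = A.shape[0]

    p = np.asarray(spec.importance_p, float) if spec.importance_p is not None else A.sum(axis=1)
    q = np.asarray(spec.importance_q, float) if spec.importance_q is not None else _betweenness(A)
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("importance vectors must be strictly positive")
    d = p**spec.a * q**spec.b
    w = d**2

    budget_max = spec.cs * w.sum()
    lo, hi = spec.cs - spec.epsilon, spec.cs + spec.epsilon
    if lo > budget_max:
        raise ValueError(
            f"budget window [{lo:.4g}, {hi:.4g}] infeasible; "
            f"achievable budget interval is [0, {budget_max:.4g}]"
        )

    x0 = np.full(n, min(spec.cs, spec.cs / w.sum()))
    x0 = np.clip(x0, 0.0, spec.cs)
    if not (lo <= w @ x0 <= hi):
        x0 = np.full(n, np.clip(spec.cs / w.sum(), 0.0, spec.cs))

    bounds = [(0.0, spec.cs)] * n
    cons = [
        {"type": "ineq", "fun": lambda k: w @ k - lo, "jac": lambda k: w},
        {"type": "ineq", "fun": lambda k: hi - w @ k, "jac": lambda k: -w},
    ]
    x = x0
    converged = True
    for beta in (100.0, 2000.0):
        res = minimize(
            lambda k: _lse_lambda_max(A, k, beta),
            x,
            jac=True,
            method="SLSQP",
            bounds=bounds,
            constraints=cons,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        x = res.x
        converged = converged and (res.success or res.status == 8)

    gains = np.clip(x, 0.0, spec.cs)
    achieved = float(np.linalg.eigvalsh(A - np.diag(gains))[-1])
    ranking = np.lexsort((np.arange(n), -gains))
    lam_min = float(np.linalg.eigvalsh(A)[0])
    return PinningResult(
        gains=gains,
        ranking=ranking,
        pinned_set=ranking[: min(spec.top_n, n)],
        achieved_bound=achieved,
        tiers=select_pinned(gains),
        budget_used=float(w @ gains),
        margin=lam_min - achieved,
        converged=converged,
    )


def select_pinned(
    gains_or_result, threshold: float = 1.24, upper: float = 1.4
) -> dict:
    """Tier the nodes by gain: first > upper, second in (threshold, upper],
    third otherwise."""
    gains = (
        gains_or_result.gains
        if isinstance(gains_or_result, PinningResult)
        else np.asarray(gains_or_result, dtype=float)
    )
    idx = np.arange(len(gains))
    return {
        "first": idx[gains > upper],
        "second": idx[(gains > threshold) & (gains <= upper)],
        "third": idx[gains <= threshold],
    }
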
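"""Weighted graph topology and Laplacian synchronizability.

Edge weights (PLV in [0, 1]) are similarities; shortest-path lengths use
the reciprocal map d = 1/w.  Reported metrics:

Cp   mean Onnela (geometric-mean triangle) weighted clustering
Lp   characteristic path length: mean finite pairwise distance
Eg   global efficiency: mean inverse distance
Eloc mean over nodes of the global efficiency of the node's
     neighborhood subgraph
Sw   small-worldness (Cp/Cp_rand)/(Lp/Lp_rand) against weight-shuffled
     surrogates (PLV graphs are complete, so topological rewiring is a
     no-op; the null permutes edge weights instead)

The synchronizability index is M = lambda_2 / lambda_max of the strength
Laplacian L = D - A: the closer the algebraic connectivity is to the
spectral radius, the more homogeneously the network supports a
synchronized state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path


@dataclass
class TopologyMetrics:
    cp: float
    lp: float
    eg: float
    eloc: float
    sw: float
    node_clustering: np.ndarray = field(repr=False, default=None)
    node_efficiency: np.ndarray = field(repr=False, default=None)     # nodal mean 1/d
    node_path_length: np.ndarray = field(repr=False, default=None)    # nodal mean finite d
    node_local_efficiency: np.ndarray = field(repr=False, default=None)
    disconnected: bool = False


@dataclass
class SyncIndex:
    lambda2: float
    lambda_max: float
    M: float
    connected: bool = True


def _as_adjacency(net) -> np.ndarray:
    """Symmetric nonnegative weight matrix with zeroed diagonal."""
    A = np.asarray(getattr(net, "matrix", net), dtype=float).copy()
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < -1e-12):
        raise ValueError("adjacency must be nonnegative")
    np.fill_diagonal(A, 0.0)
    return A


def _distances(A: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        D = np.where(A > 0, 1.0 / np.where(A > 0, A, 1.0), np.inf)
    np.fill_diagonal(D, 0.0)
    return shortest_path(D, method="D", directed=False)


def _onnela_clustering(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    wmax = A.max()
    if wmax == 0:
        return np.zeros(n)
    W = np.cbrt(A / wmax)
    num = np.diagonal(W @ W @ W)
    k = (A > 0).sum(axis=1)
    denom = k * (k - 1)
    out = np.zeros(n)
    nz = denom > 0
    out[nz] = num[nz] / denom[nz]
    return out


def _global_efficiency(A: np.ndarray) -> float:
    n = A.shape[0]
    if n < 2:
        return 0.0
    D = _distances(A)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(D[off] > 0, 1.0 / D[off], 0.0)
    return float(np.mean(inv))


def topology(
    net,
    n_surrogates: int = 100,
    seed: Optional[int] = None,
    compute_sw: bool = True,
) -> TopologyMetrics:
    """Weighted topology metrics of one network (PLVNetwork or matrix)."""
    A = _as_adjacency(net)
    n = A.shape[0]
    D = _distances(A)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    disconnected = bool(np.any(~np.isfinite(D[off])))

    lp = float(np.mean(D[finite])) if finite.any() else np.inf
    with np.errstate(divide="ignore"):
        invD = np.where(D > 0, 1.0 / D, 0.0)
    invD[~np.isfinite(D)] = 0.0
    eg = float(np.sum(invD[off]) / max(1, off.sum()))

    node_pl = np.array(
        [np.mean(D[i][finite[i]]) if finite[i].any() else np.inf for i in range(n)]
    )
    node_eff = invD.sum(axis=1) / max(1, n - 1)

    clus = _onnela_clustering(A)
    cp = float(clus.mean())

    node_eloc = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(A[i] > 0)
        if nb.size >= 2:
            node_eloc[i] = _global_efficiency(A[np.ix_(nb, nb)])
    eloc = float(node_eloc.mean())

    sw = np.nan
    if compute_sw and n >= 3:
        rng = np.random.default_rng(seed)
        cps, lps = [], []
        iu = np.triu_indices(n, 1)
        w = A[iu]
        for _ in range(n_surrogates):
            perm = rng.permutation(w.size)
            S = np.zeros_like(A)
            S[iu] = w[perm]
            S = S + S.T
            cps.append(_onnela_clustering(S).mean())
            Ds = _distances(S)
            fin = np.isfinite(Ds) & off
            lps.append(np.mean(Ds[fin]) if fin.any() else np.inf)
        cp_rand, lp_rand = float(np.mean(cps)), float(np.mean(lps))
        if cp_rand > 0 and lp_rand > 0 and np.isfinite(lp) and lp > 0:
            sw = (cp / cp_rand) / (lp / lp_rand)

    return TopologyMetrics(
        cp=cp,
        lp=lp,
        eg=eg,
        eloc=eloc,
        sw=sw,
        node_clustering=clus,
        node_efficiency=node_eff,
        node_path_length=node_pl,
        node_local_efficiency=node_eloc,
        disconnected=disconnected,
    )


def laplacian(net) -> np.ndarray:
    """Strength Laplacian L = D - A (rows sum to zero)."""
    A = _as_adjacency(net)
    return np.diag(A.sum(axis=1)) - A


def sync_index(net) -> SyncIndex:
    """Synchronizability eigenratio M = lambda_2 / lambda_max of L.

    Disconnected graphs have lambda_2 = 0 and are reported with M = 0 and
    ``connected=False``.
    """
    A = _as_adjacency(net)
    n = A.shape[0]
    if n < 2:
        raise ValueError("synchronizability needs at least 2 nodes")
    L = np.diag(A.sum(axis=1)) - A
    evals = np.linalg.eigvalsh(L)
    lam2, lam_max = float(evals[1]), float(evals[-1])
    n_comp, _ = connected_components((A > 0).astype(int), directed=False)
    connected = n_comp == 1
    if not connected or lam_max <= 0:
        return SyncIndex(lambda2=0.0, lambda_max=max(lam_max, 0.0), M=0.0, connected=False)
    return SyncIndex(lambda2=max(lam2, 0.0), lambda_max=lam_max, M=max(lam2, 0.0) / lam_max)
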
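"""Normalized adjacency operators and graph Laplacians.

Given a gene–gene network with raw weighted adjacency W and diagonal
degree matrix Dg, three normalizations are supported:

* ``symmetric``: A = Dg^(-1/2) W Dg^(-1/2)  (default — keeps the shifted
  Laplacian symmetric positive definite, hence well-conditioned solves)
* ``row``:       A = Dg^(-1) W               (row-stochastic)
* ``column``:    A = W Dg^(-1)               (column-stochastic)

The Laplacian is computed from the *normalized* adjacency: with D the
diagonal of A's row sums, L = D − A. For the symmetric mode L is
symmetric and positive semidefinite, so L + σI is SPD for every σ > 0.
Operators are stored sparse (CSR) and never densified for large graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .data_model import GeneNetwork

__all__ = ["NetworkOperators", "normalize_adjacency", "laplacian_condition_report"]

_MODES = ("symmetric", "row", "column")


@dataclass
class NetworkOperators:
    """Normalized adjacency A_norm, its degree diagonal D and L = D − A_norm."""

    genes: list[str]
    A_norm: sp.csr_matrix
    D: sp.csr_matrix
    L: sp.csr_matrix
    mode: str

    @property
    def n(self) -> int:
        return len(self.genes)


def raw_adjacency(net: GeneNetwork) -> sp.csr_matrix:
    """Raw symmetric weighted adjacency W in the network's gene order."""
    idx = {g: i for i, g in enumerate(net.genes)}
    n = net.n
    rows, cols, vals = [], [], []
    for (a, b), w in net.edges.items():
        i, j = idx[a], idx[b]
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((w, w))
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def normalize_adjacency(net: GeneNetwork, mode: str = "symmetric") -> NetworkOperators:
    """Build :class:`NetworkOperators` for ``net`` under the given mode.

    Every node must have degree >= 1; isolated nodes must be removed
    upstream (see :func:`lapstrat.data_model.align_to_network`).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if net.n == 0:
        raise ValueError("empty network")
    W = raw_adjacency(net)
    deg = np.asarray(W.sum(axis=1)).ravel()
    if (deg <= 0).any():
        isolated = [g for g, d in zip(net.genes, deg) if d <= 0]
        raise ValueError(
            f"isolated nodes present (remove upstream): {isolated[:5]}"
            + ("..." if len(isolated) > 5 else "")
        )
    if mode == "symmetric":
        inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
        A = inv_sqrt @ W @ inv_sqrt
    elif mode == "row":
        A = sp.diags(1.0 / deg) @ W
    else:  # column
        A = W @ sp.diags(1.0 / deg)
    A = sp.csr_matrix(A)
    d = np.asarray(A.sum(axis=1)).ravel()
    D = sp.diags(d, format="csr")
    L = sp.csr_matrix(D - A)
    return NetworkOperators(genes=list(net.genes), A_norm=A, D=D, L=L, mode=mode)


def _cond_estimate(M: sp.spmatrix) -> float:
    """2-norm condition number (dense) for small n, 1-norm estimate above."""
    n = M.shape[0]
    if n <= 2000:
        return float(np.linalg.cond(M.toarray()))
    lu = spla.splu(sp.csc_matrix(M))
    norm_M = spla.onenormest(M)
    norm_inv = spla.onenormest(
        spla.LinearOperator(M.shape, matvec=lu.solve, dtype=float)
    )
    return float(norm_M * norm_inv)


def laplacian_condition_report(
    ops: NetworkOperators, sigma: float, alpha: float = 0.5
) -> dict:
    """Conditioning diagnostics for the two smoothing systems.

    Reports condition-number estimates of the shifted Laplacian (L + σI)
    used by label propagation and of the RWR system (I − (1−α)A), plus
    the minimum node degree of the normalized operator — low-degree nodes
    are what drives the RWR system toward ill-conditioning.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    n = ops.n
    eye = sp.identity(n, format="csr")
    report = {
        "n": n,
        "sigma": float(sigma),
        "alpha": float(alpha),
        "min_degree": float(np.asarray(ops.D.diagonal()).min()),
        "cond_shifted_laplacian": _cond_estimate(ops.L + sigma * eye),
        "cond_rwr_system": _cond_estimate(eye - (1.0 - alpha) * ops.A_norm),
    }
    return report
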
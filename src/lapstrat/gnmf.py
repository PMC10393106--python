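"""Graph-regularized nonnegative matrix factorization (GNMF).

Factorizes a nonnegative genes × patients matrix F ≈ WH, where W
(genes × k) is the basis matrix and H (k × patients) the patient-cluster
matrix, minimizing

    ‖F − WH‖_F² + λ · Tr(H L Hᵀ)

with L = D − A the unnormalized Laplacian of a K-nearest-neighbor graph
over patients: patients close in profile space are pushed toward similar
factor loadings. Solved by the standard multiplicative updates

    W ← W ∘ (F Hᵀ) / (W H Hᵀ)
    H ← H ∘ (Wᵀ F + λ H A) / (Wᵀ W H + λ H D)

which keep both factors nonnegative and never increase the objective.
Patients are assigned to the cluster of their largest H loading.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "GNMFConfig",
    "GNMFResult",
    "KnnGraph",
    "build_knn_graph",
    "gnmf_objective",
    "fit_gnmf",
    "assign_clusters",
]


@dataclass
class GNMFConfig:
    """GNMF hyperparameters.

    k : factor rank = number of clusters (>= 2 for clustering use; k = 1
        is allowed for degenerate/diagnostic fits).
    lam : regularization constant λ >= 0 scaling the KNN-Laplacian term.
    knn_k : neighbor count of the patient KNN graph.
    max_iter, tol : stopping rule — relative objective change < tol.
    seed : RNG seed for the entrywise-uniform initialization.
    """

    k: int = 4
    lam: float = 1.0
    knn_k: int = 11
    max_iter: int = 250
    tol: float = 1e-4
    seed: int = 0
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class GNMFResult:
    W: np.ndarray  # genes × k
    H: np.ndarray  # k × patients
    objective_trace: list[float]
    converged: bool
    config: GNMFConfig | None = None


@dataclass
class KnnGraph:
    """Unnormalized KNN graph over items: adjacency A, degree D, L = D − A."""

    A: sp.csr_matrix
    D: sp.csr_matrix
    L: sp.csr_matrix
    knn_k: int


def build_knn_graph(X: np.ndarray, knn_k: int) -> KnnGraph:
    """Mutual-or KNN graph on the rows of X (Euclidean distances).

    An edge i–j (weight 1) is present when j is among i's ``knn_k``
    nearest neighbors or vice versa. Distance ties are broken by index
    order. The Laplacian is the unnormalized L = D − A.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if knn_k >= n:
        raise ValueError(f"knn_k={knn_k} must be < number of items {n}")
    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    # stable argsort: equal distances resolve to the lower index
    order = np.argsort(dist, axis=1, kind="stable")
    neighbors = order[:, :knn_k]
    rows = np.repeat(np.arange(n), knn_k)
    cols = neighbors.ravel()
    A = sp.coo_matrix((np.ones(n * knn_k), (rows, cols)), shape=(n, n))
    A = A.maximum(A.T).tocsr()  # or-rule symmetrization, weight 1
    A.data[:] = 1.0
    d = np.asarray(A.sum(axis=1)).ravel()
    D = sp.diags(d, format="csr")
    L = sp.csr_matrix(D - A)
    return KnnGraph(A=A, D=D, L=L, knn_k=knn_k)


def gnmf_objective(
    F: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    lam: float,
    L_knn: sp.spmatrix | np.ndarray | None,
) -> float:
    """Eq-style objective: squared Frobenius error + λ·Tr(H L Hᵀ)."""
    R = F - W @ H
    value = float(np.sum(R * R))
    if lam > 0 and L_knn is not None:
        HL = H @ L_knn if not sp.issparse(L_knn) else (L_knn.T @ H.T).T
        value += float(lam * np.sum(H * HL))
    return value


def fit_gnmf(
    F: np.ndarray,
    config: GNMFConfig,
    knn_graph: KnnGraph | None = None,
) -> GNMFResult:
    """Fit GNMF to a nonnegative patients × genes matrix.

    The matrix is transposed internally so that the factorization is
    F ≈ WH with W genes × k and H k × patients; the KNN graph is built on
    the patients (rows of the input) from their profiles unless a
    prebuilt graph is supplied.
    """
    F_in = np.asarray(F, dtype=float)
    if not np.isfinite(F_in).all():
        raise ValueError("non-finite entries in F")
    if (F_in < 0).any():
        raise ValueError("F must be nonnegative (clip negatives upstream)")
    n_patients, n_genes = F_in.shape
    if config.k > min(n_patients, n_genes):
        raise ValueError(
            f"k={config.k} exceeds min dimension {min(n_patients, n_genes)}"
        )
    if knn_graph is None and config.lam > 0:
        knn_graph = build_knn_graph(F_in, min(config.knn_k, n_patients - 1))
    X = F_in.T  # genes × patients
    rng = np.random.default_rng(config.seed)
    scale = max(X.mean() / config.k, np.finfo(float).tiny)
    W = rng.random((n_genes, config.k)) * scale
    H = rng.random((config.k, n_patients)) * scale
    eps = config.eps
    if config.lam > 0 and knn_graph is not None:
        A, D, L = knn_graph.A, knn_graph.D, knn_graph.L
    else:
        A = D = L = None
    trace = [gnmf_objective(X, W, H, config.lam, L)]
    converged = False
    for _ in range(config.max_iter):
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        numer = W.T @ X
        denom = (W.T @ W) @ H + eps
        if A is not None:
            numer = numer + config.lam * (A @ H.T).T  # H A (A symmetric)
            denom = denom + config.lam * (D @ H.T).T
        H *= numer / denom
        obj = gnmf_objective(X, W, H, config.lam, L)
        prev = trace[-1]
        trace.append(obj)
        if prev > 0 and (prev - obj) / prev < config.tol:
            converged = True
            break
        if prev == 0.0:
            converged = True
            break
    return GNMFResult(W=W, H=H, objective_trace=trace, converged=converged, config=config)


def assign_clusters(H: np.ndarray) -> np.ndarray:
    """Assign each patient to argmax over the k rows of H (labels 1..k).

    Ties resolve to the lowest cluster index; an all-zero column gets
    label 1 with a warning.
    """
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("H must be nonnegative")
    zero_cols = ~H.any(axis=0)
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} patients have all-zero H columns; "
            "assigned to cluster 1",
            stacklevel=2,
        )
    return H.argmax(axis=0) + 1
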
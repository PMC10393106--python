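"""Consensus clustering over subsampled smoothing + GNMF runs.

The pipeline of one run: subsample 80% of patients and genes without
replacement, smooth the subsampled binary matrix on the induced
subnetwork, quantile-normalize, clip negatives, fit GNMF, assign
clusters. Over ``n_runs`` runs, pairwise co-assignment and co-sampling
counts are accumulated into an N × N co-clustering matrix

    C_ij = (# runs i and j clustered together) / (# runs i and j co-sampled)

(normalizing by co-sampling, not total runs, since with 80% subsampling
a pair is absent from roughly a third of runs). Final labels come from
average-linkage hierarchical clustering of the dissimilarity 1 − C, cut
to k clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .data_model import GeneNetwork, MutationCohort, align_to_network
from .gnmf import GNMFConfig, assign_clusters, fit_gnmf
from .graph_ops import normalize_adjacency
from .smoothing import (
    PropagationConfig,
    SmoothedProfiles,
    quantile_normalize,
    smooth_label_propagation,
    smooth_rwr_closed_form,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "subsample_indices",
    "run_consensus",
    "finalize_clusters",
]


@dataclass
class ConsensusResult:
    """Co-clustering matrix with counts and the final cluster labels."""

    patients: list[str]
    C: np.ndarray
    together_counts: np.ndarray
    cosample_counts: np.ndarray
    labels: np.ndarray
    k: int
    n_runs: int
    seed: int
    n_failed_runs: int = 0
    clipped_mass: float = 0.0

    @property
    def n_masked_pairs(self) -> int:
        """Distinct patient pairs never co-sampled in any successful run."""
        mask = self.cosample_counts == 0
        np.fill_diagonal(mask, False)
        return int(mask.sum() // 2)


def subsample_indices(
    n_patients: int,
    n_genes: int,
    fraction: float = 0.8,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform without-replacement index subsample on both axes.

    Takes floor(fraction·n) distinct indices per axis, returned sorted.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    n_p = int(np.floor(fraction * n_patients))
    n_g = int(np.floor(fraction * n_genes))
    if n_p < 2 or n_g < 2:
        raise ValueError("subsample too small (< 2 patients or genes)")
    p_idx = np.sort(rng.choice(n_patients, size=n_p, replace=False))
    g_idx = np.sort(rng.choice(n_genes, size=n_g, replace=False))
    return p_idx, g_idx


def _smooth(
    cohort: MutationCohort,
    net: GeneNetwork,
    prop_config: PropagationConfig,
    norm_mode: str,
) -> SmoothedProfiles:
    aligned, sub_net = align_to_network(cohort, net)
    ops = normalize_adjacency(sub_net, mode=norm_mode)
    if prop_config.method == "label_propagation":
        smoothed = smooth_label_propagation(
            aligned, ops, prop_config.sigma, tol=prop_config.tol
        )
    else:
        smoothed = smooth_rwr_closed_form(
            aligned, ops, prop_config.alpha, eq8_convention=prop_config.eq8_convention
        )
    if prop_config.quantile_normalize and smoothed.F.shape[0] > 1:
        smoothed = quantile_normalize(smoothed)
    return smoothed


def _clip_nonnegative(F: np.ndarray) -> tuple[np.ndarray, float]:
    neg = F < 0
    clipped = float(-F[neg].sum()) if neg.any() else 0.0
    if clipped:
        F = np.where(neg, 0.0, F)
    return F, clipped


def run_consensus(
    cohort: MutationCohort,
    net: GeneNetwork,
    prop_config: PropagationConfig,
    gnmf_config: GNMFConfig,
    n_runs: int = 100,
    fraction: float = 0.8,
    seed: int = 0,
    norm_mode: str = "symmetric",
    smooth_first: bool = False,
    min_success_fraction: float = 0.9,
) -> ConsensusResult:
    """Subsampled consensus clustering of a mutation cohort.

    By default each run subsamples patients *and* genes, smooths the
    subsampled matrix on the induced subnetwork, and clusters it
    (subsample-then-smooth). With ``smooth_first`` the full matrix is
    smoothed once and only patients are subsampled per run. Per-run RNG
    streams are derived from the master seed and the run index, so each
    run is independently reproducible. Runs that fail are skipped; if
    fewer than ``min_success_fraction`` of runs succeed the whole
    consensus errors out.
    """
    n = cohort.n_patients
    together = np.zeros((n, n), dtype=np.int64)
    cosample = np.zeros((n, n), dtype=np.int64)
    clipped_total = 0.0

    if smooth_first:
        full_smoothed = _smooth(cohort, net, prop_config, norm_mode)
        full_F, clipped = _clip_nonnegative(full_smoothed.F)
        clipped_total += clipped

    n_failed = 0
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        gnmf_seed = int(rng.integers(2**31))
        try:
            if smooth_first:
                p_idx, _ = subsample_indices(n, cohort.n_genes, fraction, rng)
                F_sub = full_F[p_idx, :]
            else:
                p_idx, g_idx = subsample_indices(n, cohort.n_genes, fraction, rng)
                sub = MutationCohort(
                    patients=[cohort.patients[i] for i in p_idx],
                    genes=[cohort.genes[j] for j in g_idx],
                    M=cohort.M[np.ix_(p_idx, g_idx)],
                )
                smoothed = _smooth(sub, net, prop_config, norm_mode)
                F_sub, clipped = _clip_nonnegative(smoothed.F)
                clipped_total += clipped
            cfg = GNMFConfig(
                k=gnmf_config.k,
                lam=gnmf_config.lam,
                knn_k=min(gnmf_config.knn_k, F_sub.shape[0] - 1),
                max_iter=gnmf_config.max_iter,
                tol=gnmf_config.tol,
                seed=gnmf_seed,
                eps=gnmf_config.eps,
            )
            result = fit_gnmf(F_sub, cfg)
            labels = assign_clusters(result.H)
        except Exception:  # noqa: BLE001 — a failed run is skipped, not fatal
            n_failed += 1
            logger.exception("consensus run %d failed; skipping", run)
            continue
        ix = np.ix_(p_idx, p_idx)
        cosample[ix] += 1
        together[ix] += labels[:, None] == labels[None, :]

    n_ok = n_runs - n_failed
    if n_ok < min_success_fraction * n_runs:
        raise RuntimeError(
            f"only {n_ok}/{n_runs} consensus runs succeeded "
            f"(required {min_success_fraction:.0%})"
        )
    if clipped_total:
        logger.info("run_consensus: clipped negative mass %.4g before GNMF", clipped_total)

    C = np.zeros((n, n), dtype=float)
    observed = cosample > 0
    C[observed] = together[observed] / cosample[observed]
    labels = finalize_clusters(C, gnmf_config.k)
    return ConsensusResult(
        patients=list(cohort.patients),
        C=C,
        together_counts=together,
        cosample_counts=cosample,
        labels=labels,
        k=gnmf_config.k,
        n_runs=n_runs,
        seed=seed,
        n_failed_runs=n_failed,
        clipped_mass=clipped_total,
    )


def finalize_clusters(C: np.ndarray, k: int) -> np.ndarray:
    """Cut the average-linkage hierarchy of 1 − C into k clusters.

    Deterministic; labels are 1..k as returned by the tree cut.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n):
        raise ValueError("C must be square")
    if k > n:
        raise ValueError(f"k={k} exceeds number of patients {n}")
    if k == 1:
        return np.ones(n, dtype=int)
    D = 1.0 - C
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    np.clip(D, 0.0, None, out=D)
    Z = sch.linkage(squareform(D, checks=False), method="average")
    return sch.fcluster(Z, t=k, criterion="maxclust")
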
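"""Clustering-quality metrics and survival analysis.

Internal clustering metrics (all on Euclidean distances over the feature
matrix used for clustering):

* silhouette coefficient (higher = better; singleton points score 0);
* Davies–Bouldin index (lower = better);
* intra-cluster distances — complete (max pairwise), average (mean over
  distinct pairs) and centroid (mean distance to the cluster centroid),
  each averaged unweighted over clusters.

Silhouette and Davies–Bouldin are computed here from exact pairwise
distances (the quadratic-expansion shortcut some libraries use costs
~1e-8 of precision), as are intra-cluster distances and the
optimal-matching cluster accuracy. Survival analysis (Kaplan–Meier
curves per cluster and the g-sample log-rank test) delegates to
lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .data_model import ClinicalTable

__all__ = [
    "ClusterMetricsReport",
    "SurvivalReport",
    "KMCurve",
    "silhouette_score",
    "davies_bouldin_index",
    "intra_cluster_distances",
    "cluster_metrics",
    "cluster_label_accuracy",
    "kaplan_meier",
    "logrank_test",
    "survival_by_cluster",
]

FIVE_YEARS_DAYS = 1825.0


def _validate_clustering(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.shape[0]:
        raise ValueError("X rows and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    return X, labels


def silhouette_score(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b − a)/max(a, b) over points, Euclidean metric.

    ``a`` is the mean intra-cluster distance, ``b`` the smallest mean
    distance to another cluster; points in singleton clusters score 0,
    and a 0/0 degenerate point (all relevant distances zero) scores 0.
    """
    X, labels = _validate_clustering(X, labels)
    D = cdist(X, X)
    uniq = np.unique(labels)
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    scores = np.zeros(len(X))
    for i in range(len(X)):
        c = labels[i]
        if sizes[c] == 1:
            continue  # singleton convention: score 0
        a = D[i, masks[c]].sum() / (sizes[c] - 1)
        b = min(D[i, masks[o]].mean() for o in uniq if o != c)
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def davies_bouldin_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Davies–Bouldin index: mean over clusters of max_j (s_i+s_j)/d_ij,
    with s the mean distance to the cluster centroid and d the centroid
    distance. Coincident centroids of distinct clusters are an error."""
    X, labels = _validate_clustering(X, labels)
    uniq = np.unique(labels)
    centroids = np.stack([X[labels == c].mean(axis=0) for c in uniq])
    cd = cdist(centroids, centroids)
    iu = np.triu_indices(len(uniq), 1)
    if np.any(cd[iu] == 0):
        raise ValueError("coincident centroids of distinct clusters")
    scatter = np.array(
        [cdist(X[labels == c], centroids[[k]]).mean() for k, c in enumerate(uniq)]
    )
    ratios = (scatter[:, None] + scatter[None, :]) / np.where(cd > 0, cd, np.inf)
    np.fill_diagonal(ratios, 0.0)
    return float(ratios.max(axis=1).mean())


@dataclass
class ClusterMetricsReport:
    silhouette: float
    davies_bouldin: float
    intra_complete: float
    intra_average: float
    intra_centroid: float
    per_cluster: dict

    def to_dict(self) -> dict:
        return {
            "silhouette": self.silhouette,
            "davies_bouldin": self.davies_bouldin,
            "intra_complete": self.intra_complete,
            "intra_average": self.intra_average,
            "intra_centroid": self.intra_centroid,
            "per_cluster": self.per_cluster,
        }


def intra_cluster_distances(
    X: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Unweighted cluster means of (complete, average, centroid) distances.

    Per cluster: complete = max pairwise distance, average = mean over
    distinct pairs, centroid = mean distance to the cluster centroid.
    Singleton clusters contribute 0 to all three.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    per = _per_cluster_intra(X, labels)
    comp = float(np.mean([v["complete"] for v in per.values()]))
    avg = float(np.mean([v["average"] for v in per.values()]))
    cent = float(np.mean([v["centroid"] for v in per.values()]))
    return comp, avg, cent


def _per_cluster_intra(X: np.ndarray, labels: np.ndarray) -> dict:
    per: dict = {}
    for c in np.unique(labels):
        pts = X[labels == c]
        if len(pts) < 2:
            per[int(c)] = {"complete": 0.0, "average": 0.0, "centroid": 0.0, "size": len(pts)}
            continue
        pw = pdist(pts)
        centroid = pts.mean(axis=0)
        per[int(c)] = {
            "complete": float(pw.max()),
            "average": float(pw.mean()),
            "centroid": float(np.linalg.norm(pts - centroid, axis=1).mean()),
            "size": int(len(pts)),
        }
    return per


def cluster_metrics(X: np.ndarray, labels: np.ndarray) -> ClusterMetricsReport:
    """Full internal-metric report for one clustering."""
    comp, avg, cent = intra_cluster_distances(X, labels)
    return ClusterMetricsReport(
        silhouette=silhouette_score(X, labels),
        davies_bouldin=davies_bouldin_index(X, labels),
        intra_complete=comp,
        intra_average=avg,
        intra_centroid=cent,
        per_cluster=_per_cluster_intra(np.asarray(X, dtype=float), np.asarray(labels)),
    )


def cluster_label_accuracy(pred_labels, true_labels) -> float:
    """Accuracy under the best one-to-one cluster ↔ label assignment.

    The confusion matrix is matched by optimal bipartite assignment;
    with unequal numbers of clusters and labels the smaller side is
    matched and unmatched samples count as wrong.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("label vectors must have equal length")
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(true, return_inverse=True)
    confusion = np.zeros((len(pu), len(tu)), dtype=np.int64)
    np.add.at(confusion, (pi, ti), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    return float(confusion[rows, cols].sum() / len(pred))


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit curve for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "survival": self.survival.tolist(),
            "at_risk": self.at_risk.tolist(),
        }


def _truncate(times: np.ndarray, events: np.ndarray, horizon: float):
    over = times > horizon
    t = np.where(over, horizon, times)
    e = np.where(over, 0, events)
    return t, e


def kaplan_meier(
    times, events, truncate_at: float | None = None
) -> KMCurve:
    """Product-limit estimator Ŝ(t) = Π_{t_i <= t} (1 − d_i/n_i).

    ``truncate_at`` right-censors all subjects past the horizon (pass
    :data:`FIVE_YEARS_DAYS` for the 5-year convention with day units).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty group")
    if (times < 0).any():
        raise ValueError("negative times")
    if truncate_at is not None:
        times, events = _truncate(times, events, truncate_at)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        at_risk=at_risk,
    )


def logrank_test(groups) -> tuple[float, int, float]:
    """g-sample log-rank test.

    ``groups`` is a list of (times, events) arrays. Returns the
    chi-square statistic, degrees of freedom (g − 1) and the upper-tail
    p-value, comparing observed vs expected events per group under the
    hypergeometric null at each distinct event time.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    times_all, events_all, ids = [], [], []
    for gid, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {gid} is empty")
        times_all.append(t)
        events_all.append(e)
        ids.append(np.full(t.size, gid))
    times = np.concatenate(times_all)
    events = np.concatenate(events_all)
    ids = np.concatenate(ids)
    if events.sum() == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(times, ids, events)
    df = len(groups) - 1
    return float(res.test_statistic), df, float(res.p_value)


@dataclass
class SurvivalReport:
    curves: dict[int, KMCurve]
    chi2: float
    df: int
    p_value: float
    group_sizes: dict[int, int]
    time_unit: str = "days"

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "group_sizes": {str(k): v for k, v in self.group_sizes.items()},
            "time_unit": self.time_unit,
            "curves": {str(k): c.to_dict() for k, c in self.curves.items()},
        }


def survival_by_cluster(
    clinical: ClinicalTable,
    patients,
    labels,
    truncate_5y: bool = False,
) -> SurvivalReport:
    """KM curves per cluster plus the multi-group log-rank test.

    Patients missing from the clinical table are dropped. The 5-year
    truncation assumes day units (1825 days).
    """
    labels = np.asarray(labels)
    idx = {p: i for i, p in enumerate(clinical.patients)}
    keep = [(j, idx[p]) for j, p in enumerate(patients) if p in idx]
    if not keep:
        raise ValueError("no overlap between labels and clinical table")
    horizon = FIVE_YEARS_DAYS if truncate_5y else None
    groups, curves, sizes = [], {}, {}
    for c in np.unique(labels[[j for j, _ in keep]]):
        rows = [ci for j, ci in keep if labels[j] == c]
        t, e = clinical.time[rows], clinical.event[rows]
        if horizon is not None:
            t, e = _truncate(t, e, horizon)
        groups.append((t, e))
        curves[int(c)] = kaplan_meier(t, e)
        sizes[int(c)] = len(rows)
    chi2, df, p = logrank_test(groups)
    return SurvivalReport(
        curves=curves,
        chi2=chi2,
        df=df,
        p_value=p,
        group_sizes=sizes,
        time_unit=clinical.time_unit,
    )
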
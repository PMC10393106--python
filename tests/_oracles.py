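"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity from its definition with naive
loops (or tiny dense linear algebra), deliberately sharing no code with
the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def brute_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Per-point (b − a)/max(a, b), naive pairwise loops; singletons 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own])
        b = np.inf
        for c in set(labels.tolist()) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean([np.linalg.norm(X[i] - X[j]) for j in members]))
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(scores))


def brute_davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    clusters = sorted(set(labels.tolist()))
    centroids = {c: X[labels == c].mean(axis=0) for c in clusters}
    scatter = {
        c: np.mean([np.linalg.norm(x - centroids[c]) for x in X[labels == c]])
        for c in clusters
    }
    ratios = []
    for ci in clusters:
        worst = 0.0
        for cj in clusters:
            if ci == cj:
                continue
            d = np.linalg.norm(centroids[ci] - centroids[cj])
            worst = max(worst, (scatter[ci] + scatter[cj]) / d)
        ratios.append(worst)
    return float(np.mean(ratios))


def brute_intra_distances(X: np.ndarray, labels: np.ndarray):
    """Per-cluster (complete, average, centroid) distances, averaged."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    comp, avg, cent = [], [], []
    for c in sorted(set(labels.tolist())):
        pts = X[labels == c]
        if len(pts) < 2:
            comp.append(0.0)
            avg.append(0.0)
            cent.append(0.0)
            continue
        pairs = [
            np.linalg.norm(pts[i] - pts[j])
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        ]
        comp.append(max(pairs))
        avg.append(float(np.mean(pairs)))
        centroid = pts.mean(axis=0)
        cent.append(float(np.mean([np.linalg.norm(p - centroid) for p in pts])))
    return float(np.mean(comp)), float(np.mean(avg)), float(np.mean(cent))


def brute_logrank(groups):
    """g-sample log-rank from the observed/expected hypergeometric table.

    Returns (chi2, df, p). chi2 uses the first g−1 groups and the
    pseudo-inverse of their covariance block, the standard construction.
    """
    from scipy.stats import chi2 as chi2_dist

    g = len(groups)
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, dtype=int) for _, e in groups])
    gid = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    event_times = np.unique(times[events == 1])
    O = np.zeros(g)
    E = np.zeros(g)
    V = np.zeros((g, g))
    for t in event_times:
        at_risk = times >= t
        n_i = at_risk.sum()
        d_i = ((times == t) & (events == 1)).sum()
        n_gi = np.array([np.sum(at_risk & (gid == k)) for k in range(g)])
        d_gi = np.array(
            [np.sum((times == t) & (events == 1) & (gid == k)) for k in range(g)]
        )
        O += d_gi
        E += d_i * n_gi / n_i
        factor = 1.0 if n_i == 1 else (n_i - d_i) / (n_i - 1)
        factor *= d_i / n_i**2
        for a in range(g):
            for b in range(g):
                V[a, b] += factor * ((a == b) * n_gi[a] * n_i - n_gi[a] * n_gi[b])
    z = (O - E)[:-1]
    chi2 = float(z @ np.linalg.pinv(V[:-1, :-1]) @ z)
    df = g - 1
    p = float(chi2_dist.sf(chi2, df))
    return chi2, df, p


def brute_kaplan_meier(times, events):
    """Product-limit estimate at each distinct event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ts = np.unique(times[events == 1])
    surv = []
    s = 1.0
    for t in ts:
        n = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / n
        surv.append(s)
    return ts, np.array(surv)


def brute_knn_adjacency(X: np.ndarray, knn_k: int) -> np.ndarray:
    """Or-rule KNN adjacency by exhaustive distance sort (ties by index)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    A = np.zeros((n, n))
    for i in range(n):
        dists = sorted(
            (np.linalg.norm(X[i] - X[j]), j) for j in range(n) if j != i
        )
        for _, j in dists[:knn_k]:
            A[i, j] = 1.0
            A[j, i] = 1.0
    return A


def brute_gnmf_objective(F, W, H, lam, L) -> float:
    """Naive double-loop Frobenius error + λ·Tr(H L Hᵀ)."""
    F = np.asarray(F, dtype=float)
    R = F - np.asarray(W) @ np.asarray(H)
    total = 0.0
    for i in range(R.shape[0]):
        for j in range(R.shape[1]):
            total += R[i, j] ** 2
    if lam > 0 and L is not None:
        L = np.asarray(L.todense()) if hasattr(L, "todense") else np.asarray(L)
        HLHt = np.asarray(H) @ L @ np.asarray(H).T
        total += lam * np.trace(HLHt)
    return float(total)


def brute_accuracy_by_permutation(pred, true) -> float:
    """Best accuracy over all label permutations (small k only)."""
    from itertools import permutations

    pred = np.asarray(pred)
    true = np.asarray(true)
    pu = sorted(set(pred.tolist()))
    tu = sorted(set(true.tolist()))
    small, large = (pu, tu) if len(pu) <= len(tu) else (tu, pu)
    best = 0
    for perm in permutations(large, len(small)):
        mapping = dict(zip(small, perm))
        if len(pu) <= len(tu):
            correct = sum(mapping[p] == t for p, t in zip(pred, true))
        else:
            correct = sum(p == mapping[t] for p, t in zip(pred, true))
        best = max(best, correct)
    return best / len(pred)
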
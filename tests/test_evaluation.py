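import numpy as np
import pytest

from lapstrat.data_model import ClinicalTable
from lapstrat.evaluation import (
    cluster_label_accuracy,
    cluster_metrics,
    davies_bouldin_index,
    intra_cluster_distances,
    kaplan_meier,
    logrank_test,
    silhouette_score,
    survival_by_cluster,
)

from _oracles import (
    brute_accuracy_by_permutation,
    brute_davies_bouldin,
    brute_intra_distances,
    brute_kaplan_meier,
    brute_logrank,
    brute_silhouette,
)


def random_clustering(seed, n=12, d=3, k=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    labels = rng.integers(0, k, size=n)
    while len(np.unique(labels)) < 2:
        labels = rng.integers(0, k, size=n)
    return X, labels


class TestSilhouette:
    def test_two_tight_far_clusters_score_one(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0], [100.0, 0.0]])
        labels = np.array([0, 0, 1, 1])
        assert silhouette_score(X, labels) == pytest.approx(1.0)

    def test_all_identical_points_score_zero(self):
        X = np.zeros((6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert silhouette_score(X, labels) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        X, labels = random_clustering(seed, n=6, d=2, k=2)
        assert silhouette_score(X, labels) == pytest.approx(
            brute_silhouette(X, labels), abs=1e-12
        )

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            silhouette_score(np.zeros((4, 2)), np.zeros(4))


class TestDaviesBouldin:
    def test_zero_scatter_clusters(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 0.0], [5.0, 0.0]])
        labels = np.array([0, 0, 1, 1])
        assert davies_bouldin_index(X, labels) == pytest.approx(0.0)

    def test_scale_invariance(self):
        X, labels = random_clustering(3)
        a = davies_bouldin_index(X, labels)
        b = davies_bouldin_index(17.3 * X, labels)
        assert a == pytest.approx(b, rel=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        X, labels = random_clustering(seed)
        assert davies_bouldin_index(X, labels) == pytest.approx(
            brute_davies_bouldin(X, labels), abs=1e-10
        )

    def test_coincident_centroids_error(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        labels = np.array([0, 0, 1, 1])  # both centroids at the origin
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin_index(X, labels)


class TestIntraClusterDistances:
    def test_two_point_cluster_geometry(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        labels = np.array([0, 0])
        comp, avg, cent = intra_cluster_distances(X, labels)
        assert (comp, avg, cent) == (2.0, 2.0, 1.0)

    def test_all_singletons_zero(self):
        X = np.arange(8.0).reshape(4, 2)
        comp, avg, cent = intra_cluster_distances(X, np.arange(4))
        assert (comp, avg, cent) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        X, labels = random_clustering(seed, n=8, k=2)
        ours = intra_cluster_distances(X, labels)
        oracle = brute_intra_distances(X, labels)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)


class TestClusterLabelAccuracy:
    def test_permuted_labels_perfect(self):
        true = np.array([1, 1, 2, 2, 3, 3])
        pred = np.array([3, 3, 1, 1, 2, 2])
        assert cluster_label_accuracy(pred, true) == 1.0

    def test_all_one_cluster_vs_balanced(self):
        true = np.array([1, 1, 2, 2])
        pred = np.ones(4, dtype=int)
        assert cluster_label_accuracy(pred, true) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_permutation_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 3, size=15)
        true = rng.integers(0, 3, size=15)
        assert cluster_label_accuracy(pred, true) == pytest.approx(
            brute_accuracy_by_permutation(pred, true)
        )

    def test_unequal_cluster_counts(self):
        true = np.array([1, 2, 3, 3])
        pred = np.array([1, 1, 2, 2])
        # best match covers 2 pred clusters; unmatched samples are wrong
        assert cluster_label_accuracy(pred, true) == 0.75


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = kaplan_meier([5.0, 7.0, 9.0], [0, 0, 0])
        np.testing.assert_allclose(km.survival, 1.0)

    def test_all_die_at_once(self):
        km = kaplan_meier([1.0] * 5, [1] * 5)
        assert km.survival[km.times >= 1.0].max() == 0.0

    def test_hand_product_limit(self):
        # times (1,2,3), events (1,0,1): S(1)=2/3, S(2)=2/3, S(3)=0
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        s_at = dict(zip(km.times, km.survival))
        assert s_at[1.0] == pytest.approx(2 / 3)
        assert s_at[3.0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.exponential(1.0, 20).round(2)
        events = rng.integers(0, 2, 20)
        if events.sum() == 0:
            events[0] = 1
        km = kaplan_meier(times, events)
        ts, surv = brute_kaplan_meier(times, events)
        s_at = dict(zip(km.times, km.survival))
        for t, s in zip(ts, surv):
            assert s_at[t] == pytest.approx(s, abs=1e-12)

    def test_truncation_censors_past_horizon(self):
        km = kaplan_meier([100.0, 3000.0], [1, 1], truncate_at=1825.0)
        assert km.survival.min() > 0.0  # the late death became censored

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        chi2, df, p = logrank_test([(t, e), (t, e)])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_group_permutation_invariance(self):
        rng = np.random.default_rng(1)
        groups = [
            (rng.exponential(1.0, 10), rng.integers(0, 2, 10)) for _ in range(3)
        ]
        if sum(g[1].sum() for g in groups) == 0:
            groups[0][1][0] = 1
        a = logrank_test(groups)
        b = logrank_test([groups[2], groups[0], groups[1]])
        assert a[0] == pytest.approx(b[0], abs=1e-10)
        assert a[2] == pytest.approx(b[2], abs=1e-10)

    def test_small_two_group_hand_oracle(self):
        g1 = (np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 0, 1]))
        g2 = (np.array([1.5, 2.5, 3.5, 4.5]), np.array([1, 0, 1, 1]))
        chi2, df, p = logrank_test([g1, g2])
        o_chi2, o_df, o_p = brute_logrank([g1, g2])
        assert chi2 == pytest.approx(o_chi2, abs=1e-10)
        assert df == o_df
        assert p == pytest.approx(o_p, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("g", [2, 3, 4])
    def test_multigroup_matches_oracle(self, seed, g):
        rng = np.random.default_rng(seed)
        groups = []
        for _ in range(g):
            t = rng.exponential(1.0, 12).round(2)
            e = rng.integers(0, 2, 12)
            groups.append((t, e))
        if sum(gr[1].sum() for gr in groups) == 0:
            groups[0][1][0] = 1
        chi2, df, p = logrank_test(groups)
        o_chi2, o_df, o_p = brute_logrank(groups)
        assert chi2 == pytest.approx(o_chi2, abs=1e-10)
        assert df == o_df == g - 1
        assert p == pytest.approx(o_p, abs=1e-10)

    def test_zero_events_errors(self):
        with pytest.raises(ValueError):
            logrank_test([(np.ones(3), np.zeros(3, dtype=int)),
                          (np.ones(3), np.zeros(3, dtype=int))])


class TestAgainstScikitLearn:
    """Independent cross-checks against the sklearn implementations
    (looser tolerance: sklearn's distance shortcut costs ~1e-8)."""

    @pytest.mark.parametrize("seed", range(5))
    def test_silhouette_agrees(self, seed):
        from sklearn.metrics import silhouette_score as sk_sil

        X, labels = random_clustering(seed, n=20, k=3)
        assert silhouette_score(X, labels) == pytest.approx(
            sk_sil(X, labels), abs=1e-6
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_davies_bouldin_agrees(self, seed):
        from sklearn.metrics import davies_bouldin_score as sk_db

        X, labels = random_clustering(seed, n=20, k=3)
        assert davies_bouldin_index(X, labels) == pytest.approx(
            sk_db(X, labels), abs=1e-6
        )


class TestMetricInvariances:
    def test_label_permutation_invariance(self):
        X, labels = random_clustering(7, n=15, k=3)
        perm = {0: 2, 1: 0, 2: 1}
        relabeled = np.array([perm[l] for l in labels])
        assert silhouette_score(X, labels) == pytest.approx(
            silhouette_score(X, relabeled)
        )
        assert davies_bouldin_index(X, labels) == pytest.approx(
            davies_bouldin_index(X, relabeled)
        )
        np.testing.assert_allclose(
            intra_cluster_distances(X, labels), intra_cluster_distances(X, relabeled)
        )

    def test_rotation_invariance(self):
        X, labels = random_clustering(8, n=15, d=2, k=3)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        XR = X @ R.T
        assert silhouette_score(X, labels) == pytest.approx(
            silhouette_score(XR, labels), abs=1e-9
        )
        assert davies_bouldin_index(X, labels) == pytest.approx(
            davies_bouldin_index(XR, labels), abs=1e-9
        )


class TestSurvivalByCluster:
    def test_report_structure_and_df(self):
        rng = np.random.default_rng(2)
        n = 40
        patients = [f"p{i}" for i in range(n)]
        labels = np.repeat([1, 2], n // 2)
        time = np.where(labels == 1, rng.exponential(10, n), rng.exponential(3, n))
        clin = ClinicalTable(patients=patients, time=time, event=np.ones(n, dtype=int))
        report = survival_by_cluster(clin, patients, labels)
        assert report.df == 1
        assert set(report.curves) == {1, 2}
        assert 0.0 <= report.p_value <= 1.0
        for curve in report.curves.values():
            assert (np.diff(curve.survival) <= 1e-12).all()
            assert curve.survival[0] <= 1.0

    def test_full_report_roundtrips_to_dict(self):
        clin = ClinicalTable(
            patients=["a", "b", "c", "d"],
            time=np.array([1.0, 2.0, 3.0, 4.0]),
            event=np.array([1, 1, 1, 0]),
        )
        report = survival_by_cluster(clin, ["a", "b", "c", "d"], np.array([1, 1, 2, 2]))
        d = report.to_dict()
        assert {"chi2", "df", "p_value", "curves", "group_sizes"} <= set(d)


def test_cluster_metrics_report_contains_all_five(strong_cohort):
    syn, cohort, net = strong_cohort
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 4))
    labels = rng.integers(1, 4, size=30)
    report = cluster_metrics(X, labels)
    d = report.to_dict()
    for key in ("silhouette", "davies_bouldin", "intra_complete", "intra_average", "intra_centroid"):
        assert np.isfinite(d[key])
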
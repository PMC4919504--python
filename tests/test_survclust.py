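import numpy as np
import pandas as pd
import pytest

from scribpipe import survclust, synthio


# --- independent oracles -----------------------------------------------------


def km_oracle(times, events):
    """Brute-force product-limit estimate: dict event_time -> S(t)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = {}
    s = 1.0
    for t in sorted(set(times[events])):
        n = np.sum(times >= t)  # censored at t stay at risk
        d = np.sum((times == t) & events)
        s *= 1.0 - d / n
        out[t] = s
    return out


def logrank_oracle_2group(t1, e1, t2, e2):
    """Standardized O-E tabulation for the two-sample log-rank chi-squared."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2]).astype(bool)
    group = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & events).sum()
        d1 = ((times == t) & events & (group == 0)).sum()
        e1_t = d * n1 / n
        o_minus_e += d1 - e1_t
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


# --- Kaplan-Meier ------------------------------------------------------------


class TestKmCurve:
    def test_three_events_hand_product(self):
        curve = survclust.km_curve([1, 2, 3], [True, True, True])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_all_censored_flat_at_one(self):
        curve = survclust.km_curve([5, 10, 15], [False, False, False])
        assert curve.event_times.size == 0
        assert curve.at(12.0) == 1.0

    def test_mixed_eight_subjects_matches_oracle(self):
        times = [3, 5, 5, 8, 10, 12, 15, 20]
        events = [True, True, False, True, False, True, False, True]
        curve = survclust.km_curve(times, events)
        oracle = km_oracle(times, events)
        assert list(curve.event_times) == sorted(oracle)
        np.testing.assert_allclose(curve.survival, [oracle[t] for t in curve.event_times])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(100, 30).round(1) + 1
        events = rng.random(30) < 0.6
        a = survclust.km_curve(times, events)
        perm = rng.permutation(30)
        b = survclust.km_curve(times[perm], events[perm])
        np.testing.assert_allclose(a.survival, b.survival)
        np.testing.assert_array_equal(a.event_times, b.event_times)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(50, 100) + 0.1
        events = rng.random(100) < 0.5
        curve = survclust.km_curve(times, events)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            survclust.km_curve([], [])


# --- log-rank ----------------------------------------------------------------


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([3.0, 6.0, 9.0, 12.0])
        e = np.array([True, True, False, True])
        res = survclust.logrank([(t, e), (t, e)])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_three_groups_two_df(self):
        rng = np.random.default_rng(2)
        groups = [
            (rng.exponential(s, 40) + 1, np.ones(40, bool)) for s in (50, 100, 200)
        ]
        assert survclust.logrank(groups).df == 2

    def test_two_group_toy_matches_hand_oracle(self):
        t1, e1 = [2, 4, 6, 8, 10], [1, 1, 0, 1, 1]
        t2, e2 = [3, 5, 7, 9, 11], [1, 0, 1, 1, 0]
        res = survclust.logrank(
            [(np.array(t1, float), np.array(e1, bool)),
             (np.array(t2, float), np.array(e2, bool))]
        )
        assert res.statistic == pytest.approx(logrank_oracle_2group(t1, e1, t2, e2), rel=1e-9)

    def test_label_swap_invariance_and_p_range(self):
        rng = np.random.default_rng(3)
        a = (rng.exponential(80, 50) + 1, rng.random(50) < 0.7)
        b = (rng.exponential(200, 50) + 1, rng.random(50) < 0.7)
        r1 = survclust.logrank([a, b])
        r2 = survclust.logrank([b, a])
        assert r1.statistic == pytest.approx(r2.statistic)
        assert 0 < r1.p_value <= 1

    def test_no_events_anywhere(self):
        t = np.array([5.0, 6.0])
        e = np.array([False, False])
        res = survclust.logrank([(t, e), (t, e)])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_power_on_separated_hazards(self):
        # hazard ratio 5, n=100/group: p < 0.01 expected in nearly every draw
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = (rng.exponential(1 / 5e-4, 100), np.ones(100, bool))
            b = (rng.exponential(1 / 1e-4, 100), np.ones(100, bool))
            hits += survclust.logrank([a, b]).p_value < 0.01
        assert hits >= 19


# --- k-means and merging -----------------------------------------------------


class TestKmeans:
    def test_k1_wcss_is_total_ss(self):
        rng = np.random.default_rng(4)
        usage = pd.DataFrame(rng.normal(5, 2, (30, 6)))
        assign = survclust.kmeans_usage(usage, k=1, seed=0)
        assert assign.labels.nunique() == 1

    def test_beats_random_labelings(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 1, (20, 4)), rng.normal(6, 1, (20, 4))])
        usage = pd.DataFrame(x)
        assign = survclust.kmeans_usage(usage, k=2, seed=0)

        def wcss(labels):
            total = 0.0
            for lab in np.unique(labels):
                sub = x[labels == lab]
                if len(sub):
                    total += ((sub - sub.mean(0)) ** 2).sum()
            return total

        fitted = wcss(assign.labels.to_numpy())
        randoms = [wcss(rng.integers(0, 2, 40)) for _ in range(100)]
        assert fitted <= min(randoms)

    def test_k_exceeding_patients_rejected(self):
        usage = pd.DataFrame(np.ones((3, 2)))
        with pytest.raises(ValueError):
            survclust.kmeans_usage(usage, k=5)

    def test_missing_rows_dropped(self):
        usage = pd.DataFrame(np.ones((6, 2)), columns=["a", "b"])
        usage.iloc[0, 0] = np.nan
        assign = survclust.kmeans_usage(usage + np.arange(6)[:, None], k=2, seed=0)
        assert len(assign.labels) == 5

    def test_standardized_features_same_separable_partition(self):
        rng = np.random.default_rng(6)
        x = np.vstack([rng.normal(0, 1, (20, 4)), rng.normal(8, 1, (20, 4))])
        usage = pd.DataFrame(x)
        raw = survclust.kmeans_usage(usage, k=2, seed=0)
        z = survclust.kmeans_usage(usage, k=2, seed=0, standardize=True)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(raw.labels, z.labels) == 1.0

    def test_ward_order_groups_similar_profiles(self):
        x = np.vstack([np.zeros((5, 3)), np.full((5, 3), 10.0)])
        usage = pd.DataFrame(
            x[[0, 5, 1, 6, 2, 7, 3, 8, 4, 9]],  # interleave the two blocks
            index=list("ABCDEFGHIJ"),
        )
        order = survclust.ward_order(usage)
        # members of each block must come out contiguous
        low = {b for b in "ACEGI"}
        positions = [i for i, b in enumerate(order) if b in low]
        assert positions == list(range(min(positions), min(positions) + 5))


def _surv_frame(labels, hazards, seed=0):
    rng = np.random.default_rng(seed)
    lam = np.array([hazards[l - 1] for l in labels])
    return pd.DataFrame(
        {
            "survival_time": rng.exponential(1 / lam),
            "event": np.ones(len(labels), dtype=bool),
        },
        index=[f"P{i}" for i in range(len(labels))],
    )


class TestMergeSimilarClusters:
    def _assignment(self, sizes):
        labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
        return survclust.ClusterAssignment(
            labels=pd.Series(labels, index=[f"P{i}" for i in range(labels.size)]),
            k_initial=len(sizes),
        )

    def test_same_hazard_pair_merges_first(self):
        assign = self._assignment([80, 80, 80, 80])
        # clusters 2 and 3 share a hazard; 1 and 4 are far apart
        surv = _surv_frame(assign.labels.to_numpy(), [5e-3, 5e-4, 5e-4, 5e-5], seed=6)
        merged = survclust.merge_similar_clusters(assign, surv, p_merge=0.2, k_target=3)
        assert merged.k_final == 3
        assert merged.merge_map[2] == merged.merge_map[3]

    def test_threshold_never_binding_reaches_k_target(self):
        assign = self._assignment([40, 40, 40, 40])
        surv = _surv_frame(assign.labels.to_numpy(), [8e-3, 2e-3, 5e-4, 1e-4], seed=7)
        merged = survclust.merge_similar_clusters(assign, surv, p_merge=1.01, k_target=2)
        assert merged.k_final == 2

    def test_distinct_survival_identity_at_k_target(self):
        assign = self._assignment([100, 100])
        surv = _surv_frame(assign.labels.to_numpy(), [5e-3, 1e-4], seed=8)
        merged = survclust.merge_similar_clusters(assign, surv, p_merge=0.2, k_target=2)
        assert merged.k_final == 2
        assert merged.merge_map == {1: 1, 2: 2}

    def test_merge_map_surjective_and_never_more_clusters(self):
        assign = self._assignment([30, 30, 30, 30])
        surv = _surv_frame(assign.labels.to_numpy(), [4e-3, 2e-3, 1e-3, 5e-4], seed=9)
        merged = survclust.merge_similar_clusters(assign, surv, p_merge=0.2, k_target=3)
        assert merged.k_final <= 4
        assert set(merged.merge_map.values()) == set(
            int(x) for x in merged.labels.unique()
        )


class TestClusterSummary:
    def _assignment(self, labels, index):
        return survclust.ClusterAssignment(
            labels=pd.Series(labels, index=index), k_initial=len(set(labels))
        )

    def test_constant_usage(self):
        usage = pd.DataFrame(5.0, index=["A", "B", "C"], columns=[1, 2])
        out = survclust.cluster_usage_summary(
            usage, self._assignment([1, 1, 1], ["A", "B", "C"])
        )
        assert (out[["q1", "median", "q3"]] == 5.0).all().all()

    def test_type7_quantiles_on_1_to_100(self):
        usage = pd.DataFrame({1: np.arange(1, 101, dtype=float)},
                             index=[f"P{i}" for i in range(100)])
        out = survclust.cluster_usage_summary(
            usage, self._assignment([1] * 100, usage.index)
        )
        assert out.loc[0, "median"] == pytest.approx(50.5)
        assert out.loc[0, "q1"] == pytest.approx(np.quantile(np.arange(1, 101), 0.25))

    def test_singleton_cluster(self):
        usage = pd.DataFrame({1: [7.0, 2.0]}, index=["A", "B"])
        out = survclust.cluster_usage_summary(usage, self._assignment([1, 2], ["A", "B"]))
        row = out[(out.cluster == 1)].iloc[0]
        assert row.q1 == row["median"] == row.q3 == 7.0
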
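"""Gap statistic, k-means wrapper, cluster summaries, and E/I labeling."""

import numpy as np
import pandas as pd
import pytest

from mocsyn.cluster import (
    PscCluster,
    build_feature_matrix,
    ei_latency_difference,
    gap_select_k,
    kmeans_cluster,
    label_clusters_by_holding,
    summarize_clusters,
)

# Frozen 16-point fixture (two tight 2-D blobs, rng PCG64 seed 42) and the
# reference gap curve computed independently with R cluster::clusGap
# (kmeans, nstart=25, B=500, d.power=2, spaceH0="original", set.seed(1)).
# R's W_k is inertia/2, so its logW differs from ours by exactly log(2),
# which cancels in the gap; gap/SE agree to bootstrap error.
GAP_FIXTURE = np.array([
    [0.0914, -0.3120], [0.2251, 0.2822], [-0.5853, -0.3907], [0.0384, -0.0949],
    [-0.0050, -0.2559], [0.2638, 0.2333], [0.0198, 0.3382], [0.1403, -0.2578],
    [6.1106, 5.7123], [6.2635, 5.9850], [5.9445, 5.7957], [6.3668, 5.9536],
    [5.8715, 5.8944], [6.1597, 6.1096], [6.1238, 6.1292], [6.6425, 5.8781],
])
R_LOGW_PLUS_LOG2 = np.array([5.0006752218, -0.1857757809, -0.6952095983,
                             -1.1430205705]) + np.log(2.0)
R_GAP = np.array([-0.9270877311, 3.5466628856, 3.4423731990, 3.3981108519])


class TestGapSelectK:
    def test_single_gaussian_blob_selects_one(self, rng):
        """The method's selling point: it can pick k = 1 on unimodal data."""
        x = rng.normal(0.0, 1.0, size=(200, 2))
        k, _ = gap_select_k(x, kmax=5, B=60, nstart=10, seed=0)
        assert k == 1

    def test_two_separated_blobs_select_two(self):
        """10-sigma-separated blobs: k = 2 across seeds (MC oracle)."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = np.vstack([
                r.normal(0.0, 1.0, size=(100, 2)),
                r.normal(10.0, 1.0, size=(100, 2)),
            ])
            k, _ = gap_select_k(x, kmax=5, B=40, nstart=10, seed=seed)
            hits += k == 2
        assert hits >= 9

    def test_degenerate_identical_points(self):
        x = np.zeros((2, 3))
        with pytest.warns(UserWarning, match="clipping"):
            k, _ = gap_select_k(x, kmax=10, B=20, nstart=5, seed=0)
        assert k == 1

    def test_matches_r_clusgap_reference(self):
        """Frozen cross-check against R cluster::clusGap on the fixture."""
        k, curve = gap_select_k(GAP_FIXTURE, kmax=4, B=500, nstart=25, seed=1)
        assert k == 2
        np.testing.assert_allclose(curve.log_wk, R_LOGW_PLUS_LOG2, atol=1e-4)
        np.testing.assert_allclose(curve.gap, R_GAP, atol=0.12)

    def test_wk_nonincreasing_and_matches_bruteforce(self):
        """Reported W_k equals recomputation from assignments; W_k drops in k."""
        r = np.random.default_rng(3)
        x = np.vstack([r.normal(0, 1, (40, 2)), r.normal(6, 1, (40, 2))])
        wks = []
        for k in range(1, 5):
            labels, wk = kmeans_cluster(x, k, nstart=10, seed=5)
            brute = sum(
                np.sum((x[labels == c] - x[labels == c].mean(axis=0)) ** 2)
                for c in range(k)
            )
            assert wk == pytest.approx(brute, rel=1e-9)
            wks.append(wk)
        assert all(a >= b - 1e-9 for a, b in zip(wks, wks[1:]))


class TestKMeans:
    def test_k1_total_sum_of_squares(self, rng):
        x = rng.normal(size=(30, 3))
        labels, wk = kmeans_cluster(x, 1)
        assert set(labels) == {0}
        assert wk == pytest.approx(np.sum((x - x.mean(axis=0)) ** 2))

    def test_four_points_two_pairs(self):
        """Exhaustive-partition oracle: {1,2} vs {3,4} is the optimum."""
        x = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels, wk = kmeans_cluster(x, 2, nstart=10, seed=0)
        assert labels[0] == labels[1] != labels[2] == labels[3]
        assert wk == pytest.approx(1.0)  # two pairs, 0.5 SS each

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 2)), 4)

    def test_two_latency_clusters_against_ground_truth(self):
        """Latency clusters at 1.9/4.5 ms, jitter 0.25/0.5: >= 98% assignment
        agreement with the generating labels."""
        r = np.random.default_rng(11)
        n = 150
        lat = np.concatenate([r.normal(1.9, 0.25, n), r.normal(4.5, 0.5, n)])
        truth = np.repeat([0, 1], n)
        labels, _ = kmeans_cluster(lat[:, None], 2, nstart=25, seed=2,
                                   order_by=lat)
        agreement = np.mean(labels == truth)
        assert agreement >= 0.98

    def test_clusters_ordered_by_latency(self):
        r = np.random.default_rng(4)
        lat = np.concatenate([r.normal(5.0, 0.1, 50), r.normal(2.0, 0.1, 50)])
        labels, _ = kmeans_cluster(lat[:, None], 2, order_by=lat, seed=0)
        assert lat[labels == 0].mean() < lat[labels == 1].mean()


def events_frame(latencies, rise=0.5, ttp=1.0, amp=-60.0, decay=3.0):
    n = len(latencies)
    return pd.DataFrame({
        "onset_latency": latencies,
        "rise_time": np.full(n, rise),
        "time_to_peak": np.full(n, ttp),
        "amplitude": np.full(n, amp),
        "decay_tau": np.full(n, decay),
    })


class TestSummarizeClusters:
    def test_identical_latencies_zero_jitter(self):
        ev = events_frame([2.0] * 8)
        (cl,) = summarize_clusters(ev, np.zeros(8, dtype=int), n_sweeps=8)
        assert cl.onset_jitter == 0.0
        assert cl.peak_jitter == 0.0
        assert cl.n == 8

    def test_probability_binomial_recovery(self):
        """80 sweeps, 1 stimulus, generator probability 0.45."""
        r = np.random.default_rng(7)
        n_events = int(np.sum(r.random(80) < 0.45))
        ev = events_frame(r.normal(4.5, 0.5, n_events))
        (cl,) = summarize_clusters(ev, np.zeros(n_events, dtype=int), n_sweeps=80)
        assert cl.probability == pytest.approx(0.45, abs=0.12)

    def test_jitter_recovery(self):
        """Generator jitter 0.25 ms recovered within 0.05 ms for n >= 60."""
        r = np.random.default_rng(9)
        lat = r.normal(1.9, 0.25, 120)
        ev = events_frame(lat)
        (cl,) = summarize_clusters(ev, np.zeros(120, dtype=int), n_sweeps=120)
        assert cl.onset_jitter == pytest.approx(0.25, abs=0.05)

    def test_assignments_must_cover_events(self):
        with pytest.raises(ValueError):
            summarize_clusters(events_frame([1.0, 2.0]), np.array([0]), 2)


def make_cluster(cid, latency, jitter=0.5, label="unknown", n=10):
    return PscCluster(
        cluster_id=cid, event_ids=np.arange(n), n=n,
        mean_onset_latency=latency, median_onset_latency=latency,
        onset_jitter=jitter, peak_jitter=jitter + 0.1, probability=0.5,
        median_amplitude=-60.0, median_rise_time=0.6, median_decay_tau=3.0,
        label=label,
    )


class TestLabeling:
    def test_matching_latency_is_inhibitory(self):
        m60 = [make_cluster(0, 4.5, jitter=0.5)]
        at0 = [make_cluster(0, 4.6, jitter=0.5)]
        out = label_clusters_by_holding(m60, at0)
        assert out[0].label == "inhibitory"
        assert at0[0].label == "inhibitory"

    def test_unmatched_latency_is_excitatory(self):
        m60 = [make_cluster(0, 1.9, jitter=0.1)]
        at0 = [make_cluster(0, 4.6, jitter=0.1)]
        assert label_clusters_by_holding(m60, at0)[0].label == "excitatory"

    def test_empty_0mv_list_all_excitatory_flagged(self):
        m60 = [make_cluster(0, 1.9), make_cluster(1, 4.5)]
        out = label_clusters_by_holding(m60, [])
        assert all(c.label == "excitatory" for c in out)
        assert all("no-0mV-data" in c.flags for c in out)

    def test_synthetic_cells_label_recovery(self):
        """Full pipeline on generator sweeps at both holdings: labels match
        generator ground truth."""
        from mocsyn.events import detect_events, events_to_frame
        from mocsyn.synth import (
            EXCITATORY_CLUSTER,
            INHIBITORY_CLUSTER,
            SweepGenSpec,
            generate_sweep_set,
        )

        def cell(holding, seed):
            spec = SweepGenSpec(
                n_sweeps=60, duration=40.0, stim_times=(10.0,),
                clusters=(EXCITATORY_CLUSTER, INHIBITORY_CLUSTER),
                holding_potential=holding, noise_rms=1.0, seed=seed,
            )
            ss, _ = generate_sweep_set(spec)
            df = events_to_frame(detect_events(ss, threshold_multiple=3.0))
            fm = build_feature_matrix(df)
            k, _ = gap_select_k(fm, kmax=4, B=40, nstart=10, seed=seed)
            labels, _ = kmeans_cluster(fm, k, seed=seed)
            kept = df.loc[fm.event_index]
            return summarize_clusters(kept, labels, n_sweeps=60)

        m60 = cell(-60.0, 101)
        at0 = cell(0.0, 102)
        out = label_clusters_by_holding(m60, at0)
        # earliest cluster excitatory, a later one inhibitory
        assert out[0].label == "excitatory"
        assert any(c.label == "inhibitory" for c in out[1:])
        delta = ei_latency_difference(out)
        assert delta == pytest.approx(
            INHIBITORY_CLUSTER.mean_onset_latency
            - EXCITATORY_CLUSTER.mean_onset_latency,
            abs=0.5,
        )


class TestEILatencyDifference:
    def test_positive_when_excitation_first(self):
        cl = [make_cluster(0, 1.9, label="excitatory"),
              make_cluster(1, 4.7, label="inhibitory")]
        assert ei_latency_difference(cl) == pytest.approx(2.8)

    def test_zero_when_simultaneous(self):
        cl = [make_cluster(0, 3.0, label="excitatory"),
              make_cluster(1, 3.0, label="inhibitory")]
        assert ei_latency_difference(cl) == 0.0

    def test_negative_when_inhibition_first(self):
        cl = [make_cluster(0, 1.0, label="inhibitory"),
              make_cluster(1, 5.4, label="excitatory")]
        assert ei_latency_difference(cl) == pytest.approx(-4.4)

    def test_none_when_class_missing(self):
        assert ei_latency_difference([make_cluster(0, 2.0, label="excitatory")]) is None


class TestFeatureMatrix:
    def test_null_features_dropped_and_standardized(self):
        df = events_frame([1.0, 2.0, 3.0, 4.0])
        df.loc[1, "decay_tau"] = np.nan
        fm = build_feature_matrix(df)
        assert fm.n_events == 3
        np.testing.assert_allclose(fm.values.mean(axis=0), 0.0, atol=1e-12)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            build_feature_matrix(events_frame([1.0]))

    def test_amplitude_flag(self):
        df = events_frame([1.0, 2.0, 3.0])
        fm = build_feature_matrix(df, include_amplitude=True)
        assert "amplitude" in fm.feature_names
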
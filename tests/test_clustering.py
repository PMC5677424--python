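"""Competitive learning and the K-means/FCM/OSORT baselines."""

import numpy as np
import pytest

import spikecl as scl
from spikecl.clustering import SHIFT_SCALE_BITS, _shift_update


def make_codebook(centers, eta=2.0 ** -5, **kw):
    cb = scl.Codebook(eta=eta, eta_exponent=None, **kw)
    cb.centers[0] = np.asarray(centers, dtype=float)
    cb.update_count[0] = 0
    return cb


class TestInitCodebook:
    def test_k_equals_n_is_permutation_of_data(self):
        x = np.arange(10, dtype=float).reshape(5, 2)
        cb = scl.init_codebook({0: x}, k=5, seed=0)
        got = {tuple(r) for r in cb.centers[0]}
        assert got == {tuple(r) for r in x}

    def test_seed_determinism(self):
        x = np.random.default_rng(0).normal(size=(50, 2))
        a = scl.init_codebook({0: x}, k=3, seed=9)
        b = scl.init_codebook({0: x}, k=3, seed=9)
        np.testing.assert_array_equal(a.centers[0], b.centers[0])

    def test_selection_frequencies_uniform(self):
        x = np.arange(20, dtype=float).reshape(10, 2)
        counts = np.zeros(10)
        draws = 10_000
        for s in range(draws):
            cb = scl.init_codebook({0: x}, k=2, seed=s)
            for c in cb.centers[0]:
                counts[int(c[0]) // 2] += 1
        p = 2 / 10
        sd = np.sqrt(draws * p * (1 - p))
        assert np.all(np.abs(counts - draws * p) < 3 * sd)

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError, match="fewer than K"):
            scl.init_codebook({0: np.zeros((2, 2))}, k=3)


class TestFindWinner:
    def test_direct_distance(self):
        cb = make_codebook([(0, 0), (10, 10)])
        k, d = scl.find_winner(cb, 0, np.array([1.0, 1.0]))
        assert k == 0 and d == pytest.approx(2.0)

    def test_tie_breaks_to_smallest_index(self):
        cb = make_codebook([(0, 0), (10, 10)])
        k, _ = scl.find_winner(cb, 0, np.array([5.0, 5.0]))
        assert k == 0

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        centers = rng.normal(size=(8, 2))
        cb = make_codebook(centers)
        for x in rng.normal(size=(1000, 2)):
            k, d = scl.find_winner(cb, 0, x)
            dists = [((c - x) ** 2).sum() for c in centers]
            assert k == int(np.argmin(dists))
            assert d == pytest.approx(min(dists))

    def test_dimension_mismatch_rejected(self):
        cb = make_codebook([(0, 0)])
        with pytest.raises(ValueError, match="dimension"):
            scl.find_winner(cb, 0, np.array([1.0, 2.0, 3.0]))


class TestUpdateWinner:
    def test_hardware_eta_step(self):
        cb = make_codebook([(0.0, 0.0)])
        new = scl.update_winner(cb, 0, 0, np.array([1.0, 1.0]))
        np.testing.assert_allclose(new, [0.03125, 0.03125])

    def test_nonwinners_unchanged(self):
        cb = make_codebook([(0, 0), (5, 5), (9, 9)])
        before = cb.centers[0].copy()
        scl.update_winner(cb, 0, 1, np.array([4.0, 4.0]))
        np.testing.assert_array_equal(cb.centers[0][[0, 2]],
                                      before[[0, 2]])

    def test_eta_one_jumps_to_input(self):
        cb = make_codebook([(3.0, -2.0)], eta=1.0)
        new = scl.update_winner(cb, 0, 0, np.array([7.0, 7.0]))
        np.testing.assert_array_equal(new, [7.0, 7.0])

    def test_contraction_identity(self):
        # ||C' - X||^2 == (1 - eta)^2 ||C - X||^2, exactly per update
        rng = np.random.default_rng(2)
        cb = make_codebook(rng.normal(size=(3, 2)))
        eta = cb.eta
        for x in rng.normal(size=(200, 2)):
            k, _ = scl.find_winner(cb, 0, x)
            before = cb.centers[0][k].copy()
            after = scl.update_winner(cb, 0, k, x)
            lhs = ((after - x) ** 2).sum()
            rhs = (1 - eta) ** 2 * ((before - x) ** 2).sum()
            assert lhs == pytest.approx(rhs, abs=1e-12)


class TestShiftUpdate:
    def test_exact_when_representable(self):
        # operands on the 2^-15 grid with differences divisible by 2^5
        c = np.array([0.25, -0.5])
        x = c + np.array([32, -64]) * 2.0 ** -SHIFT_SCALE_BITS * 4
        got = _shift_update(c, x, 5)
        expected = c + 2.0 ** -5 * (x - c)
        np.testing.assert_array_equal(got, expected)

    def test_within_one_lsb_of_float_update(self):
        rng = np.random.default_rng(3)
        for _ in range(10_000):
            c = rng.uniform(-1, 1, size=2)
            x = rng.uniform(-1, 1, size=2)
            got = _shift_update(c, x, 5)
            scale = 2.0 ** SHIFT_SCALE_BITS
            cq, xq = np.round(c * scale) / scale, np.round(x * scale) / scale
            expected = cq + 2.0 ** -5 * (xq - cq)
            assert np.all(np.abs(got - expected) < 2.0 ** -SHIFT_SCALE_BITS)

    def test_shift_mode_codebook_trains(self):
        x, y = scl.feature_cloud(200, [(0, 0), (1, 1)], 0.05, seed=4)
        cb = scl.init_codebook({0: x}, k=2, seed=0, shift_mode=True)
        scl.cl_train({0: x}, cb, scl.TrainingConfig(k=2, shift_mode=True))
        pred = scl.cl_classify_batch(cb, 0, x)
        assert scl.csr(pred, y).csr > 0.99


class TestCLTrain:
    def test_closed_form_geometric_convergence(self):
        eta = 2.0 ** -5
        c0 = np.array([0.0, 0.0])
        x = np.array([1.0, 1.0])
        cb = make_codebook([c0])
        scl.cl_train(np.tile(x, (300, 1)), cb)
        expected = x - (1 - eta) ** 300 * (x - c0)
        np.testing.assert_allclose(cb.centers[0][0], expected, atol=1e-9)

    def test_empty_stream_rejected(self):
        cb = make_codebook([(0, 0)])
        with pytest.raises(ValueError, match="empty"):
            scl.cl_train(np.empty((0, 2)), cb)

    def test_winner_take_all_one_center_changes_per_presentation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(500, 2))
        cb = scl.init_codebook({0: x}, k=4, seed=0)
        prev = cb.centers[0].copy()
        for xi in x:
            k, _ = scl.find_winner(cb, 0, xi)
            scl.update_winner(cb, 0, k, xi)
            changed = np.any(cb.centers[0] != prev, axis=1)
            assert changed.sum() == 1
            prev = cb.centers[0].copy()

    def test_distance_counter_equals_k_times_presentations(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(321, 2))
        for k in (2, 5):
            cb = scl.init_codebook({0: x}, k=k, seed=0)
            scl.cl_train({0: x}, cb, scl.TrainingConfig(k=k, epochs=2))
            assert cb.distance_evals == k * 321 * 2
            assert cb.update_count[0] == 321 * 2

    def test_centers_stay_in_convex_hull(self):
        x, _ = scl.feature_cloud(300, [(0, 0), (4, 4)], 1.0, seed=7)
        cb = scl.init_codebook({0: x}, k=2, seed=1)
        scl.cl_train({0: x}, cb)
        lo, hi = x.min(axis=0), x.max(axis=0)
        assert np.all(cb.centers[0] >= lo - 1e-12)
        assert np.all(cb.centers[0] <= hi + 1e-12)

    def test_two_cluster_parameter_recovery(self):
        x, _ = scl.feature_cloud(1000, [(0, 0), (10, 10)], 0.5, seed=8)
        cb = scl.init_codebook({0: x}, k=2, seed=2)
        scl.cl_train({0: x}, cb)
        centers = cb.centers[0][np.argsort(cb.centers[0][:, 0])]
        assert np.linalg.norm(centers[0] - [0, 0]) < 0.3
        assert np.linalg.norm(centers[1] - [10, 10]) < 0.3


class TestCLClassify:
    def test_pure_and_idempotent(self):
        cb = make_codebook([(0, 0), (10, 10)])
        before = {q: c.copy() for q, c in cb.centers.items()}
        x = np.array([9.0, 9.0])
        assert scl.cl_classify(cb, 0, x) == scl.cl_classify(cb, 0, x) == 1
        np.testing.assert_array_equal(cb.centers[0], before[0])

    def test_center_classifies_to_itself(self):
        cb = make_codebook([(0, 0), (10, 10)])
        assert scl.cl_classify(cb, 0, np.array([10.0, 10.0])) == 1

    def test_batch_matches_scalar_path(self):
        rng = np.random.default_rng(9)
        cb = make_codebook(rng.normal(size=(4, 2)))
        x = rng.normal(size=(100, 2))
        batch = scl.cl_classify_batch(cb, 0, x)
        scalar = [scl.cl_classify(cb, 0, xi) for xi in x]
        np.testing.assert_array_equal(batch, scalar)


class TestAdaptiveK:
    def test_infinite_threshold_keeps_k_two(self):
        x, _ = scl.feature_cloud(200, [(0, 0), (10, 10), (20, 0)], 1.0,
                                 seed=10)
        cfg = scl.TrainingConfig(adaptive=True,
                                 new_cluster_threshold=np.inf)
        cb = scl.cl_train_adaptive({0: x}, cfg)
        assert cb.k(0) == 2

    def test_three_separated_clusters_found(self):
        x, y = scl.feature_cloud(300, [(0, 0), (20, 20), (0, 40)], 1.0,
                                 seed=11)
        cfg = scl.TrainingConfig(adaptive=True, seed=1)
        cb = scl.cl_train_adaptive({0: x}, cfg)
        assert cb.k(0) == 3
        pred = scl.cl_classify_batch(cb, 0, x)
        assert scl.csr(pred, y).csr > 0.98

    def test_growth_capped_at_kmax(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 100, size=(500, 2))
        cfg = scl.TrainingConfig(adaptive=True, new_cluster_threshold=1.0,
                                 k_max=4)
        cb = scl.cl_train_adaptive({0: x}, cfg)
        assert cb.k(0) == 4

    def test_repeated_points_no_growth_beyond_distinct_values(self):
        x = np.tile(np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 0.0]]),
                    (30, 1))
        cfg = scl.TrainingConfig(adaptive=True,
                                 new_cluster_threshold=1e-9, k_max=8)
        cb = scl.cl_train_adaptive({0: x}, cfg)
        # random init may duplicate a repeated value, but no center value
        # beyond the three distinct data points may ever appear
        distinct = np.unique(cb.centers[0], axis=0)
        assert len(distinct) == 3
        assert cb.k(0) <= 4  # 2 initial + at most the unseen values


class TestKMeans:
    def test_k1_center_is_mean(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(100, 2))
        centers, labels, _ = scl.kmeans_train(x, 1, seed=0)
        np.testing.assert_allclose(centers[0], x.mean(axis=0))
        assert set(labels) == {0}

    def test_recovers_separated_means(self):
        x, _ = scl.feature_cloud(500, [(0, 0), (10, 10)], 0.5, seed=14)
        centers, _, _ = scl.kmeans_train(x, 2, seed=0)
        centers = centers[np.argsort(centers[:, 0])]
        assert np.linalg.norm(centers[0] - [0, 0]) < 0.05
        assert np.linalg.norm(centers[1] - [10, 10]) < 0.05

    def test_sse_non_increasing(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=(400, 2))
        _, _, history = scl.kmeans_train(x, 4, seed=1)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_agrees_with_sklearn_on_separated_data(self):
        from sklearn.cluster import KMeans

        x, y = scl.feature_cloud(300, [(0, 0), (8, 8)], 1.0, seed=16)
        _, labels, _ = scl.kmeans_train(x, 2, seed=0)
        ref = KMeans(2, n_init=10, random_state=0).fit_predict(x)
        assert scl.csr(labels, ref).csr == 1.0


class TestFCM:
    def test_equidistant_point_memberships_half(self):
        x = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 0.0]] * 20)
        centers, u = scl.fcm_train(x, 2, seed=0)
        mid = np.all(x == [5.0, 0.0], axis=1)
        np.testing.assert_allclose(u[mid], 0.5, atol=0.02)

    def test_memberships_sum_to_one(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(200, 2))
        _, u = scl.fcm_train(x, 3, seed=1)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)

    def test_hardened_labels_match_kmeans_on_separated_data(self):
        x, _ = scl.feature_cloud(400, [(0, 0), (10, 10)], 0.8, seed=18)
        _, u = scl.fcm_train(x, 2, seed=0)
        _, klabels, _ = scl.kmeans_train(x, 2, seed=0)
        assert scl.csr(u.argmax(axis=1), klabels).csr == 1.0


class TestOSORT:
    def test_infinite_threshold_single_cluster_mean(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=(100, 8))
        means, labels = scl.osort_train(x, 1e12)
        assert len(means) == 1 and set(labels) == {0}
        np.testing.assert_allclose(means[0], x.mean(axis=0))

    def test_tiny_threshold_separates_distinct_waveforms(self):
        x = np.tile(np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]), (25, 1))
        means, labels = scl.osort_train(x, 1e-9)
        assert len(means) == 2
        assert scl.csr(labels, np.tile([0, 1], 25)).csr == 1.0

    def test_sorts_waveforms_at_8db(self, templates):
        spec = scl.SimulationSpec(snr_db=8.0, duration_s=10.0, seed=20)
        rec, truth = scl.generate_recording(spec, templates)
        spikes = scl.process_multichannel(rec)
        tdf = truth.for_channel(0)
        pairs, _, _ = scl.match_detections(
            [s.peak_index for s in spikes],
            tdf["sample_index"].to_numpy(), 32)
        wf = np.vstack([spikes[i].waveform for i, _ in pairs])
        true = tdf["label"].to_numpy()[[j for _, j in pairs]]
        from spikecl.evaluation import osort_threshold

        _, pred = scl.osort_train(wf, osort_threshold(wf))
        assert scl.csr(pred, true).csr >= 0.95
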
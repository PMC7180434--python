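"""k-means center training, kernel widths, NLMS weight training, threshold
selection and classification of the RBF network."""

import numpy as np
import pytest

from needleox import (
    RBFNetwork,
    TrainingConfig,
    kmeans_centers,
    metrics,
    confusion,
    nlms_train,
    select_threshold,
    set_widths,
    train_network,
)
from needleox.evaluation import sweep_table
from needleox.exceptions import (
    CompatibilityError,
    ConfigurationError,
    NotTrainedError,
    SelectionError,
)
from needleox.rbfnn import DEFAULT_GRID, labels_to_targets
from needleox.synthetic import generate_dataset, vessel_labels


def two_blobs(n_per=40, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, 2))
    b = rng.normal(sep, 1.0, size=(n_per, 2))
    X = np.vstack([a, b])
    y = ["other"] * n_per + ["vessel"] * n_per
    return X, y, a, b


class TestKMeans:
    def test_k_equals_n_reaches_zero_sse(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 5.0], [9.0, 2.0]])
        centers, history = kmeans_centers(X, 4, seed=1, return_history=True)
        assert history[-1] == pytest.approx(0.0, abs=1e-24)
        # centers are the points, up to permutation
        matched = {tuple(c) for c in np.round(centers, 12)}
        assert matched == {tuple(r) for r in X}

    def test_two_blobs_centers_near_blob_means(self):
        X, _, a, b = two_blobs(n_per=200, seed=2)
        centers = kmeans_centers(X, 2, seed=2)
        tol = 3.0 / np.sqrt(200)  # 3 sigma / sqrt(n) per blob
        for mean in (a.mean(axis=0), b.mean(axis=0)):
            assert min(np.linalg.norm(centers - mean, axis=1)) < tol

    def test_deterministic_under_seed(self):
        X = np.random.default_rng(5).normal(size=(50, 2))
        c1 = kmeans_centers(X, 8, seed=11)
        c2 = kmeans_centers(X, 8, seed=11)
        assert np.array_equal(c1, c2)

    def test_sse_history_non_increasing(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 3))
        _, history = kmeans_centers(X, 10, seed=9, return_history=True)
        assert all(b <= a * (1 + 1e-12) for a, b in zip(history, history[1:]))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ConfigurationError):
            kmeans_centers(np.zeros((3, 2)), 4)

    def test_agrees_with_sklearn_on_separated_blobs(self):
        # independent oracle: scikit-learn's k-means on an easy problem
        # reaches the same partition cost
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        X, _, _, _ = two_blobs(n_per=100, seed=4)
        ours, history = kmeans_centers(X, 2, seed=4, return_history=True)
        ref = sklearn_cluster.KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        assert history[-1] == pytest.approx(ref.inertia_, rel=1e-6)

    def test_duplicate_points_do_not_crash(self):
        X = np.tile(np.array([[1.0, 2.0], [3.0, 4.0]]), (5, 1))
        centers = kmeans_centers(X, 4, seed=0)
        assert centers.shape == (4, 2)


class TestWidths:
    def test_two_centers_on_a_line(self):
        widths = set_widths(np.array([[0.0], [1.0]]), p=1)
        assert np.allclose(widths, [1.0, 1.0])

    def test_uniform_grid_gives_equal_widths(self):
        grid = np.array([[float(i), float(j)] for i in range(3) for j in range(3)])
        widths = set_widths(grid, p=2)
        assert np.allclose(widths, widths[0])

    def test_single_center_fallback(self):
        assert set_widths(np.array([[3.0, 4.0]])) == pytest.approx([1.0])

    def test_duplicate_centers_get_positive_widths(self):
        widths = set_widths(np.array([[0.0], [0.0], [5.0]]), p=1)
        assert (widths > 0).all()


class TestForward:
    def make_net(self, centers, widths, weights, bias=0.0):
        return RBFNetwork(
            centers=np.asarray(centers, dtype=float),
            widths=np.asarray(widths, dtype=float),
            weights=np.asarray(weights, dtype=float),
            bias=bias,
        )

    def test_unit_activation_at_center(self):
        net = self.make_net([[1.0, 2.0], [5.0, 5.0]], [1.0, 1.0], [0.7, 0.0])
        assert net.forward(np.array([1.0, 2.0]))[0] == pytest.approx(0.7)

    def test_bias_only_network_is_constant(self):
        net = self.make_net([[0.0], [1.0]], [1.0, 1.0], [0.0, 0.0], bias=0.3)
        x = np.array([[0.2], [7.0], [-3.0]])
        assert np.allclose(net.forward(x), 0.3)

    def test_hand_computed_two_center_output(self):
        net = self.make_net([[0.0], [2.0]], [1.0, 2.0], [0.5, -0.25], bias=0.1)
        x = 1.0
        expected = (
            0.1
            + 0.5 * np.exp(-(x - 0.0) ** 2 / (2 * 1.0**2))
            - 0.25 * np.exp(-(x - 2.0) ** 2 / (2 * 2.0**2))
        )
        assert net.forward(np.array([x]))[0] == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch(self):
        net = self.make_net([[0.0, 0.0]], [1.0], [1.0])
        with pytest.raises(CompatibilityError):
            net.forward(np.array([[1.0, 2.0, 3.0]]))

    def test_untrained_network_refuses_to_predict(self):
        net = RBFNetwork(centers=np.zeros((1, 2)), widths=np.ones(1))
        with pytest.raises(NotTrainedError):
            net.forward(np.zeros((1, 2)))


class TestNLMS:
    def test_zero_error_leaves_weights_unchanged(self):
        net = RBFNetwork(centers=np.array([[0.0], [1.0]]), widths=np.ones(2),
                         weights=np.array([0.4, 0.2]), bias=0.05)
        X = np.array([[0.3], [0.8]])
        targets = net.forward(X).copy()  # already fit exactly
        w0, b0 = net.weights.copy(), net.bias
        nlms_train(net, X, targets, TrainingConfig(n_centers=2, epochs=3, seed=1))
        assert np.allclose(net.weights, w0) and net.bias == pytest.approx(b0)

    def test_full_step_fits_single_sample(self):
        # mu = 1, eps -> 0: one NLMS update makes the output hit the target
        net = RBFNetwork(centers=np.array([[0.0]]), widths=np.ones(1),
                         weights=np.zeros(1), bias=0.0)
        cfg = TrainingConfig(n_centers=1, nlms_step=1.0, nlms_reg=1e-15,
                             epochs=1, seed=0)
        X, t = np.array([[0.5]]), np.array([0.8])
        nlms_train(net, X, t, cfg)
        assert net.forward(X)[0] == pytest.approx(0.8, abs=1e-10)

    def test_aposteriori_error_never_exceeds_apriori(self):
        # single-update contraction property for mu in (0, 1]
        rng = np.random.default_rng(12)
        for mu in (0.25, 0.5, 1.0):
            phi = np.append(rng.normal(size=4), 1.0)  # activations + bias
            w = rng.normal(size=5)
            t = rng.normal()
            e_prior = t - phi @ w
            w_new = w + mu * e_prior * phi / (1e-6 + phi @ phi)
            e_post = t - phi @ w_new
            assert abs(e_post) <= abs(e_prior) + 1e-15

    def test_separable_blobs_reach_perfect_training_f(self):
        X, y, _, _ = two_blobs(n_per=30, seed=7)
        cfg = TrainingConfig(n_centers=8, epochs=50, seed=7)
        net = train_network(X, y, cfg)
        pred, _ = net.classify(X)
        m = metrics(confusion(y, list(pred)))
        assert m.f_measure == 1.0

    def test_step_size_outside_stable_range_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainingConfig(nlms_step=2.5)
        with pytest.raises(ConfigurationError):
            TrainingConfig(nlms_step=0.0)

    def test_interpolation_on_few_distinct_points(self):
        # K = n centers with tight kernels: NLMS driven to convergence
        # interpolates the training targets
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, size=(15, 2))
        t = rng.uniform(0, 1, size=15)
        net = RBFNetwork(centers=X.copy(), widths=np.full(15, 0.05))
        cfg = TrainingConfig(n_centers=15, nlms_step=0.9, epochs=3000, seed=3)
        nlms_train(net, X, t, cfg)
        assert np.abs(net.forward(X) - t).max() < 1e-3


class TestThresholdSelection:
    def test_tie_break_toward_half_on_separated_outputs(self):
        # outputs 0.4 / 0.6 by class: thresholds 0.4, 0.5, 0.6 all perfect
        net = RBFNetwork(centers=np.array([[0.0], [1.0]]), widths=np.ones(2),
                         weights=np.zeros(2), bias=0.0)
        X = np.array([[0.0]] * 3 + [[1.0]] * 3)
        y = ["other"] * 3 + ["vessel"] * 3
        cfg = TrainingConfig(n_centers=2, epochs=300, seed=0)
        nlms_train(net, X, labels_to_targets(y), cfg)
        assert select_threshold(net, X, y, DEFAULT_GRID) == 0.5

    def test_degenerate_all_positive_returns_half(self):
        net = RBFNetwork(centers=np.array([[0.0]]), widths=np.ones(1),
                         weights=np.zeros(1), bias=1.0)  # constant output 1.0
        X = np.zeros((4, 1))
        y = ["vessel"] * 4
        assert select_threshold(net, X, y, DEFAULT_GRID) == 0.5

    def test_all_undefined_raises(self):
        net = RBFNetwork(centers=np.array([[0.0]]), widths=np.ones(1),
                         weights=np.zeros(1), bias=0.0)  # constant output 0.0
        X = np.zeros((4, 1))
        y = ["other"] * 4  # no true positives, no predicted positives
        with pytest.raises(SelectionError):
            select_threshold(net, X, y, DEFAULT_GRID)

    def test_matches_exhaustive_grid_argmax_on_default_dataset(self):
        train, _ = generate_dataset(n_train=300, n_test=100, seed=0)
        y = vessel_labels(train.labels)
        net = train_network(train.features, y, TrainingConfig(seed=0))
        table = sweep_table(net.forward(train.features), y, DEFAULT_GRID)
        table = table.dropna(subset=["f_measure"])
        best_f = table["f_measure"].max()
        ties = table[table["f_measure"] == best_f]["threshold"].to_numpy()
        expected = min(ties, key=lambda t: (abs(t - 0.5), t))
        assert net.threshold == expected


@pytest.fixture(scope="module")
def trained():
    X, y, _, _ = two_blobs(n_per=25, seed=1)
    return X, y, train_network(X, y, TrainingConfig(n_centers=6, seed=1))


class TestClassify:
    def test_score_at_threshold_is_other(self, trained):
        _, _, net = trained
        # boundary rule is strict: vessel only for score strictly above
        x_query = net.centers[0] * net.norm_scale + net.norm_mean
        score = net.forward(x_query[None, :])[0]
        net2 = RBFNetwork.from_dict(net.to_dict())
        net2.threshold = float(score)
        label, _ = net2.classify_one(x_query)
        assert label == "other"

    def test_batch_equals_per_sample(self, trained):
        X, _, net = trained
        batch_labels, batch_scores = net.classify(X)
        singles = [net.classify_one(x) for x in X]
        assert [s[0] for s in singles] == list(batch_labels)
        assert np.allclose([s[1] for s in singles], batch_scores)

    def test_high_score_is_vessel(self, trained):
        _, _, net = trained
        net2 = RBFNetwork.from_dict(net.to_dict())
        net2.weights = np.zeros_like(net2.weights)
        net2.bias = 0.9
        net2.threshold = 0.5
        label, score = net2.classify_one(np.zeros(2))
        assert label == "vessel" and score == pytest.approx(0.9)


class TestSerialization:
    def test_identical_seed_and_config_bit_identical_json(self):
        X, y, _, _ = two_blobs(n_per=20, seed=6)
        cfg = TrainingConfig(n_centers=5, epochs=20, seed=42)
        j1 = train_network(X, y, cfg).to_json()
        j2 = train_network(X, y, cfg).to_json()
        assert j1 == j2

    def test_round_trip_preserves_predictions(self):
        X, y, _, _ = two_blobs(n_per=20, seed=8)
        net = train_network(X, y, TrainingConfig(n_centers=5, epochs=20, seed=8))
        clone = RBFNetwork.from_json(net.to_json())
        l1, s1 = net.classify(X)
        l2, s2 = clone.classify(X)
        assert list(l1) == list(l2)
        assert np.array_equal(s1, s2)

    def test_n_centers_larger_than_dataset_rejected(self):
        X, y, _, _ = two_blobs(n_per=4, seed=0)
        with pytest.raises(ConfigurationError):
            train_network(X, y, TrainingConfig(n_centers=100))
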
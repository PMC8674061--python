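"""Classifiers: class coding, splitting, gradient correctness, LM step,
memorization, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from eoghci.features import FEATURE_COLUMNS, FeatureVector
from eoghci.networks import (CODEBOOK, NetworkConfig, NetworkError,
                             TrainedNetwork, decode_output, encode_labels,
                             ernn_pattern_gradients, lm_step, predict,
                             split_dataset, train_dtdnn, train_ernn)
from eoghci.networks import _init_weights, frame_to_xy
from eoghci.synthetic import TASKS, Task


def _blob_dataset(n_per_class=4, sd=0.02, seed=0):
    """Separable toy set: 11 random centroids in [0,1]^16 with small spread."""
    rng = np.random.default_rng(seed)
    centroids = rng.uniform(0.1, 0.9, size=(11, 16))
    X, Y, labels = [], [], []
    for ti, task in enumerate(TASKS):
        for _ in range(n_per_class):
            X.append(np.clip(centroids[ti] + rng.normal(0, sd, 16), 0, 1))
            Y.append(encode_labels(task))
            labels.append(task)
    return np.array(X), np.array(Y), labels


class TestClassCoding:
    def test_binary_codes(self):
        assert encode_labels(TASKS[0]).tolist() == [0, 0, 0, 0]
        assert encode_labels(TASKS[10]).tolist() == [1, 0, 1, 0]

    def test_all_codes_distinct_and_invertible(self):
        assert len({tuple(row) for row in CODEBOOK}) == 11
        for task in TASKS:
            assert decode_output(encode_labels(task)) == task

    def test_nearest_code_decoding(self):
        assert decode_output([0.9, 0.1, 0.9, 0.1]) == TASKS[10]

    def test_tie_breaks_to_lowest_index(self):
        assert decode_output([0.5, 0.5, 0.5, 0.5]) == TASKS[0]


class TestSplit:
    def _frame(self, n_per_task=10):
        rows = []
        for task in TASKS:
            for i in range(1, n_per_task + 1):
                row = {"subject_id": "S1", "task": task.value,
                       "trial_index": i}
                row.update({c: 0.0 for c in FEATURE_COLUMNS})
                rows.append(row)
        return pd.DataFrame(rows)

    def test_75_25_split_is_88_22(self):
        train, test = split_dataset(self._frame(), 0.75, seed=0)
        assert len(train) == 88 and len(test) == 22
        assert (train.groupby("task").size() == 8).all()
        assert (test.groupby("task").size() == 2).all()

    def test_extreme_fraction_keeps_one_test_trial(self):
        train, test = split_dataset(self._frame(), 0.999, seed=0)
        assert (train.groupby("task").size() == 9).all()
        assert (test.groupby("task").size() == 1).all()

    def test_fraction_bounds_rejected(self):
        for frac in (0.0, 1.0, 1.5):
            with pytest.raises(NetworkError):
                split_dataset(self._frame(), frac, seed=0)

    def test_same_seed_same_split(self):
        t1, _ = split_dataset(self._frame(), 0.75, seed=5)
        t2, _ = split_dataset(self._frame(), 0.75, seed=5)
        assert t1.index.tolist() == t2.index.tolist()

    def test_non_stratifiable_rejected(self):
        df = self._frame().iloc[:11]  # one trial per task
        with pytest.raises(NetworkError):
            split_dataset(df, 0.75, seed=0)


class TestGradients:
    def test_ernn_gradients_match_finite_differences(self):
        cfg = NetworkConfig(n_input=5, n_hidden=3, n_output=4, seed=2)
        rng = np.random.default_rng(2)
        w = _init_weights(cfg, rng, {
            "W_in": (3, 5), "W_ctx": (3, 3), "b_h": (3,),
            "W_out": (4, 3), "b_o": (4,),
        })
        x = rng.uniform(0, 1, 5)
        c = rng.uniform(0, 1, 3)
        t = np.array([1.0, 0, 1, 0])
        _, grads = ernn_pattern_gradients(w, x, c, t)
        eps = 1e-5
        for name in w:
            g_fd = np.zeros_like(w[name])
            it = np.nditer(w[name], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = w[name][idx]
                w[name][idx] = orig + eps
                lp, _ = ernn_pattern_gradients(w, x, c, t)
                w[name][idx] = orig - eps
                lm, _ = ernn_pattern_gradients(w, x, c, t)
                w[name][idx] = orig
                g_fd[idx] = (lp - lm) / (2 * eps)
            denom = np.maximum(np.abs(g_fd), 1e-8)
            assert np.max(np.abs(grads[name] - g_fd) / denom) < 1e-4

    def test_lm_step_with_vanishing_damping_is_gauss_newton(self):
        """For a linear model the damped step with lambda -> 0 lands on the
        least-squares solution computed independently by lstsq."""
        rng = np.random.default_rng(0)
        A = rng.normal(size=(30, 5))
        b = rng.normal(size=30)
        theta0 = rng.normal(size=5)
        r = A @ theta0 - b
        delta = lm_step(A, r, 1e-12)
        theta1 = theta0 - delta
        theta_star = np.linalg.lstsq(A, b, rcond=None)[0]
        np.testing.assert_allclose(theta1, theta_star, rtol=1e-6, atol=1e-8)


class TestTraining:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        X, Y, _ = _blob_dataset(n_per_class=1)
        cfg = NetworkConfig(learning_rate=0.0, max_iterations=5, seed=0)
        model = train_ernn(X, Y, cfg)
        fresh = _init_weights(cfg, np.random.default_rng(0), {
            "W_in": (8, 16), "W_ctx": (8, 8), "b_h": (8,),
            "W_out": (4, 8), "b_o": (4,),
        })
        for name, v in fresh.items():
            np.testing.assert_array_equal(model.weights[name], v)

    def test_single_pattern_memorization_both_architectures(self):
        X, Y, _ = _blob_dataset(n_per_class=1)
        X, Y = X[:1], Y[:1]
        m1 = train_ernn(X, Y, NetworkConfig(seed=0))
        assert m1.final_error < 0.001
        m2 = train_dtdnn(X, Y, NetworkConfig(architecture="dtdnn", seed=0))
        assert m2.final_error < 0.001

    def test_blob_dataset_memorized(self):
        X, Y, labels = _blob_dataset()
        m = train_ernn(X, Y, NetworkConfig(seed=1))
        preds = m.predict_batch(X)
        assert np.mean([p == t for p, t in zip(preds, labels)]) == 1.0

    def test_dtdnn_zero_delays_is_order_independent(self):
        X, Y, labels = _blob_dataset()
        cfg = NetworkConfig(architecture="dtdnn", seed=1,
                            delays_input=(0,), delays_hidden=(0,),
                            dtdnn_eval="sequential")
        m = train_dtdnn(X, Y, cfg)
        perm = np.random.default_rng(0).permutation(len(X))
        preds = m.predict_batch(X)
        preds_perm = m.predict_batch(X[perm])
        assert [preds[i] for i in perm] == preds_perm

    def test_fixed_seed_serialization_identical(self):
        X, Y, _ = _blob_dataset(n_per_class=2)
        cfg = NetworkConfig(seed=7, max_iterations=20)
        a = train_ernn(X, Y, cfg).to_json()
        b = train_ernn(X, Y, cfg).to_json()
        assert a == b
        model = TrainedNetwork.from_json(a)
        np.testing.assert_array_equal(
            model.weights["W_in"], train_ernn(X, Y, cfg).weights["W_in"])


class TestPredict:
    def test_requires_normalized_vector(self):
        X, Y, _ = _blob_dataset(n_per_class=1)
        m = train_ernn(X, Y, NetworkConfig(seed=0, max_iterations=5))
        with pytest.raises(NetworkError):
            predict(m, FeatureVector("t", X[0], normalized=False))
        assert predict(m, FeatureVector("t", X[0], normalized=True)) in TASKS

    def test_repeated_calls_after_reset_agree(self):
        X, Y, _ = _blob_dataset(n_per_class=1)
        m = train_ernn(X, Y, NetworkConfig(seed=0, max_iterations=5))
        fv = FeatureVector("t", X[3], normalized=True)
        assert predict(m, fv) == predict(m, fv)

    def test_out_of_range_inputs_rejected(self):
        X, Y, _ = _blob_dataset(n_per_class=1)
        m = train_ernn(X, Y, NetworkConfig(seed=0, max_iterations=5))
        with pytest.raises(NetworkError):
            m.predict_batch(np.full((1, 16), 7.0))
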
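"""NIPALS PLS2 against closed forms and an independent SIMPLS oracle."""

import numpy as np
import pytest

from honeyprint import (
    classify,
    encode_labels,
    fit_gaussian_thresholds,
    fit_pls2,
    fit_plsda,
    load_model,
    predict_responses,
    save_model,
)
from honeyprint.preprocess import autoscale_apply, autoscale_fit

from _oracles import simpls_coefficients


def _random_two_class(seed):
    r = np.random.default_rng(seed)
    n = int(r.integers(8, 24))
    p = int(r.integers(3, 12))
    X = r.standard_normal((n, p))
    labels = r.choice(["a", "b"], n)
    while len(set(labels)) < 2:
        labels = r.choice(["a", "b"], n)
    return X, labels


class TestEncodeLabels:
    def test_year_example(self):
        d = encode_labels([2020, 2021, 2020])
        assert d.class_order == ("2020", "2021")
        assert np.array_equal(d.Y, [[1, 0], [0, 1], [1, 0]])

    def test_four_classes_row_sums(self):
        d = encode_labels(["linden", "acacia", "colza", "honeydew", "acacia"])
        assert d.class_order == ("acacia", "colza", "honeydew", "linden")
        assert d.Y.shape == (5, 4)
        assert np.array_equal(d.Y.sum(axis=1), np.ones(5))

    def test_missing_label_raises(self):
        with pytest.raises(ValueError, match="missing"):
            encode_labels(["a", None, "b"])

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="two distinct"):
            encode_labels(["a", "a", "a"])


class TestFitPls2:
    def test_univariate_single_component_equals_least_squares(self, rng):
        x = rng.standard_normal((15, 1))
        x -= x.mean(axis=0)
        y = 2.5 * x[:, 0] + rng.standard_normal(15) * 0.1
        y = (y - y.mean())[:, None]
        m = fit_pls2(x, y, 1)
        slope = float((x[:, 0] @ y[:, 0]) / (x[:, 0] @ x[:, 0]))
        assert np.abs(m.B[0, 0] - slope) < 1e-10

    @pytest.mark.parametrize("seed,classes", [(3, 2), (5, 4)])
    def test_full_rank_equals_ols(self, seed, classes):
        r = np.random.default_rng(seed)
        n, p = 9, 5
        X = r.standard_normal((n, p))
        labels = np.array([f"c{i % classes}" for i in range(n)])
        sc = autoscale_fit(X)
        Xs = autoscale_apply(sc, X)
        d = encode_labels(labels)
        Yc = d.Y - d.Y.mean(axis=0)
        m = fit_pls2(Xs, d, p)
        B_ols = np.linalg.lstsq(Xs, Yc, rcond=None)[0]
        assert np.abs(Xs @ m.B - Xs @ B_ols).max() < 1e-8

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_independent_simpls(self, seed):
        X, labels = _random_two_class(seed)
        sc = autoscale_fit(X)
        Xs = autoscale_apply(sc, X)
        d = encode_labels(labels)
        Yc = d.Y - d.Y.mean(axis=0)
        A = int(min(Xs.shape[0] - 1, Xs.shape[1], 4))
        m = fit_pls2(Xs, d, A)
        B_simpls = simpls_coefficients(Xs, Yc, A)
        assert np.abs(Xs @ m.B - Xs @ B_simpls).max() < 1e-8

    def test_model_invariants(self, rng):
        X = rng.standard_normal((20, 8))
        labels = np.array(["a", "b"] * 10)
        m = fit_plsda(X, labels, 4)
        # unit weights
        assert np.allclose(np.linalg.norm(m.W, axis=0), 1.0)
        # mutually orthogonal scores
        G = m.T.T @ m.T
        norms = np.sqrt(np.diag(G))
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * norms.max() ** 2
        # B reproduces training predictions through the component expansion
        Xs = autoscale_apply(m.scaling, X)
        yhat_components = m.T @ m.Q.T + m.y_means
        assert np.abs(predict_responses(m, X) - yhat_components).max() < 1e-8

    def test_row_permutation_equivariance(self, rng):
        X = rng.standard_normal((14, 6))
        labels = np.array(["a", "b"] * 7)
        perm = rng.permutation(14)
        sc = autoscale_fit(X)
        Xs = autoscale_apply(sc, X)
        d = encode_labels(labels)
        m1 = fit_pls2(Xs, d, 3)
        m2 = fit_pls2(Xs[perm], encode_labels(labels[perm]), 3)
        assert np.abs(m1.B - m2.B).max() < 1e-10
        assert np.abs(m1.T[perm] - m2.T).max() < 1e-10

    def test_duplicated_variable_does_not_hurt_training_fit(self, rng):
        X = rng.standard_normal((16, 5))
        labels = np.array(["a", "b"] * 8)
        d = encode_labels(labels)
        Xdup = np.hstack([X, X[:, :1]])

        def train_rmse(Xr):
            sc = autoscale_fit(Xr)
            Xs = autoscale_apply(sc, Xr)
            m = fit_pls2(Xs, d, 3)
            yhat = Xs @ m.B + m.y_means
            return float(np.sqrt(np.mean((yhat - d.Y) ** 2)))

        assert train_rmse(Xdup) <= train_rmse(X) + 1e-8

    def test_a_out_of_range(self, rng):
        X = rng.standard_normal((6, 4))
        with pytest.raises(ValueError, match="out of range"):
            fit_pls2(X, encode_labels(["a", "b"] * 3), 6)


class TestPredictAndClassify:
    def test_training_mean_row_predicts_class_means(self, rng):
        X = rng.standard_normal((12, 5))
        labels = np.array(["a", "b"] * 6)
        m = fit_plsda(X, labels, 3)
        yhat = predict_responses(m, X.mean(axis=0)[None, :])
        assert np.abs(yhat - m.y_means).max() < 1e-10

    def test_output_shape(self, rng):
        X = rng.standard_normal((12, 5))
        labels = np.array(["a", "b", "c"] * 4)
        m = fit_plsda(X, labels, 3)
        assert predict_responses(m, X).shape == (12, 3)

    def test_argmax_and_tie_break(self):
        order = ("a", "b")
        assert classify(np.array([[0.9, 0.1]]), order)[0] == "a"
        assert classify(np.array([[0.1, 0.9]]), order)[0] == "b"
        # exact tie goes to the lexicographically first class
        assert classify(np.array([[0.5, 0.5]]), order)[0] == "a"

    def test_gaussian_threshold_midpoint_for_equal_spread(self):
        # perfectly separated, equal within-group spread: threshold is midway
        yhat = np.array([
            [1.0, 0.0], [1.2, -0.2], [0.8, 0.2],
            [0.0, 1.0], [0.2, 0.8], [-0.2, 1.2],
        ])
        d = encode_labels(["a", "a", "a", "b", "b", "b"])
        th = fit_gaussian_thresholds(yhat, d)
        assert np.allclose(th.thresholds, [0.5, 0.5], atol=1e-12)
        pred = classify(yhat, d.class_order, rule="gaussian_threshold", thresholds=th)
        assert list(pred) == ["a", "a", "a", "b", "b", "b"]


def test_model_json_round_trip(tmp_path, rng):
    X = rng.standard_normal((10, 4))
    labels = np.array(["a", "b"] * 5)
    m = fit_plsda(X, labels, 2)
    path = tmp_path / "model.json"
    save_model(m, path)
    back = load_model(path)
    assert back.class_order == m.class_order
    assert np.array_equal(back.B, m.B)
    assert np.abs(predict_responses(back, X) - predict_responses(m, X)).max() == 0.0
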
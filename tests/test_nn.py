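"""KAN layers, attention stack, training loop: oracles and gradient checks."""

import numpy as np
import pytest
from scipy.interpolate import BSpline

from plasmokan.nn import (
    FeatureKAN,
    FullSpectrumKAN,
    KANLayer,
    MLPReference,
    TrainConfig,
    bce_loss,
    bspline_basis,
    build_feature_model,
    build_full_spectrum_model,
    build_mlp_reference,
    fit_spline_coefficients,
    load_model,
    make_knots,
    n_basis,
    positional_encoding,
    predict,
    save_model,
    subject_scores,
    train,
)
from plasmokan.nn.models import sigmoid


def _silu(x):
    return x / (1.0 + np.exp(-x))


class TestSplines:
    def test_basis_matches_scipy_design_matrix(self):
        k = 3
        t = make_knots(5, k)
        x = np.linspace(-3, 3, 101)
        ours = bspline_basis(x, t, k)
        ref = BSpline.design_matrix(np.clip(x, -3, 3 - 1e-12), t, k).toarray()
        assert np.abs(ours - ref).max() < 1e-10

    def test_partition_of_unity_inside_range(self):
        t = make_knots(7, 2, (-1.0, 2.0))
        x = np.linspace(-1, 2, 200)
        B = bspline_basis(x, t, 2)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_derivative_matches_finite_differences(self):
        k = 3
        t = make_knots(6, k)
        x = np.linspace(-2.9, 2.9, 77)
        _, dB = bspline_basis(x, t, k, with_deriv=True)
        num = (bspline_basis(x + 1e-6, t, k) - bspline_basis(x - 1e-6, t, k)) / 2e-6
        assert np.abs(dB - num).max() < 1e-6


class TestKANLayer:
    def test_zero_parameters_give_zero_output(self):
        rng = np.random.default_rng(0)
        layer = KANLayer(3, 2, rng)
        layer.coef.value[...] = 0.0
        layer.base_w.value[...] = 0.0
        out = layer.forward(rng.normal(size=(5, 3)))
        assert np.allclose(out, 0.0)

    def test_identity_edge_via_coefficient_solve(self):
        """One edge interpolating the identity reproduces that coordinate."""
        rng = np.random.default_rng(0)
        layer = KANLayer(3, 2, rng)
        layer.coef.value[...] = 0.0
        layer.base_w.value[...] = 0.0
        xs = np.linspace(-3, 3, 50)
        layer.coef.value[1, 2] = fit_spline_coefficients(xs, xs, layer.knots, layer.order)
        x = rng.uniform(-2.8, 2.8, size=(20, 3))
        out = layer.forward(x)
        assert np.allclose(out[:, 0], 0.0)
        assert np.abs(out[:, 1] - x[:, 2]).max() < 1e-8  # cubic spline is exact on a line

    def test_forward_equals_bruteforce_double_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d_in = int(rng.integers(1, 5))
            d_out = int(rng.integers(1, 5))
            layer = KANLayer(d_in, d_out, rng)
            x = rng.normal(size=(3, d_in))
            got = layer.forward(x)
            B = bspline_basis(x, layer.knots, layer.order)
            want = np.zeros((3, d_out))
            for b in range(3):
                for q in range(d_out):
                    for p in range(d_in):
                        want[b, q] += B[b, p] @ layer.coef.value[q, p]
                        want[b, q] += layer.base_w.value[q, p] * _silu(x[b, p])
            assert np.abs(got - want).max() < 1e-10

    def test_width_mismatch_and_nonfinite_rejected(self):
        layer = KANLayer(3, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            layer.forward(np.zeros((4, 5)))
        with pytest.raises(ValueError):
            layer.forward(np.array([[np.nan, 0.0, 1.0]]))


def _grad_check(model, X, y, tol=2e-3, n_per_param=10):
    """Compare analytic parameter gradients with central finite differences."""

    def loss():
        return bce_loss(y, sigmoid(model.forward(X)))

    probs = sigmoid(model.forward(X))
    model.zero_grad()
    model.backward((probs - y) / len(y))
    rng = np.random.default_rng(123)
    worst = 0.0
    for param in model.parameters():
        flat, gflat = param.value.ravel(), param.grad.ravel()
        for i in rng.choice(flat.size, size=min(n_per_param, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + 1e-6
            lp = loss()
            flat[i] = orig - 1e-6
            lm = loss()
            flat[i] = orig
            num = (lp - lm) / 2e-6
            worst = max(worst, abs(num - gflat[i]) / max(1e-6, abs(num) + abs(gflat[i])))
    assert worst < tol, f"worst relative gradient error {worst}"


class TestGradients:
    def test_feature_kan_gradients(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-2.5, 2.5, size=(8, 5))
        y = (rng.random(8) > 0.5).astype(float)
        _grad_check(FeatureKAN(5, hidden=(4, 3), seed=0), X, y)

    def test_mlp_gradients(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 5))
        y = (rng.random(8) > 0.5).astype(float)
        _grad_check(MLPReference(5, hidden=(6, 4), seed=0), X, y)

    def test_full_spectrum_gradients(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 7, 10))
        y = (rng.random(4) > 0.5).astype(float)
        _grad_check(
            FullSpectrumKAN(10, d_model=8, n_layers=2, n_heads=2, head_hidden=(4,), seed=0),
            X,
            y,
        )


class TestPositionalEncoding:
    def test_entries_bounded_and_first_positions(self):
        enc = positional_encoding(50, 8)
        assert enc.shape == (50, 8)
        assert np.all(np.abs(enc) <= 1.0)
        # position 0: sin(0)=0 on even dims, cos(0)=1 on odd dims
        assert np.allclose(enc[0, 0::2], 0.0)
        assert np.allclose(enc[0, 1::2], 1.0)
        # dimension-pair 0 has angle rate 1: enc[pos, 0] = sin(pos)
        assert enc[1, 0] == pytest.approx(np.sin(1.0))

    def test_angle_rate_formula(self):
        # pos / 10000**(2i/d): at 2i/d = 1 and pos = 10000 the angle is exactly 1
        assert 10000.0 / 10000.0 ** 1.0 == pytest.approx(1.0)
        enc = positional_encoding(3, 4)
        # second pair (i=1, 2i/d=0.5): angle = pos / 100
        assert enc[2, 2] == pytest.approx(np.sin(2.0 / 100.0))

    def test_odd_d_model_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(10, 7)


class TestBCELoss:
    def test_uninformative_prediction_is_ln2(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert bce_loss(y, np.full(4, 0.5)) == pytest.approx(np.log(2.0))

    def test_perfect_prediction_is_clipped_near_zero(self):
        y = np.array([0.0, 1.0])
        assert bce_loss(y, y) <= 1.001e-7

    def test_single_sample_hand_value(self):
        assert bce_loss(np.array([1.0]), np.array([0.25])) == pytest.approx(np.log(4.0), abs=1e-9)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5]), np.array([0.5]))


class TestModels:
    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        model = build_full_spectrum_model(patch_length=8, d_model=16, n_heads=4, seed=0)
        maps = model.attention_maps(rng.normal(size=(3, 12, 16)))
        assert maps.shape == (2, 4, 12, 12)
        assert np.allclose(maps.sum(axis=-1), 1.0, atol=1e-6)

    def test_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(0)
        model = build_feature_model(8, seed=0)
        p = predict(model, rng.normal(size=(10, 8)))
        assert np.all((p > 0) & (p < 1))

    def test_identical_records_get_identical_probabilities(self):
        model = build_full_spectrum_model(patch_length=8, d_model=16, seed=0)
        X = np.tile(np.random.default_rng(0).normal(size=(1, 12, 16)), (5, 1, 1))
        p = predict(model, X)
        assert np.allclose(p, p[0])

    def test_too_small_attention_stack_rejected(self):
        with pytest.raises(ValueError):
            build_full_spectrum_model(n_layers=1)
        with pytest.raises(ValueError):
            build_full_spectrum_model(n_heads=1)

    def test_kan_uses_fewer_parameters_than_mlp_reference(self):
        kan = build_feature_model(8)
        mlp = build_mlp_reference(8)
        assert kan.n_parameters < mlp.n_parameters

    def test_deterministic_init_under_fixed_seed(self):
        a = build_feature_model(4, seed=9)
        b = build_feature_model(4, seed=9)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_checkpoint_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        model = build_feature_model(6, seed=1)
        X = rng.normal(size=(7, 6))
        save_model(model, str(tmp_path / "ckpt.npz"))
        loaded = load_model(str(tmp_path / "ckpt.npz"))
        assert np.allclose(predict(model, X), predict(loaded, X))


def _gaussian_task(n=400, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) > 0.5).astype(float)
    X = rng.normal(size=(n, 2)) + 3.0 * y[:, None]
    return X, y


class TestTraining:
    def test_separable_task_reaches_high_auc(self):
        X, y = _gaussian_task()
        model = build_feature_model(2, seed=0)
        result = train(model, X[:300], y[:300], X[300:], y[300:], TrainConfig(epochs=50, seed=0))
        assert result.best_val_auc >= 0.99
        assert len(result.train_loss) <= 50

    def test_label_shuffle_gives_chance_auc(self):
        """Destroying the label-feature association leaves AUC at chance.

        A single null AUC at n_val = 200 has s.d. ~ 0.04, so the check averages
        three independent shuffles against the 0.5 +- 0.1 band.
        """
        X, y = _gaussian_task()
        aucs = []
        for k in range(3):
            rng = np.random.default_rng(k)
            y_shuffled = rng.permutation(y)
            model = build_feature_model(2, seed=k)
            result = train(
                model,
                X[:200],
                y_shuffled[:200],
                X[200:],
                y_shuffled[200:],
                TrainConfig(epochs=30, seed=k),
            )
            aucs.append(result.val_auc[result.best_epoch])
        assert 0.4 <= float(np.mean(aucs)) <= 0.6

    def test_same_seed_identical_learning_curves(self):
        X, y = _gaussian_task()
        r1 = train(build_feature_model(2, seed=3), X[:300], y[:300], X[300:], y[300:], TrainConfig(epochs=8, seed=3))
        r2 = train(build_feature_model(2, seed=3), X[:300], y[:300], X[300:], y[300:], TrainConfig(epochs=8, seed=3))
        assert r1.train_loss == r2.train_loss
        assert r1.val_loss == r2.val_loss

    def test_subject_scores_average_replicates(self):
        probs = np.array([0.2, 0.4, 0.9, 0.7])
        s = subject_scores(probs, ["A", "A", "B", "B"])
        assert s["A"] == pytest.approx(0.3)
        assert s["B"] == pytest.approx(0.8)
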
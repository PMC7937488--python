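import numpy as np
import pytest

from emgait.classifiers import (elm_training_loss, lda_objective, load_model,
                                predict_elm, predict_lda,
                                predict_serialized_svm, predict_svm,
                                save_model, train_elm, train_lda, train_svm)


@pytest.fixture
def four_blobs(rng):
    x = np.vstack([rng.normal(i * 5, 1.0, size=(30, 3)) for i in range(4)])
    y = np.repeat(np.arange(4), 30)
    return x, y


class TestSVM:
    def test_separable_blobs_interpolated(self, rng):
        x = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(8, 1, (40, 2))])
        y = np.repeat([0, 1], 40)
        model = train_svm(x, y, C=10, g=1)
        assert np.mean(predict_svm(model, x) == y) == 1.0

    def test_xor_with_narrow_kernel(self):
        x = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([0, 0, 1, 1])
        model = train_svm(x, y, C=100, g=0.3)
        assert np.array_equal(predict_svm(model, x), y)

    def test_dual_coefficients_in_box(self, four_blobs):
        x, y = four_blobs
        model = train_svm(x, y, C=2.5, g=1.0)
        # dual_coef_ holds alpha_i * y_i: |.| bounded by C
        assert np.all(np.abs(model.dual_coefficients()) <= 2.5 + 1e-9)

    def test_multiclass_vote_matches_reference_solver(self, four_blobs):
        x, y = four_blobs
        model = train_svm(x, y, C=5, g=2)
        mine = predict_svm(model, x)
        ref = model.svc.predict(model.normalizer(x))
        assert np.array_equal(mine, ref)

    def test_duplicate_rows_identical_predictions(self, four_blobs):
        x, y = four_blobs
        model = train_svm(x, y, C=1, g=1)
        pred = predict_svm(model, np.vstack([x[:5], x[:5]]))
        assert np.array_equal(pred[:5], pred[5:])

    def test_g_parameterization_is_inverse_square(self, four_blobs):
        x, y = four_blobs
        model = train_svm(x, y, C=1, g=4.0)
        assert model.svc.gamma == pytest.approx(1 / 16)

    def test_invalid_inputs_rejected(self, four_blobs):
        x, y = four_blobs
        with pytest.raises(ValueError):
            train_svm(x, np.zeros_like(y), C=1, g=1)  # single class
        with pytest.raises(ValueError):
            train_svm(x, y, C=-1, g=1)
        model = train_svm(x, y, C=1, g=1)
        with pytest.raises(ValueError):
            predict_svm(model, x[:, :2])  # dimension mismatch


class TestLDA:
    def test_two_class_direction_matches_fisher_closed_form(self, rng):
        x = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(3, 1, (60, 2))])
        y = np.repeat([0, 1], 60)
        model = train_lda(x, y)
        w = model.projection[:, 0] / np.linalg.norm(model.projection[:, 0])
        fisher = np.linalg.solve(model.s_w, x[y == 0].mean(0) - x[y == 1].mean(0))
        fisher /= np.linalg.norm(fisher)
        angle = np.degrees(np.arccos(np.clip(abs(w @ fisher), -1, 1)))
        assert angle < 1e-4

    def test_four_separated_classes_training_accuracy(self, four_blobs):
        x, y = four_blobs
        model = train_lda(x, y)
        assert np.mean(predict_lda(model, x) == y) >= 0.99

    def test_projected_dimension_bound(self, four_blobs):
        x, y = four_blobs
        model = train_lda(x, y)
        assert model.projection.shape[1] <= 3

    def test_within_scatter_psd_symmetric(self, four_blobs):
        x, y = four_blobs
        model = train_lda(x, y)
        np.testing.assert_allclose(model.s_w, model.s_w.T)
        assert np.all(np.linalg.eigvalsh(model.s_w) >= -1e-10)

    def test_rayleigh_quotient_maximal_over_random_directions(self, four_blobs):
        x, y = four_blobs
        model = train_lda(x, y)
        best = lda_objective(model, model.projection[:, 0])
        rng = np.random.default_rng(0)
        for _ in range(100):
            d = rng.standard_normal(x.shape[1])
            assert best >= lda_objective(model, d) - 1e-8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_lda(np.ones((3, 2)), np.zeros(3, dtype=int))


class TestELM:
    def test_exact_interpolation_when_overparameterized(self, rng):
        x = rng.standard_normal((40, 3))
        y = rng.integers(0, 4, 40)
        model = train_elm(x, y, hidden_size=80, seed=1)
        assert elm_training_loss(model, x, y) < 1e-6

    def test_deterministic_given_seed(self, four_blobs):
        x, y = four_blobs
        a = train_elm(x, y, hidden_size=50, seed=3)
        b = train_elm(x, y, hidden_size=50, seed=3)
        np.testing.assert_array_equal(a.input_weights, b.input_weights)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)
        np.testing.assert_array_equal(predict_elm(a, x), predict_elm(b, x))

    def test_separable_classes_high_training_accuracy(self, four_blobs):
        x, y = four_blobs
        model = train_elm(x, y, hidden_size=100, seed=0)
        assert np.mean(predict_elm(model, x) == y) >= 0.95

    def test_least_squares_optimality(self, rng):
        x = rng.standard_normal((60, 4))
        y = rng.integers(0, 3, 60)
        model = train_elm(x, y, hidden_size=20, seed=2)
        loss = elm_training_loss(model, x, y)
        t = (y[:, None] == model.classes[None, :]).astype(float)
        h = 1 / (1 + np.exp(-(x @ model.input_weights + model.biases)))
        for _ in range(100):
            beta = model.output_weights + 0.1 * rng.standard_normal(
                model.output_weights.shape)
            assert loss <= np.sum((h @ beta - t) ** 2) + 1e-8

    def test_invalid_hidden_size_rejected(self, four_blobs):
        x, y = four_blobs
        with pytest.raises(ValueError):
            train_elm(x, y, hidden_size=0)


class TestSerialization:
    def test_svm_json_round_trip_predictions(self, four_blobs, tmp_path):
        """The stored support vectors, dual coefficients and biases evaluate
        the pairwise decision function to the same predictions."""
        x, y = four_blobs
        model = train_svm(x, y, C=5, g=3)
        save_model(model, tmp_path / "svm.json")
        back = load_model(tmp_path / "svm.json")
        assert np.array_equal(predict_serialized_svm(back, x),
                              predict_svm(model, x))

    def test_lda_and_elm_round_trip(self, four_blobs, tmp_path):
        x, y = four_blobs
        lda = train_lda(x, y)
        save_model(lda, tmp_path / "lda.json")
        assert np.array_equal(predict_lda(load_model(tmp_path / "lda.json"), x),
                              predict_lda(lda, x))
        elm = train_elm(x, y, hidden_size=40, seed=1)
        save_model(elm, tmp_path / "elm.json")
        assert np.array_equal(predict_elm(load_model(tmp_path / "elm.json"), x),
                              predict_elm(elm, x))
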
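import numpy as np
import pytest

from oddnet.preprocessing import build_idealized_dataset
from oddnet.rnn_model import (
    ModelConfig,
    TrainedHierarchicalRNN,
    _backward,
    crossvalidate,
    fit_metrics,
    forward_with_activations,
    record_condition_activations,
    train,
    train_ensemble_and_select,
)
from oddnet.synthetic_data import CohortConfig, simulate_cohort
from oddnet import preprocessing as pp


def _tiny_dataset(seed=0, n_standards=8, n_d1=2, n_d2=2, **kw):
    cfg = CohortConfig(
        n_animals=2, n_standards=n_standards, n_d1=n_d1, n_d2=n_d2, seed=seed,
        trial_noise_sd=kw.pop("trial_noise_sd", 0.5), **kw,
    )
    return build_idealized_dataset(pp.balance_cohort(pp.preprocess(simulate_cohort(cfg))))


class TestBuild:
    def test_architecture_defaults(self):
        m = TrainedHierarchicalRNN.build()
        assert m.n_hidden_units == 256
        assert m.params["W0"].shape == (101, 64)
        assert m.params["U3"].shape == (64, 64)
        assert m.params["w_out"].shape == (64,)
        # recurrent matrices are orthogonal
        for l in range(4):
            U = m.params[f"U{l}"]
            np.testing.assert_allclose(U @ U.T, np.eye(64), atol=1e-10)

    def test_seed_determinism(self):
        a = TrainedHierarchicalRNN.build(ModelConfig(seed=5))
        b = TrainedHierarchicalRNN.build(ModelConfig(seed=5))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_zero_input_zero_output(self):
        m = TrainedHierarchicalRNN.build(ModelConfig(seed=2))
        y = m.forward(np.zeros((101, 111)))
        np.testing.assert_allclose(y, 0, atol=1e-15)

    def test_positive_scale_homogeneity_with_zero_bias(self, rng):
        """With zero biases the rectifier stack is positively homogeneous."""
        m = TrainedHierarchicalRNN.build(ModelConfig(seed=3))
        x = rng.random((101, 111))
        np.testing.assert_allclose(m.forward(2 * x), 2 * m.forward(x), rtol=1e-9)

    def test_nonzero_bias_breaks_scale_linearity(self, rng):
        m = TrainedHierarchicalRNN.build(ModelConfig(seed=3))
        for l in range(4):
            m.params[f"b{l}"] = 0.1 * rng.standard_normal(64)
        x = rng.random((101, 111))
        assert not np.allclose(m.forward(2 * x), 2 * m.forward(x), rtol=1e-3)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        cfg = ModelConfig(n_input=3, n_layers=2, units_per_layer=4, seed=1)
        m = TrainedHierarchicalRNN.build(cfg)
        x = rng.random((2, 3, 7))
        g = rng.standard_normal((2, 7))

        def loss():
            y = m.forward(x)
            return ((y - g) ** 2).mean()

        def dy_fn(y):
            return 2.0 / y.size * (y - g)

        grads, _ = _backward(m, x, dy_fn)
        eps = 1e-6
        for k, v in m.params.items():
            base = np.array(v, dtype=float)
            for i in range(0, base.size, max(1, base.size // 5)):
                for sign in (+1, -1):
                    pert = base.copy().ravel()
                    pert[i] += sign * eps
                    m.params[k] = pert.reshape(base.shape)
                    if sign > 0:
                        lp = loss()
                    else:
                        lm = loss()
                m.params[k] = base
                num = (lp - lm) / (2 * eps)
                ana = np.atleast_1d(grads[k]).ravel()[i]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-8), k


class TestTrain:
    def test_loss_decreases(self):
        ds = _tiny_dataset()
        losses = []
        for seed in range(3):
            m = TrainedHierarchicalRNN.build(ModelConfig(seed=seed, batch_size=16))
            train(m, ds, epochs=50)
            losses.append((m.history[0], m.history[-1]))
        assert np.median([a for a, _ in losses]) > np.median([b for _, b in losses])

    def test_zero_targets_drive_output_towards_silence(self):
        """The degenerate all-zero-target fit collapses the loss by orders
        of magnitude within 100 epochs (the exact floor depends on the raw
        input scale, so the check is relative)."""
        ds = _tiny_dataset()
        ds.targets = np.zeros_like(ds.targets)
        m = TrainedHierarchicalRNN.build(ModelConfig(seed=0, batch_size=16))
        train(m, ds, epochs=100)
        assert m.history[-1] < 1e-3 * m.history[0]

    def test_training_determinism(self):
        ds = _tiny_dataset()
        runs = []
        for _ in range(2):
            m = TrainedHierarchicalRNN.build(ModelConfig(seed=4, batch_size=8))
            train(m, ds, epochs=5)
            runs.append(m)
        for k in runs[0].params:
            np.testing.assert_array_equal(runs[0].params[k], runs[1].params[k])
        assert runs[0].history == runs[1].history

    def test_save_load_roundtrip(self, tmp_path):
        ds = _tiny_dataset()
        m = TrainedHierarchicalRNN.build(ModelConfig(seed=0, batch_size=8))
        train(m, ds, epochs=2)
        m.save(tmp_path / "model")
        m2 = TrainedHierarchicalRNN.load(tmp_path / "model")
        x = ds.unique_inputs["S"].magnitudes
        np.testing.assert_array_equal(m.forward(x), m2.forward(x))


class TestActivations:
    def test_record_shapes_and_nonnegativity(self):
        ds = _tiny_dataset()
        m = TrainedHierarchicalRNN.build(ModelConfig(seed=1))
        acts, y = forward_with_activations(m, ds.unique_inputs["S"].magnitudes)
        assert acts.shape == (4, 64, 111)
        assert y.shape == (111,)
        assert (acts >= 0).all()
        np.testing.assert_array_equal(y, m.forward(ds.unique_inputs["S"].magnitudes))

    def test_condition_record_flattens_to_5_by_28416(self):
        ds = _tiny_dataset()
        m = TrainedHierarchicalRNN.build(ModelConfig(seed=1))
        rec = record_condition_activations(m, ds)
        flat = rec.stacked().reshape(5, -1)
        assert flat.shape == (5, 28_416)

    def test_shape_mismatch_rejected(self):
        m = TrainedHierarchicalRNN.build(ModelConfig(seed=0))
        with pytest.raises(ValueError):
            forward_with_activations(m, np.zeros((7, 111)))


class TestCrossValidation:
    def test_fold_structure_and_generalisation(self):
        ds = _tiny_dataset(n_standards=20, n_d1=5, n_d2=5, trial_noise_sd=0.0,
                           animal_effect_sd=0.0, alpha_amplitude=0.0)
        cfg = ModelConfig(seed=0, batch_size=16)
        cv = crossvalidate(cfg, ds, k=5, epochs=40)
        assert len(cv) == 5
        assert (cv["n_val"] == ds.n_trials // 5).all()
        # noise-free targets: validation tracks training
        assert cv["val_mse"].mean() <= 2 * cv["train_mse"].mean()

    def test_k1_rejected(self):
        ds = _tiny_dataset()
        with pytest.raises(ValueError):
            crossvalidate(ModelConfig(seed=0), ds, k=1)

    def test_small_stratum_rejected(self):
        ds = _tiny_dataset(n_standards=8, n_d1=2, n_d2=2)
        with pytest.raises(ValueError):
            crossvalidate(ModelConfig(seed=0), ds, k=5)


class TestEnsembleSelection:
    def test_single_model_returned(self):
        ds = _tiny_dataset()
        best, table = train_ensemble_and_select(
            ModelConfig(seed=0, batch_size=16), ds, n_models=1, epochs=3
        )
        assert len(table) == 1
        assert best.history  # trained

    def test_selection_is_order_free(self):
        ds = _tiny_dataset()
        _, table = train_ensemble_and_select(
            ModelConfig(seed=0, batch_size=16), ds, n_models=3, epochs=3
        )
        winner = table.sort_values(
            ["mean_r_squared", "mean_mse"], ascending=[False, True]
        ).iloc[0]["model"]
        best_again, _ = train_ensemble_and_select(
            ModelConfig(seed=0, batch_size=16), ds, n_models=3, epochs=3
        )
        assert best_again.config.seed == int(table.iloc[int(winner)]["seed"])

    def test_fit_metrics_bounds(self):
        ds = _tiny_dataset()
        m = TrainedHierarchicalRNN.build(ModelConfig(seed=0, batch_size=16))
        train(m, ds, epochs=2)
        fm = fit_metrics(m, ds)
        for c, r2 in fm.r_squared.items():
            assert 0.0 <= r2 <= 1.0
            assert fm.mse[c] >= 0
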
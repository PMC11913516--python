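"""Cost accounting, network mechanics, training behaviour of the classifier."""

from fractions import Fraction

import numpy as np
import pytest

from mondnet.classifier import (
    ArchConfig,
    ConfigurationError,
    ConvSpec,
    MondNet,
    MondNetModel,
    TrainConfig,
    build_model,
    cost_report,
    features_to_maps,
    fuse_inputs,
    predict,
    separable_conv_cost,
    standard_conv_cost,
    train,
)


def separable_toy_problem(n_per_class=50, dim=288, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0, 1, (n_per_class, dim))
    x0[:, :10] += 2.0
    x1 = rng.normal(0, 1, (n_per_class, dim))
    x1[:, :10] -= 2.0
    features = np.vstack([x0, x1])
    labels = ["normal"] * n_per_class + ["abnormal"] * n_per_class
    return features, labels


class TestCostAccounting:
    def test_standard_cost_worked_example(self):
        spec = ConvSpec(in_channels=16, out_channels=32, kernel_size=3, out_spatial=8)
        assert standard_conv_cost(spec) == 8 * 8 * 16 * 32 * 3 * 3 == 294912

    def test_separable_cost_worked_example(self):
        spec = ConvSpec(in_channels=16, out_channels=32, kernel_size=3, out_spatial=8)
        assert separable_conv_cost(spec) == 8 * 8 * 16 * 9 + 16 * 32 * 9 == 13824

    def test_reduction_ratio_matches_closed_form(self):
        spec = ConvSpec(in_channels=16, out_channels=32, kernel_size=3, out_spatial=8)
        rep = cost_report(spec)
        assert rep.ratio == Fraction(1, 32) + Fraction(1, 64)
        assert float(rep.ratio) == pytest.approx(0.046875)

    def test_unit_cases(self):
        unit = ConvSpec(1, 1, 1, 1)
        assert standard_conv_cost(unit) == 1
        assert separable_conv_cost(unit) == 2

    def test_cost_linear_in_out_channels(self):
        a = ConvSpec(7, 5, 3, 6)
        b = ConvSpec(7, 10, 3, 6)
        assert standard_conv_cost(b) == 2 * standard_conv_cost(a)

    def test_ratio_identity_randomized_exact(self, rng):
        # exact rational arithmetic over randomized layer shapes
        for _ in range(1000):
            spec = ConvSpec(
                in_channels=int(rng.integers(1, 512)),
                out_channels=int(rng.integers(1, 512)),
                kernel_size=int(rng.integers(1, 12)),
                out_spatial=int(rng.integers(1, 128)),
            )
            rep = cost_report(spec)
            expected = Fraction(1, spec.out_channels) + Fraction(1, spec.out_spatial**2)
            assert rep.ratio == expected
            assert rep.ratio == Fraction(rep.separable_cost, rep.standard_cost)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            ConvSpec(0, 1, 1, 1)


class TestNetworkMechanics:
    def test_softmax_outputs_probability_vector(self, rng):
        model = build_model(feature_length=40, seed=0)
        proba = model.predict_proba(rng.normal(size=(5, 40)))
        assert proba.shape == (5, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert (proba >= 0).all()

    def test_separable_has_fewer_params_than_standard(self):
        sep = build_model(feature_length=288, seed=0)
        std = build_model(feature_length=288, seed=0, standard_only=True)
        assert sep.n_params() < std.n_params()

    def test_untrained_model_near_chance(self, rng):
        model = build_model(feature_length=64, seed=1)
        x = rng.normal(size=(200, 64))
        labels, _ = model.predict(x)
        truth = np.array(["normal", "abnormal"] * 100)
        acc = (labels == truth).mean()
        assert abs(acc - 0.5) < 0.15

    def test_feature_map_reshape_pads_with_zeros(self):
        maps = features_to_maps(np.arange(5, dtype=float))
        assert maps.shape == (1, 3, 3, 1)
        assert maps.reshape(-1)[:5].tolist() == [0, 1, 2, 3, 4]
        assert (maps.reshape(-1)[5:] == 0).all()

    def test_fuse_inputs_stacks_image_and_histogram_channel(self, rng):
        feats = rng.uniform(size=(2, 9))
        imgs = rng.integers(0, 256, size=(2, 32, 32, 3))
        x = fuse_inputs(feats, imgs)
        assert x.shape == (2, 32, 32, 4)
        np.testing.assert_allclose(x[:, :, :, :3], imgs / 255.0)
        np.testing.assert_allclose(x[0, :3, :3, 3].reshape(-1), feats[0])
        assert (x[:, 3:, :, 3] == 0).all()

    def test_feature_length_mismatch_rejected(self, rng):
        model = build_model(feature_length=40, seed=0)
        with pytest.raises(ConfigurationError):
            model.predict(rng.normal(size=(3, 41)))

    def test_single_class_training_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            MondNet(rng.normal(size=(10, 8)), ["normal"] * 10)


class TestTraining:
    def test_separable_problem_reaches_high_train_accuracy(self):
        features, labels = separable_toy_problem()
        results = train(features, labels, TrainConfig(epochs=30, seed=3))
        assert results.final_accuracy >= 0.95

    def test_loss_trend_nonincreasing_smoothed(self):
        # 10-epoch moving averages of the loss must not increase on a
        # separable problem, up to the batch-noise wobble of the converged
        # plateau; the curve must also actually reach a low plateau
        features, labels = separable_toy_problem()
        results = train(features, labels, TrainConfig(epochs=30, seed=3))
        loss = results.history["loss"].to_numpy()
        win = np.convolve(loss, np.ones(10) / 10, mode="valid")
        assert all(b <= a + 0.01 for a, b in zip(win, win[1:]))
        assert win[-1] < 0.2 * win[0]

    def test_seeded_training_reproducible(self):
        features, labels = separable_toy_problem(n_per_class=10, dim=36)
        cfg = TrainConfig(epochs=5, seed=9)
        r1 = train(features, labels, cfg)
        r2 = train(features, labels, cfg)
        np.testing.assert_array_equal(
            r1.history["loss"].to_numpy(), r2.history["loss"].to_numpy()
        )

    def test_history_has_expected_columns(self):
        features, labels = separable_toy_problem(n_per_class=5, dim=16)
        results = train(features, labels, TrainConfig(epochs=3, seed=0))
        assert list(results.history.columns) == ["epoch", "loss", "accuracy"]
        assert len(results.history) == 3

    def test_summary_mentions_architecture_and_params(self):
        features, labels = separable_toy_problem(n_per_class=5, dim=16)
        results = train(features, labels, TrainConfig(epochs=2, seed=0))
        text = results.summary()
        assert "Parameters:" in text and "dw-sep blocks" in text


class TestPredict:
    def test_probabilities_sum_to_one(self):
        features, labels = separable_toy_problem(n_per_class=10, dim=36)
        results = train(features, labels, TrainConfig(epochs=5, seed=1))
        proba = results.predict_proba(features)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_composition_invariance(self):
        features, labels = separable_toy_problem(n_per_class=10, dim=36)
        results = train(features, labels, TrainConfig(epochs=5, seed=1))
        batched = results.predict_proba(features)
        singles = np.vstack([results.predict_proba(features[i : i + 1]) for i in range(len(features))])
        np.testing.assert_allclose(batched, singles, atol=1e-6)

    def test_matches_nearest_centroid_oracle(self):
        features, labels = separable_toy_problem(n_per_class=50, seed=4)
        results = train(features, labels, TrainConfig(epochs=30, seed=4))
        preds, _ = results.predict(features)
        c_normal = features[:50].mean(axis=0)
        c_abnormal = features[50:].mean(axis=0)
        centroid = np.where(
            np.linalg.norm(features - c_abnormal, axis=1)
            < np.linalg.norm(features - c_normal, axis=1),
            "abnormal",
            "normal",
        )
        assert (preds == centroid).mean() >= 0.95

    def test_tie_breaks_toward_abnormal(self):
        model = build_model(feature_length=4, seed=0)
        # force exactly tied logits by zeroing the head
        dense = model.net.layers[-1]
        dense.params["w"][:] = 0.0
        dense.params["b"][:] = 0.0
        labels, proba = model.predict(np.ones((3, 4)))
        np.testing.assert_allclose(proba, 0.5)
        assert (labels == "abnormal").all()

    def test_model_roundtrip_through_file(self, tmp_path, rng):
        features, labels = separable_toy_problem(n_per_class=5, dim=16)
        results = train(features, labels, TrainConfig(epochs=2, seed=0))
        path = tmp_path / "model.npz"
        results.model.save(path)
        loaded = MondNetModel.load(path)
        x = rng.normal(size=(4, 16))
        np.testing.assert_allclose(
            loaded.predict_proba(x), results.predict_proba(x), atol=1e-12
        )
        p1 = predict(loaded, x)
        np.testing.assert_array_equal(p1[0], results.predict(x)[0])
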
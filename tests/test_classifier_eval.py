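import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qus_settingcal import ExperimentConfig, TrainConfig
from qus_settingcal.classifier_eval import (
    architecture_summary,
    dry_run_shapes,
    evaluate,
    fine_tune,
    normalize_patch_array,
    repeat_experiment,
    train_classifier,
    zscore_normalize,
)
from qus_settingcal.patching import Patch


class TestZScore:
    def test_ramp_standardized(self):
        x = np.arange(200 * 26, dtype=float).reshape(200, 26)
        out = zscore_normalize(x)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, rel=1e-12)

    def test_constant_patch_maps_to_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_normalize(np.full((10, 5), 3.0))
        assert np.all(out == 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 6))
        np.testing.assert_allclose(
            zscore_normalize(a * x + b), zscore_normalize(x), atol=1e-8
        )

    def test_patch_object_round_trip(self):
        p = Patch(np.arange(12.0).reshape(4, 3), 2, 1, 5, "c")
        out = zscore_normalize(p)
        assert isinstance(out, Patch)
        assert out.depth_line == 2 and out.label == "c"

    def test_dataset_mode_shares_statistics(self):
        X = np.stack([np.full((4, 4), 1.0), np.full((4, 4), 3.0)])
        out = normalize_patch_array(X, mode="dataset")
        # per-patch means survive dataset-level normalization
        assert out[0].mean() == pytest.approx(-1.0)
        assert out[1].mean() == pytest.approx(1.0)


class TestArchitecturePresets:
    def test_resnet_dry_run_shapes(self):
        shapes = dict(dry_run_shapes("resnet50_mod", (200, 26)))
        assert shapes["conv1"] == (100, 13)
        assert shapes["conv5"] == (7, 1)
        assert shapes["output"] == (2,)

    def test_densenet_declared_table(self):
        shapes = dict(dry_run_shapes("densenet201_mod", (200, 26)))
        assert shapes["conv1"] == (102, 15)
        assert shapes["output"] == (2,)

    def test_summaries_and_training_refusal(self):
        assert architecture_summary("resnet50_mod")[0][0] == "conv1"
        X = np.zeros((4, 200, 26))
        y = np.array([0, 0, 1, 1])
        with pytest.raises(NotImplementedError):
            train_classifier(X, y, TrainConfig(architecture="resnet50_mod"))


def _tone_patches(rng, n_per_class=200, shape=(200, 26)):
    """Two classes as distinct narrowband textures; linearly separable in
    the spectral domain."""
    fs = 40e6
    t = np.arange(shape[0]) / fs
    X, y = [], []
    for label, f0 in (("a", 3e6), ("b", 7e6)):
        for _ in range(n_per_class):
            phase = rng.uniform(0, 2 * np.pi, shape[1])
            tone = np.sin(2 * np.pi * f0 * t[:, None] + phase[None, :])
            X.append(tone + 0.1 * rng.normal(size=shape))
            y.append(label)
    return np.stack(X).astype(np.float32), np.array(y)


class TestTrainClassifier:
    @pytest.mark.parametrize("arch", ["small_cnn", "spectral_logreg"])
    def test_separable_classes_learned_to_99pct(self, rng, arch):
        X, y = _tone_patches(rng)
        cfg = TrainConfig(architecture=arch, epochs=8, seed=1)
        model = train_classifier(X, y, cfg)
        res = evaluate(model, X, y)
        assert res["accuracy"] >= 99.0

    def test_training_is_deterministic_without_flips(self, rng):
        X, y = _tone_patches(rng, n_per_class=100)
        cfg = TrainConfig(epochs=2, flip_prob=0.0, seed=42)
        m1 = train_classifier(X, y, cfg)
        m2 = train_classifier(X, y, cfg)
        assert m1.loss_history == m2.loss_history
        np.testing.assert_array_equal(m1.net.params["W1"], m2.net.params["W1"])

    def test_single_class_rejected(self):
        X = np.zeros((8, 200, 26), dtype=np.float32)
        y = np.array(["a"] * 8)
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(X, y, TrainConfig())

    def test_unknown_architecture_rejected(self):
        X = np.zeros((4, 200, 26))
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="architecture"):
            train_classifier(X, y, TrainConfig(architecture="vgg"))


class TestFineTune:
    def test_zero_epochs_leaves_model_unchanged(self, rng):
        X, y = _tone_patches(rng, n_per_class=60)
        model = train_classifier(X, y, TrainConfig(epochs=1, seed=2))
        tuned = fine_tune(model, X, y, TrainConfig(epochs=0))
        np.testing.assert_array_equal(
            tuned.predict_proba(X[:16]), model.predict_proba(X[:16])
        )

    def test_small_set_fine_tuning_runs(self, rng):
        X, y = _tone_patches(rng, n_per_class=81)  # 162 patches total
        model = train_classifier(X, y, TrainConfig(epochs=1, seed=3))
        tuned = fine_tune(
            model, X, y, TrainConfig(epochs=1, learning_rate=2e-6, seed=3)
        )
        assert tuned is not model
        assert evaluate(tuned, X, y)["accuracy"] > 0

    def test_in_domain_fine_tuning_does_not_regress(self, rng):
        X, y = _tone_patches(rng, n_per_class=150)
        hold = slice(0, 60)
        model = train_classifier(X[60:], y[60:], TrainConfig(epochs=2, seed=4))
        before = evaluate(model, X[hold], y[hold])["accuracy"]
        tuned = fine_tune(
            model, X[60:], y[60:], TrainConfig(epochs=1, learning_rate=2e-6, seed=4)
        )
        after = evaluate(tuned, X[hold], y[hold])["accuracy"]
        assert after >= before - 2.0


class _FakeModel:
    def __init__(self, scores, classes=(0, 1)):
        self.scores = np.asarray(scores, dtype=float)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return np.column_stack([1 - self.scores, self.scores])


class TestEvaluate:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        model = _FakeModel([0.1, 0.2, 0.8, 0.9])
        res = evaluate(model, np.zeros((4, 2, 2)), y)
        assert res["accuracy"] == 100.0 and res["auc"] == 1.0

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(7)
        n = 2000
        y = np.repeat([0, 1], n // 2)
        model = _FakeModel(rng.uniform(size=n))
        res = evaluate(model, np.zeros((n, 1, 1)), y)
        assert abs(res["accuracy"] - 50.0) < 3.0
        assert abs(res["auc"] - 0.5) < 0.05

    def test_auc_equals_mann_whitney_enumeration(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        # enumerate all (positive, negative) pairs: 0.35>0.1, 0.35<0.4,
        # 0.8>0.1, 0.8>0.4 -> 3/4
        model = _FakeModel(scores)
        res = evaluate(model, np.zeros((4, 1, 1)), y)
        assert res["auc"] == pytest.approx(0.75)

    def test_single_class_auc_is_missing(self):
        y = np.zeros(4, dtype=int)
        model = _FakeModel([0.1, 0.2, 0.3, 0.4])
        res = evaluate(model, np.zeros((4, 1, 1)), y)
        assert res["auc"] is None
        assert res["accuracy"] == 100.0


class TestRepeatExperiment:
    def test_single_repeat_has_zero_std(self):
        cfg = ExperimentConfig(
            mismatch="power",
            conditions=("benchmark",),
            n_train_frames_per_class=3,
            n_test_frames_per_class=2,
            n_cal_repeats=2,
            max_train_patches=400,
            train=TrainConfig(epochs=1, seed=0),
            seed=5,
        )
        res = repeat_experiment(cfg, n_repeats=1)
        assert res.accuracy_std == 0.0
        assert 0.0 <= res.accuracy_mean <= 100.0
        assert len(res.per_repeat) == 1

    def test_requires_single_condition(self):
        cfg = ExperimentConfig(conditions=("benchmark", "test_time"))
        with pytest.raises(ValueError):
            repeat_experiment(cfg, n_repeats=1)
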
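import numpy as np
import pytest

from mirtarget.ann import (
    LabeledExample,
    MlpModel,
    TrainingConfig,
    compute_gradients,
    evaluate,
    predict,
    train,
    train_per_class,
)
from mirtarget.features import FeatureVector
from mirtarget.site_classes import TargetClass


def fv(values) -> FeatureVector:
    return FeatureVector.from_iterable(values)


def xor_examples() -> list[LabeledExample]:
    """XOR lifted into 16 dimensions: two informative inputs, 14 zeros."""
    out = []
    for a in (0.0, 1.0):
        for b in (0.0, 1.0):
            label = 1 if (a != b) else -1
            for _rep in range(8):
                out.append(
                    LabeledExample(fv([a, b] + [0.0] * 14), label, TargetClass.DOMINANT)
                )
    return out


def gaussian_examples(n, seed, separation=4.0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        label = 1 if rng.random() < 0.45 else -1
        center = separation / 2 if label == 1 else -separation / 2
        out.append(
            LabeledExample(fv(rng.normal(center, 1.0, size=16)), label, TargetClass.DOMINANT)
        )
    return out


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        for activation in ("tanh", "logistic"):
            w1 = rng.uniform(-0.5, 0.5, (9, 16)); b1 = rng.uniform(-0.5, 0.5, 9)
            w2 = rng.uniform(-0.5, 0.5, (1, 9)); b2 = rng.uniform(-0.5, 0.5, 1)
            x = rng.uniform(0, 1, 16)
            t = 1.0 if activation == "tanh" else 1.0
            grads = compute_gradients(w1, b1, w2, b2, x, t, activation)
            params = [w1, b1, w2, b2]
            eps = 1e-6

            def loss():
                h = np.tanh(w1 @ x + b1) if activation == "tanh" else 1/(1+np.exp(-(w1 @ x + b1)))
                y = np.tanh(w2 @ h + b2) if activation == "tanh" else 1/(1+np.exp(-(w2 @ h + b2)))
                return 0.5 * float((y[0] - t) ** 2)

            for p, g in zip(params, grads):
                flat_p, flat_g = p.ravel(), g.ravel()
                for k in rng.choice(flat_p.size, size=min(10, flat_p.size), replace=False):
                    orig = flat_p[k]
                    flat_p[k] = orig + eps; up = loss()
                    flat_p[k] = orig - eps; dn = loss()
                    flat_p[k] = orig
                    fd = (up - dn) / (2 * eps)
                    denom = max(abs(fd), abs(flat_g[k]), 1e-8)
                    assert abs(fd - flat_g[k]) / denom < 1e-5


class TestTraining:
    def test_xor_in_16d_converges(self):
        model = train(xor_examples(), TrainingConfig(seed=5))
        X = np.array([e.features.as_tuple() for e in xor_examples()])
        T = np.array([e.label for e in xor_examples()], dtype=float)
        preds = np.array([model.forward(model.normalize(x)) for x in X])
        mse = float(np.mean((preds - T) ** 2))
        assert mse < 0.05

    def test_separable_gaussians_reach_high_heldout_accuracy(self):
        model = train(gaussian_examples(350, seed=2), TrainingConfig(seed=3))
        test = gaussian_examples(200, seed=99)
        correct = 0
        for e in test:
            score, _ = predict(model, e.features)
            correct += (score >= 0) == (e.label == 1)
        assert correct / len(test) >= 0.95

    def test_same_seed_same_data_bitwise_identical(self):
        data = gaussian_examples(60, seed=4)
        m1 = train(data, TrainingConfig(seed=7))
        m2 = train(data, TrainingConfig(seed=7))
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.w2, m2.w2)
        assert np.array_equal(m1.b1, m2.b1) and np.array_equal(m1.b2, m2.b2)

    def test_single_class_input_rejected(self):
        data = [
            LabeledExample(fv(np.arange(16) + i), 1, TargetClass.DOMINANT)
            for i in range(12)
        ]
        with pytest.raises(ValueError, match="both"):
            train(data, TrainingConfig(seed=0))

    def test_too_few_examples_rejected(self):
        data = gaussian_examples(6, seed=1)
        with pytest.raises(ValueError):
            train(data, TrainingConfig(seed=0))

    def test_normalization_statistics_come_from_training_split_only(self):
        data = gaussian_examples(100, seed=8)
        cfg = TrainingConfig(seed=9)
        model = train(data, cfg)
        rng = np.random.default_rng(cfg.seed)
        X = np.array([e.features.as_tuple() for e in data])
        order = rng.permutation(len(data))
        n_train = int(round(cfg.train_fraction * len(data)))
        np.testing.assert_array_equal(model.feat_min, X[order[:n_train]].min(axis=0))
        np.testing.assert_array_equal(model.feat_max, X[order[:n_train]].max(axis=0))

    def test_logistic_output_variant_trains(self):
        model = train(
            gaussian_examples(120, seed=12),
            TrainingConfig(seed=13, activation="logistic", max_epochs=200),
        )
        score, _ = predict(model, gaussian_examples(1, seed=50)[0].features)
        assert 0.0 <= score <= 1.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=0)
        with pytest.raises(ValueError):
            TrainingConfig(momentum=1.0)
        with pytest.raises(ValueError):
            TrainingConfig(activation="relu")


class TestPredict:
    def test_zero_weights_score_zero_below_threshold(self):
        model = MlpModel(
            w1=np.zeros((9, 16)), b1=np.zeros(9),
            w2=np.zeros((1, 9)), b2=np.zeros(1),
            feat_min=np.zeros(16), feat_max=np.ones(16),
        )
        score, is_target = predict(model, fv([0.5] * 16))
        assert score == 0.0 and not is_target

    def test_dimension_check(self):
        model = train(gaussian_examples(60, seed=4), TrainingConfig(seed=7))
        with pytest.raises(ValueError):
            predict(model, np.zeros(15))

    def test_lower_threshold_never_decreases_positive_count(self):
        model = train(gaussian_examples(80, seed=20), TrainingConfig(seed=21))
        test = gaussian_examples(60, seed=22)
        scores = [predict(model, e.features)[0] for e in test]
        n_high = sum(s >= 0.98 for s in scores)
        n_low = sum(s >= 0.5 for s in scores)
        assert n_low >= n_high


class TestPerClass:
    def test_models_trained_per_class_and_isolated(self, corpus):
        cfg = TrainingConfig(seed=31)
        models = train_per_class(corpus.train_examples, cfg)
        assert set(models) == {
            TargetClass.SEED_ONLY, TargetClass.DOMINANT, TargetClass.CANONICAL
        }
        # permuting one class's examples leaves the other models untouched
        shuffled = dict(corpus.train_examples)
        shuffled[TargetClass.CANONICAL] = list(reversed(shuffled[TargetClass.CANONICAL]))
        models2 = train_per_class(shuffled, cfg)
        assert np.array_equal(
            models[TargetClass.SEED_ONLY].w1, models2[TargetClass.SEED_ONLY].w1
        )
        assert np.array_equal(
            models[TargetClass.DOMINANT].w1, models2[TargetClass.DOMINANT].w1
        )

    def test_missing_partition_is_an_error(self, corpus):
        partial = {TargetClass.SEED_ONLY: corpus.train_examples[TargetClass.SEED_ONLY]}
        with pytest.raises(ValueError, match="CANONICAL"):
            train_per_class(partial, TrainingConfig(seed=0))

    def test_model_json_roundtrip(self, tmp_path, corpus, models):
        model = models[TargetClass.DOMINANT]
        path = tmp_path / "dom.json"
        model.save(path)
        back = MlpModel.load(path)
        assert np.array_equal(back.w1, model.w1)
        assert back.threshold == model.threshold
        assert back.target_class == model.target_class
        x = fv(np.linspace(0, 50, 16))
        assert predict(back, x) == predict(model, x)


class TestEvaluate:
    def test_perfect_scorer(self):
        m = evaluate([0.99, 0.99, -0.99, -0.99], [1, 1, -1, -1])
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0
        assert m["accuracy"] == 1.0 and m["auc"] == 1.0

    def test_constant_scorer_has_half_auc(self):
        m = evaluate([0.3] * 6, [1, 1, 1, -1, -1, -1], threshold=0.5)
        assert m["auc"] == pytest.approx(0.5)

    def test_frozen_confusion_matrix(self):
        # hand-computed: scores vs labels at threshold 0.5
        scores = [0.9, 0.8, 0.4, 0.6, 0.2, 0.1]
        labels = [1, 1, 1, -1, -1, -1]
        m = evaluate(scores, labels, threshold=0.5)
        assert (m["tp"], m["fn"], m["fp"], m["tn"]) == (2, 1, 1, 2)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["auc"] == pytest.approx(8 / 9)

    def test_empty_or_single_label_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])
        with pytest.raises(ValueError):
            evaluate([0.5, 0.4], [1, 1])
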
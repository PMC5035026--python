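import numpy as np
import pytest

from antioxpred.classifiers import (
    AverageProbabilityEnsemble,
    ClassifierRanking,
    VotingFeatureIntervals,
    default_registry,
    fit_ensemble,
    rank_classifiers,
    select_classifier_subset,
    select_subset_size,
)

# per-subset CV accuracies printed for the nested ensembles on the balanced
# 100+100 training set, from size 1 (best single classifier) to size 10
SUBSET_ACCURACIES = (0.895, 0.885, 0.915, 0.925, 0.91, 0.905, 0.91, 0.905, 0.9, 0.89)

# per-classifier CV accuracies on the same set, in registry order
SINGLE_ACCURACIES = {
    "RF": 0.895, "SMO": 0.885, "NNA": 0.865, "J48": 0.86, "BN": 0.845,
    "RBFNetwork": 0.845, "DT": 0.835, "Adaboost": 0.83, "VFI": 0.765, "NB": 0.755,
}


class TestVotingFeatureIntervals:
    def test_separated_intervals_give_confident_votes(self):
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        y = np.array([0, 0, 1, 1])
        vfi = VotingFeatureIntervals().fit(X, y)
        proba = vfi.predict_proba(np.array([[0.05], [1.05]]))
        np.testing.assert_allclose(proba, [[1.0, 0.0], [0.0, 1.0]])
        assert vfi.predict(np.array([[0.05]]))[0] == 0

    def test_overlapping_intervals_split_the_vote(self):
        X = np.array([[0.0], [1.0], [0.5], [1.5]])
        y = np.array([0, 0, 1, 1])
        vfi = VotingFeatureIntervals().fit(X, y)
        proba = vfi.predict_proba(np.array([[0.7]]))
        np.testing.assert_allclose(proba, [[0.5, 0.5]])

    def test_outside_all_intervals_falls_back_to_uniform(self):
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        y = np.array([0, 0, 1, 1])
        vfi = VotingFeatureIntervals().fit(X, y)
        np.testing.assert_allclose(vfi.predict_proba(np.array([[9.0]])), [[0.5, 0.5]])

    def test_probabilities_valid_on_random_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        y = rng.integers(0, 2, size=30)
        proba = VotingFeatureIntervals().fit(X, y).predict_proba(rng.normal(size=(10, 5)))
        assert np.all(proba >= 0)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)


class TestRegistry:
    def test_ten_uniquely_named_members(self):
        registry = default_registry()
        names = [s.name for s in registry]
        assert len(names) == 10
        assert len(set(names)) == 10

    def test_every_member_emits_two_class_probabilities(self, separable_xy):
        X, y = separable_xy
        for spec in default_registry():
            est = spec.build(seed=0)
            est.fit(X, y)
            proba = est.predict_proba(X)
            assert proba.shape == (len(y), 2), spec.name
            assert np.all(proba >= -1e-12), spec.name
            np.testing.assert_allclose(proba.sum(axis=1), 1.0, err_msg=spec.name)


class TestRankClassifiers:
    def test_stub_accuracies_reproduce_reported_order(self):
        ranking = rank_classifiers(
            default_registry(), None, None,
            evaluator=lambda spec: SINGLE_ACCURACIES[spec.name],
        )
        assert list(ranking.order) == [
            "RF", "SMO", "NNA", "J48", "BN", "RBFNetwork", "DT", "Adaboost", "VFI", "NB",
        ]

    def test_equal_accuracy_preserves_registry_order(self):
        ranking = rank_classifiers(default_registry(), None, None, evaluator=lambda s: 0.5)
        assert list(ranking.order) == [s.name for s in default_registry()]

    def test_failing_spec_dropped_with_warning(self):
        def evaluator(spec):
            if spec.name == "SMO":
                raise RuntimeError("no convergence")
            return SINGLE_ACCURACIES[spec.name]

        with pytest.warns(UserWarning, match="SMO"):
            ranking = rank_classifiers(default_registry(), None, None, evaluator=evaluator)
        assert "SMO" not in ranking.order
        assert len(ranking.order) == 9


class TestSubsetSelection:
    def test_reported_subset_curve_selects_four_members(self):
        assert select_subset_size(SUBSET_ACCURACIES) == 4

    def test_monotone_decreasing_curve_selects_one(self):
        assert select_subset_size([0.9, 0.85, 0.8]) == 1

    def test_flat_curve_selects_smallest(self):
        assert select_subset_size([0.7, 0.7, 0.7]) == 1

    def test_stubbed_selection_returns_top_four_members(self, separable_xy):
        X, y = separable_xy
        ranking = rank_classifiers(
            default_registry(), None, None,
            evaluator=lambda spec: SINGLE_ACCURACIES[spec.name],
        )
        model = select_classifier_subset(
            ranking, default_registry(), X, y,
            feature_names=["f0", "f1"],
            subset_evaluator=lambda size: SUBSET_ACCURACIES[size - 1],
        )
        assert model.member_names == ["RF", "SMO", "NNA", "J48"]
        np.testing.assert_allclose(model.subset_curve, SUBSET_ACCURACIES)

    def test_selected_subset_never_below_best_single_by_construction(self):
        # the size-1 subset IS the best single classifier, so the selected
        # maximum can never fall below it
        for curve in ([0.9, 0.2, 0.1], [0.5, 0.9, 0.7], [0.6] * 5):
            k = select_subset_size(curve)
            assert curve[k - 1] >= curve[0]


class TestAverageProbabilityFusion:
    class _Stub:
        def __init__(self, p):
            self.p = p
            self.classes_ = np.array([0, 1])

        def fit(self, X, y):
            return self

        def get_params(self, deep=True):
            return {"p": self.p}

        def set_params(self, **kw):
            self.p = kw.get("p", self.p)
            return self

        def predict_proba(self, X):
            return np.tile([1 - self.p, self.p], (len(X), 1))

    def _fit(self, probs):
        ens = AverageProbabilityEnsemble([(f"m{i}", self._Stub(p)) for i, p in enumerate(probs)])
        return ens.fit(np.zeros((4, 1)), np.array([0, 0, 1, 1]))

    def test_mean_of_member_probabilities(self):
        ens = self._fit([0.6, 0.8])
        np.testing.assert_allclose(ens.predict_proba(np.zeros((1, 1)))[:, 1], 0.7)
        assert ens.predict(np.zeros((1, 1)))[0] == 1

    def test_single_member_identity(self):
        ens = self._fit([0.3])
        np.testing.assert_allclose(ens.predict_proba(np.zeros((2, 1)))[:, 1], 0.3)

    def test_half_probability_tie_called_positive(self):
        ens = self._fit([0.4, 0.6])
        assert ens.predict(np.zeros((1, 1)))[0] == 1

    def test_permutation_invariance_of_members(self):
        a = self._fit([0.2, 0.5, 0.9]).predict_proba(np.zeros((3, 1)))
        b = self._fit([0.9, 0.2, 0.5]).predict_proba(np.zeros((3, 1)))
        np.testing.assert_allclose(a, b)

    def test_identical_members_match_single(self):
        single = self._fit([0.35]).predict_proba(np.zeros((2, 1)))
        triple = self._fit([0.35, 0.35, 0.35]).predict_proba(np.zeros((2, 1)))
        np.testing.assert_allclose(single, triple)


class TestEnsembleModel:
    def test_fit_predict_on_separable_data(self, separable_xy):
        X, y = separable_xy
        model = fit_ensemble(["RF", "J48"], default_registry(), X, y, ["f0", "f1"], seed=0)
        proba = model.predict_proba(X)
        assert proba.shape == (len(y),)
        assert np.all((proba >= 0) & (proba <= 1))
        assert (model.predict(X) == y).mean() > 0.9

    def test_schema_mismatch_rejected(self, separable_xy):
        X, y = separable_xy
        model = fit_ensemble(["RF"], default_registry(), X, y, ["f0", "f1"], seed=0)
        with pytest.raises(ValueError, match="schema"):
            model.predict_proba(X, feature_names=["other", "names"])
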
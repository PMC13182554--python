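"""Model tests: class weighting, CORAL, hierarchy, ensemble, tuner."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from odorstrength import models
from odorstrength.coral import CoralClassifier


class FixedPredictor(BaseEstimator, ClassifierMixin):
    """Stub returning a fixed prediction vector (for ensemble rule tests)."""

    def __init__(self, codes):
        self.codes = codes

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.asarray(self.codes)


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        y = np.repeat([0, 1, 2, 3], 10)
        assert all(w == pytest.approx(1.0) for w in models.class_weights(y).values())

    def test_weight_formula_arithmetic(self):
        y = np.repeat([0, 1, 2, 3], [40, 12, 100, 48])
        w = models.class_weights(y)
        assert w[1] == pytest.approx(200 / (4 * 12))  # the "low" minority
        assert w[2] == pytest.approx(200 / (4 * 100))


class TestModelSpec:
    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="unknown hyperparameters"):
            models.ModelSpec("logistic", {"n_estimators": 5})

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            models.ModelSpec("svm")

    @pytest.mark.parametrize("algo", models.ALGORITHMS)
    def test_factory_builds_every_family(self, algo):
        est = models.make_model(models.ModelSpec(algo, seed=1))
        assert hasattr(est, "fit")


def _separable_problem(n=200, seed=0):
    """Wide-margin single-feature ordinal problem; perfectly learnable."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 4, size=n)
    x = y * 10.0 + rng.uniform(-1, 1, size=n)  # margins of width 8
    X = np.column_stack([x, rng.normal(size=n)])
    return X, y


class TestDirect:
    def test_random_forest_fits_separable_data_perfectly(self):
        X, y = _separable_problem()
        model = models.train_direct(X, y, models.ModelSpec("random_forest", seed=0))
        assert (models.predict_ordinal(model, X) == y).mean() == 1.0

    def test_missing_class_raises(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        y = np.array([0, 1, 2] * 10)
        with pytest.raises(ValueError, match="four categories"):
            models.train_direct(X, y, models.ModelSpec("logistic"))

    def test_balanced_weighting_raises_minority_recall(self):
        """On 9:1 binary data the n/(K n_c) weights improve minority recall."""
        gains = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 400
            y = (rng.random(n) < 0.1).astype(int)
            X = y[:, None] * 1.2 + rng.normal(size=(n, 3))
            yt = (rng.random(n) < 0.1).astype(int)
            Xt = yt[:, None] * 1.2 + rng.normal(size=(n, 3))
            rec = {}
            for weighting in ("balanced", "none"):
                spec = models.ModelSpec("logistic", class_weighting=weighting, seed=seed)
                m = models.make_model(spec).fit(X, y)
                pred = m.predict(Xt)
                rec[weighting] = (pred[yt == 1] == 1).mean()
            gains.append(rec["balanced"] - rec["none"])
        assert np.mean(gains) > 0


class TestCoral:
    def test_rank_consistency_on_random_inputs(self):
        """Cumulative probabilities non-increasing for random fitted models."""
        rng = np.random.default_rng(0)
        for trial in range(10):
            X = rng.normal(size=(80, 4))
            y = rng.integers(0, 4, size=80)
            m = CoralClassifier(n_epochs=60, random_state=trial).fit(X, y)
            cum = m.predict_cumulative_proba(rng.normal(size=(100, 4)))
            assert np.all(np.diff(cum, axis=1) <= 1e-12)

    def test_recovers_constructed_threshold_problem(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-3, 3, size=(400, 1))
        y = (x[:, 0] > -1.5).astype(int) + (x[:, 0] > 0) + (x[:, 0] > 1.5)
        xt = rng.uniform(-3, 3, size=(400, 1))
        yt = (xt[:, 0] > -1.5).astype(int) + (xt[:, 0] > 0) + (xt[:, 0] > 1.5)
        m = CoralClassifier(random_state=0).fit(x, y)
        assert (m.predict(xt) == yt).mean() >= 0.95

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-3, 3, size=(300, 1))
        y = (x[:, 0] > -1).astype(int) + (x[:, 0] > 0.5) + (x[:, 0] > 2)
        xt = rng.uniform(-3, 3, size=(300, 1))
        m = CoralClassifier(random_state=3).fit(x, y)
        m_inv = CoralClassifier(random_state=3).fit(x, 3 - y)
        agree = ((3 - m_inv.predict(xt)) == m.predict(xt)).mean()
        assert agree >= 0.9  # stochastic-fit tolerance

    def test_predict_counts_cumulative_probabilities_above_half(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        m = CoralClassifier(n_epochs=50, random_state=0).fit(X, rng.integers(0, 4, 50))
        cum = m.predict_cumulative_proba(X)
        assert np.array_equal(m.predict(X), (cum > 0.5).sum(axis=1))

    def test_class_probabilities_normalized_and_consistent(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        m = CoralClassifier(n_epochs=50, random_state=0).fit(X, rng.integers(0, 4, 60))
        p = m.predict_proba(X)
        assert p.shape == (60, 4)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)


class TestHierarchical:
    def test_all_odorless_training_raises(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            models.HierarchicalOrdinalClassifier().fit(X, np.zeros(10, dtype=int))

    def test_perfect_stages_compose_to_truth(self):
        X, y = _separable_problem(n=300, seed=5)
        m = models.train_hierarchical(
            X, y, models.ModelSpec("random_forest", seed=0), models.ModelSpec("random_forest", seed=1)
        )
        assert (m.predict(X) == y).mean() == 1.0

    def test_stage1_odorless_overrides_stage2(self):
        X, y = _separable_problem(n=300, seed=6)
        m = models.train_hierarchical(
            X, y, models.ModelSpec("random_forest", seed=0), models.ModelSpec("random_forest", seed=1)
        )
        stage1_odorless = np.asarray(m.stage1_.predict(X), dtype=int) == 0
        assert np.all(m.predict(X)[stage1_odorless] == 0)


class TestEnsemble:
    def test_code_averaging_rounds_half_away_from_zero(self):
        X = np.zeros((3, 1))
        ens = models.OrdinalVoteEnsemble(
            [FixedPredictor([2, 1, 0]), FixedPredictor([2, 2, 0]), FixedPredictor([3, 0, 0])]
        )
        # means: (2.33, 1.0, 0.0) -> (2, 1, 0)
        assert ens.predict(X).tolist() == [2, 1, 0]
        ens2 = models.OrdinalVoteEnsemble([FixedPredictor([1, 0]), FixedPredictor([2, 0])])
        # mean 1.5 rounds to 2 (half away from zero)
        assert ens2.predict(np.zeros((2, 1))).tolist() == [2, 0]

    def test_identical_members_equal_any_member(self):
        X, y = _separable_problem(n=100, seed=7)
        member = models.train_direct(X, y, models.ModelSpec("random_forest", seed=0))
        ens = models.OrdinalVoteEnsemble([member, member, member])
        assert np.array_equal(ens.predict(X), member.predict(X))

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            models.OrdinalVoteEnsemble([FixedPredictor([0])])

    def test_member_predictions_retained_for_audit(self):
        ens = models.OrdinalVoteEnsemble([FixedPredictor([1, 2]), FixedPredictor([3, 2])])
        ens.predict(np.zeros((2, 1)))
        assert ens.member_predictions_.shape == (2, 2)


class TestTune:
    def _data(self):
        X, y = _separable_problem(n=160, seed=8)
        return X, y, np.arange(len(y))

    def test_budget_one_returns_single_spec(self):
        X, y, g = self._data()
        space = {"algorithm": "random_forest", "samplers": {"n_estimators": lambda r: int(r.integers(10, 30))}}
        best, trials = models.tune(space, X, y, g, budget=1, n_folds=3, n_repeats=1, seed=0)
        assert len(trials) == 1
        assert best is trials[0].spec

    def test_best_spec_has_best_completed_objective(self):
        X, y, g = self._data()
        space = {
            "algorithm": "random_forest",
            "samplers": {
                "n_estimators": lambda r: int(r.integers(5, 50)),
                "max_depth": lambda r: int(r.integers(1, 8)),
            },
        }
        best, trials = models.tune(space, X, y, g, budget=6, n_folds=3, n_repeats=2, seed=1)
        done = [t for t in trials if t.objective is not None]
        best_trial = next(t for t in done if t.spec is best)
        assert all(best_trial.objective <= t.objective for t in done)

    def test_trailing_trial_is_pruned(self):
        """A trial whose first repetition trails the 25th percentile by more
        than the tolerance gets marked pruned before finishing."""
        X, y, g = self._data()
        # depth-1 trees after several strong trials will trail badly
        calls = iter([30, 30, 30, 30, 30, 1])
        space = {"algorithm": "random_forest", "samplers": {"max_depth": lambda r: next(calls)}}
        _, trials = models.tune(space, X, y, g, budget=6, n_folds=3, n_repeats=2, seed=2,
                                prune_tolerance=0.02)
        assert trials[-1].pruned
        assert trials[-1].objective is None

    def test_invalid_budget(self):
        X, y, g = self._data()
        with pytest.raises(ValueError):
            models.tune({"algorithm": "xgb"}, X, y, g, budget=0)


class TestBundle:
    def test_roundtrip_preserves_predictions_and_standardization(self, tmp_path):
        X, y = _separable_problem(n=120, seed=9)
        spec = models.ModelSpec("logistic", seed=0)
        model = models.train_direct(X, y, spec)
        models.save_bundle(tmp_path / "b", model, spec, "descriptors", {"radius": 3}, seed=0)
        loaded, manifest = models.load_bundle(tmp_path / "b")
        assert np.array_equal(loaded.predict(X), model.predict(X))
        assert manifest["encoder_id"] == "descriptors"
        assert manifest["standardization"] is not None  # logistic is standardized
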
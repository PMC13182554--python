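"""Ordinal odor-strength learners.

Direct approach: one 4-class learner (logistic regression, random forest,
XGBoost, MLP, or CORAL) over all categories, with cost-sensitive class
weights n/(K*n_k). Hierarchical (indirect) approach: stage 1 decides
odorous-vs-odorless, stage 2 grades the strength of the truly odorous
training records; at prediction time stage 2 only sees records stage 1 called
odorous. The descriptor ensemble averages member ordinal codes and rounds
half away from zero.

Everything is a scikit-learn estimator; linear/MLP/CORAL families are wrapped
in a standardization pipeline whose constants ship with the model bundle.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .coral import CoralClassifier

ALGORITHMS = ("logistic", "random_forest", "xgb", "mlp", "coral")
#: families that consume standardized features; trees take raw values
STANDARDIZED = ("logistic", "mlp", "coral")

_SCHEMA: dict[str, set[str]] = {
    "logistic": {"C", "max_iter", "penalty"},
    "random_forest": {"n_estimators", "max_depth", "min_samples_leaf", "max_features"},
    "xgb": {"n_estimators", "max_depth", "learning_rate", "subsample", "colsample_bytree", "reg_lambda"},
    "mlp": {"hidden_layer_sizes", "alpha", "learning_rate_init", "max_iter"},
    "coral": {"hidden_layer_size", "n_epochs", "learning_rate", "l2"},
}


@dataclass
class ModelSpec:
    """Algorithm choice plus validated hyperparameters."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    class_weighting: str = "balanced"  # "balanced" or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        unknown = set(self.hyperparameters) - _SCHEMA[self.algorithm]
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.algorithm}: {sorted(unknown)}")
        if self.class_weighting not in ("balanced", "none"):
            raise ValueError("class_weighting must be 'balanced' or 'none'")


def class_weights(y: Sequence[int]) -> dict[int, float]:
    """Cost-sensitive weights w_c = n / (K * n_c) over the classes present."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    k = len(classes)
    return {int(c): len(y) / (k * n) for c, n in zip(classes, counts)}


def _balanced_resample(X, y, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded weighted bootstrap to the n/(K*n_c) weights (for learners
    without native sample-weight support)."""
    y = np.asarray(y)
    w = np.asarray([class_weights(y)[int(c)] for c in y], dtype=float)
    rng = np.random.Generator(np.random.PCG64(seed))
    idx = rng.choice(len(y), size=len(y), replace=True, p=w / w.sum())
    return np.asarray(X)[idx], y[idx]


def make_model(spec: ModelSpec) -> BaseEstimator:
    """Unfitted sklearn estimator for a spec; standardization included where due."""
    hp = dict(spec.hyperparameters)
    balanced = spec.class_weighting == "balanced"
    if spec.algorithm == "logistic":
        est = LogisticRegression(
            max_iter=hp.pop("max_iter", 2000),
            class_weight="balanced" if balanced else None,
            random_state=spec.seed,
            **hp,
        )
    elif spec.algorithm == "random_forest":
        est = RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 300),
            class_weight="balanced" if balanced else None,
            random_state=spec.seed,
            n_jobs=1,
            **hp,
        )
    elif spec.algorithm == "xgb":
        est = _WeightedXGB(balanced=balanced, seed=spec.seed, hp=hp)
    elif spec.algorithm == "mlp":
        est = _ResampledMLP(balanced=balanced, seed=spec.seed, hp=hp)
    else:
        est = CoralClassifier(
            class_weight="balanced" if balanced else None, random_state=spec.seed, **hp
        )
    if spec.algorithm in STANDARDIZED:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


class _WeightedXGB(BaseEstimator, ClassifierMixin):
    """XGBoost classifier applying n/(K*n_c) sample weights at fit time."""

    def __init__(self, balanced: bool = True, seed: int = 0, hp: dict | None = None):
        self.balanced = balanced
        self.seed = seed
        self.hp = hp

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        hp = {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1, **(self.hp or {})}
        self.model_ = XGBClassifier(
            random_state=self.seed, n_jobs=1, eval_metric="mlogloss", **hp
        )
        sw = None
        if self.balanced:
            cw = class_weights(y_enc)
            sw = np.asarray([cw[int(c)] for c in y_enc])
        self.model_.fit(np.asarray(X), y_enc, sample_weight=sw)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.classes_[self.model_.predict(np.asarray(X))]

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X))

    def get_booster(self):
        return self.model_.get_booster()


class _ResampledMLP(BaseEstimator, ClassifierMixin):
    """sklearn MLP with balanced weighting realized by seeded bootstrap."""

    def __init__(self, balanced: bool = True, seed: int = 0, hp: dict | None = None):
        self.balanced = balanced
        self.seed = seed
        self.hp = hp

    def fit(self, X, y):
        hp = {"hidden_layer_sizes": (64,), "max_iter": 400, **(self.hp or {})}
        if isinstance(hp["hidden_layer_sizes"], list):
            hp["hidden_layer_sizes"] = tuple(hp["hidden_layer_sizes"])
        self.model_ = MLPClassifier(random_state=self.seed, **hp)
        if self.balanced:
            X, y = _balanced_resample(X, y, self.seed)
        self.model_.fit(np.asarray(X), np.asarray(y))
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X))

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X))


def train_direct(X, y, spec: ModelSpec) -> BaseEstimator:
    """Fit a 4-class direct learner; requires every category in the training data."""
    y = np.asarray(y)
    if len(np.unique(y)) < 4:
        raise ValueError("direct approach requires all four categories in training data")
    return make_model(spec).fit(np.asarray(X), y)


def predict_ordinal(model: BaseEstimator, X) -> np.ndarray:
    """Predicted ordinal codes (argmax for classifiers, threshold count for CORAL)."""
    return np.asarray(model.predict(np.asarray(X)), dtype=int)


class HierarchicalOrdinalClassifier(BaseEstimator, ClassifierMixin):
    """Two-step indirect predictor: odorous-vs-odorless, then strength 1..3.

    Stage 1 trains on the binary target 1{y > 0} with minority-sensitive
    weighting; stage 2 trains on the *truly* odorous records only. Prediction
    composes the stages: records stage 1 calls odorless get code 0.
    """

    def __init__(self, stage1_spec: ModelSpec | None = None, stage2_spec: ModelSpec | None = None):
        self.stage1_spec = stage1_spec
        self.stage2_spec = stage2_spec

    def fit(self, X, y):
        X, y = np.asarray(X), np.asarray(y)
        odorous = y > 0
        if not odorous.any() or len(np.unique(y[odorous])) < 3:
            raise ValueError("stage 2 needs classes 1..3 among the odorous training records")
        s1 = self.stage1_spec or ModelSpec("random_forest")
        s2 = self.stage2_spec or ModelSpec("random_forest")
        self.stage1_ = make_model(s1).fit(X, odorous.astype(int))
        self.stage2_ = make_model(s2).fit(X[odorous], y[odorous])
        self.classes_ = np.array([0, 1, 2, 3])
        return self

    def predict(self, X):
        check_is_fitted(self, "stage1_")
        X = np.asarray(X)
        out = np.zeros(len(X), dtype=int)
        odorous = np.asarray(self.stage1_.predict(X), dtype=int) == 1
        if odorous.any():
            out[odorous] = np.asarray(self.stage2_.predict(X[odorous]), dtype=int)
        return out


def train_hierarchical(X, y, spec1: ModelSpec, spec2: ModelSpec) -> HierarchicalOrdinalClassifier:
    return HierarchicalOrdinalClassifier(spec1, spec2).fit(X, y)


class OrdinalVoteEnsemble(BaseEstimator, ClassifierMixin):
    """Average of member ordinal codes, rounded half away from zero.

    ``average="proba"`` switches to averaging per-class probabilities and
    taking the argmax instead. Member predictions are retained on the
    instance for audit after each ``predict``.
    """

    def __init__(self, members: Sequence[BaseEstimator], average: str = "codes"):
        if len(members) < 2:
            raise ValueError("ensemble needs at least two members")
        if average not in ("codes", "proba"):
            raise ValueError("average must be 'codes' or 'proba'")
        self.members = list(members)
        self.average = average

    def fit(self, X, y):
        self.members_ = [clone(m).fit(np.asarray(X), np.asarray(y)) for m in self.members]
        self.classes_ = np.unique(np.asarray(y))
        return self

    def _fitted_members(self):
        return getattr(self, "members_", self.members)

    def predict(self, X):
        X = np.asarray(X)
        members = self._fitted_members()
        self.member_predictions_ = np.stack(
            [np.asarray(m.predict(X), dtype=int) for m in members]
        )
        if self.average == "proba":
            probs = np.mean([m.predict_proba(X) for m in members], axis=0)
            return np.argmax(probs, axis=1)
        mean = self.member_predictions_.mean(axis=0)
        # round half away from zero, clip to the valid code range
        codes = np.floor(mean + 0.5).astype(int)
        return np.clip(codes, 0, 3)

    def predict_proba(self, X):
        members = self._fitted_members()
        return np.mean([m.predict_proba(np.asarray(X)) for m in members], axis=0)


def ensemble_predict(models: Sequence[BaseEstimator], X, average: str = "codes") -> np.ndarray:
    return OrdinalVoteEnsemble(list(models), average=average).predict(X)


@dataclass
class Trial:
    spec: ModelSpec
    scores: list[float]
    pruned: bool
    objective: float | None


def tune(
    spec_space: dict,
    X,
    y,
    groups,
    budget: int = 100,
    objective: str = "macro_mse",
    n_folds: int = 5,
    n_repeats: int = 3,
    seed: int = 0,
    prune_tolerance: float | None = None,
) -> tuple[ModelSpec, list[Trial]]:
    """Budgeted sequential hyperparameter search with 25th-percentile pruning.

    ``spec_space`` maps ``algorithm`` to a name plus per-hyperparameter
    samplers (callables taking an rng). Each trial is scored by repeated
    grouped+stratified CV; after each repetition a trial trailing the 25th
    percentile of completed objectives by more than the tolerance (0.02 for
    macro MSE, 0.015 for minority F1) is pruned. Returns the best spec and
    the full trial ledger.
    """
    from .evaluate import macro_mse
    from .split import RepeatedGroupedStratifiedKFold
    from sklearn.metrics import f1_score

    if budget < 1:
        raise ValueError("budget must be >= 1")
    if objective not in ("macro_mse", "minority_f1"):
        raise ValueError("objective must be 'macro_mse' or 'minority_f1'")
    minimize = objective == "macro_mse"
    tol = prune_tolerance if prune_tolerance is not None else (0.02 if minimize else 0.015)

    X, y, groups = np.asarray(X), np.asarray(y), np.asarray(groups)
    rng = np.random.Generator(np.random.PCG64(seed))
    algorithm = spec_space["algorithm"]
    samplers: dict[str, Callable] = spec_space.get("samplers", {})

    cv = RepeatedGroupedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats, seed=seed)
    assignments = cv.fold_assignments(y, groups)

    def score_fold(spec: ModelSpec, train_idx, val_idx) -> float:
        model = make_model(spec).fit(X[train_idx], y[train_idx])
        pred = predict_ordinal(model, X[val_idx])
        if minimize:
            return macro_mse(y[val_idx], pred)
        minority = np.argmin(np.bincount(y[train_idx], minlength=2)[: len(np.unique(y))])
        return f1_score(y[val_idx], pred, pos_label=int(minority), average="binary" if len(np.unique(y)) == 2 else "macro")

    trials: list[Trial] = []
    completed: list[float] = []
    for _ in range(budget):
        hp = {name: fn(rng) for name, fn in samplers.items()}
        spec = ModelSpec(algorithm, hp, seed=int(rng.integers(2**31)))
        rep_means, pruned = [], False
        for r in range(n_repeats):
            folds = assignments[r]
            fold_scores = [
                score_fold(spec, np.where(folds != f)[0], np.where(folds == f)[0])
                for f in range(n_folds)
            ]
            rep_means.append(float(np.mean(fold_scores)))
            if len(completed) >= 4:
                q25 = np.percentile(completed, 25)
                running = float(np.mean(rep_means))
                behind = (running - q25) if minimize else (q25 - running)
                if behind > tol and r < n_repeats - 1:
                    pruned = True
                    break
        obj = None if pruned else float(np.mean(rep_means))
        if obj is not None:
            completed.append(obj)
        trials.append(Trial(spec=spec, scores=rep_means, pruned=pruned, objective=obj))

    done = [t for t in trials if t.objective is not None]
    best = min(done, key=lambda t: t.objective) if minimize else max(done, key=lambda t: t.objective)
    return best.spec, trials


def save_bundle(path: str | Path, model: BaseEstimator, spec: ModelSpec | None, encoder_id: str, encoder_params: dict, seed: int) -> None:
    """Serialize a fitted model with its encoder identity and spec manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "model.pkl", "wb") as fh:
        pickle.dump(model, fh)
    manifest = {
        "encoder_id": encoder_id,
        "encoder_params": encoder_params,
        "seed": seed,
        "spec": None if spec is None else {
            "algorithm": spec.algorithm,
            "hyperparameters": spec.hyperparameters,
            "class_weighting": spec.class_weighting,
            "seed": spec.seed,
        },
    }
    scaler = None
    if isinstance(model, Pipeline) and "scale" in model.named_steps:
        sc = model.named_steps["scale"]
        scaler = {"mean": sc.mean_.tolist(), "scale": sc.scale_.tolist()}
    manifest["standardization"] = scaler
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_bundle(path: str | Path) -> tuple[BaseEstimator, dict]:
    path = Path(path)
    with open(path / "model.pkl", "rb") as fh:
        model = pickle.load(fh)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    return model, manifest
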
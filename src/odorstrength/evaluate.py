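"""Evaluation of ordinal odor-strength predictions.

The headline metric is the macro-averaged mean squared error: the MSE between
ordinal codes is computed separately within each true category and the
per-category MSEs are averaged without sample weighting, so minority
categories count as much as the majority. Categories absent from y_true are
excluded and the number of included categories is reported. Companion
metrics: micro MSE, macro/micro F1, one-vs-rest macro ROC AUC, and the
row-normalized confusion matrix.

Model comparison uses the 5x2cv paired t-test: five replications of 2-fold
CV; with score differences p_i^(j) (replication i, fold j), per-replication
variance s_i^2 = (p_i^(1) - p_bar_i)^2 + (p_i^(2) - p_bar_i)^2 and

    t = p_1^(1) / sqrt(mean_i s_i^2),   p two-sided from t with 5 dof.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score

from .split import GroupedStratifiedKFold

N_CLASSES = 4


def per_class_mse(y_true, y_pred) -> dict[int, float]:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    out = {}
    for c in np.unique(y_true):
        mask = y_true == c
        out[int(c)] = float(np.mean((y_pred[mask] - y_true[mask]) ** 2))
    return out


def macro_mse(y_true, y_pred) -> float:
    """Unweighted mean of per-true-category MSEs over categories present."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("inputs must be nonempty and equal length")
    return float(np.mean(list(per_class_mse(y_true, y_pred).values())))


def micro_mse(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    return float(np.mean((y_pred - y_true) ** 2))


@dataclass
class EvaluationReport:
    macro_mse: float
    micro_mse: float
    f1_macro: float
    f1_micro: float
    roc_auc: float | None
    confusion: np.ndarray
    confusion_normalized: np.ndarray
    per_class: dict[int, dict[str, float]]
    n_test: int
    n_categories_present: int
    empty_rows: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "macro_mse": self.macro_mse,
            "micro_mse": self.micro_mse,
            "f1_macro": self.f1_macro,
            "f1_micro": self.f1_micro,
            "roc_auc": self.roc_auc,
            "confusion": self.confusion.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "n_test": self.n_test,
            "n_categories_present": self.n_categories_present,
            "empty_rows": self.empty_rows,
        }


def report(y_true, y_pred, probabilities=None) -> EvaluationReport:
    """Full evaluation report; ROC AUC only when probabilities are supplied."""
    y_true, y_pred = np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("inputs must be nonempty and equal length")
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[t, p] += 1
    row_tot = confusion.sum(axis=1, keepdims=True)
    empty = [int(i) for i in range(N_CLASSES) if row_tot[i, 0] == 0]
    normalized = np.divide(
        confusion, row_tot, out=np.zeros_like(confusion, dtype=float), where=row_tot > 0
    )
    auc = None
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        if np.max(np.abs(probabilities.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("probability rows must sum to 1 within 1e-6")
        present = sorted(set(y_true.tolist()))
        if len(present) > 1:
            auc = float(
                roc_auc_score(y_true, probabilities[:, present] if len(present) < N_CLASSES else probabilities,
                              multi_class="ovr", average="macro", labels=present)
            )
    mses = per_class_mse(y_true, y_pred)
    per_class = {}
    for c in range(N_CLASSES):
        if row_tot[c, 0] == 0:
            continue
        per_class[c] = {
            "precision": float(precision_score(y_true, y_pred, labels=[c], average="macro", zero_division=0)),
            "recall": float(recall_score(y_true, y_pred, labels=[c], average="macro", zero_division=0)),
            "f1": float(f1_score(y_true, y_pred, labels=[c], average="macro", zero_division=0)),
            "mse": mses[c],
        }
    return EvaluationReport(
        macro_mse=macro_mse(y_true, y_pred),
        micro_mse=micro_mse(y_true, y_pred),
        f1_macro=float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        f1_micro=float(f1_score(y_true, y_pred, average="micro", zero_division=0)),
        roc_auc=auc,
        confusion=confusion,
        confusion_normalized=normalized,
        per_class=per_class,
        n_test=len(y_true),
        n_categories_present=len(mses),
        empty_rows=empty,
    )


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    dof: int
    score_pairs: list[tuple[float, float]]  # (score_A, score_B) per (rep, fold)
    infinite: bool = False


def t_from_differences(diffs: np.ndarray) -> tuple[float, float, bool]:
    """(t, p, infinite) from the 5x2 matrix of per-fold score differences."""
    diffs = np.asarray(diffs, dtype=float)
    bar = diffs.mean(axis=1, keepdims=True)
    s2 = ((diffs - bar) ** 2).sum(axis=1)
    denom = np.sqrt(s2.mean())
    if denom == 0.0:
        if diffs[0, 0] == 0.0:
            return 0.0, 1.0, False
        return float(np.inf) * float(np.sign(diffs[0, 0])), 0.0, True
    t = float(diffs[0, 0] / denom)
    return t, float(2 * stats.t.sf(abs(t), df=5)), False


def paired_ttest_5x2cv(
    learner_a: BaseEstimator,
    learner_b: BaseEstimator,
    X,
    y,
    groups=None,
    metric: Callable | None = None,
    seed: int = 0,
) -> PairedTestResult:
    """5x2cv paired t-test between two learners on grouped+stratified folds.

    Degenerate conventions: zero variance with zero first difference gives
    t=0, p=1; zero variance with a nonzero difference is flagged infinite.
    """
    metric = metric or macro_mse
    X, y = np.asarray(X), np.asarray(y)
    groups = np.arange(len(y)) if groups is None else np.asarray(groups)

    diffs = np.zeros((5, 2))
    pairs = []
    for i in range(5):
        cv = GroupedStratifiedKFold(n_splits=2, seed=seed * 31 + i)
        for j, (train_idx, test_idx) in enumerate(cv.split(X, y, groups)):
            ma = clone(learner_a).fit(X[train_idx], y[train_idx])
            mb = clone(learner_b).fit(X[train_idx], y[train_idx])
            sa = metric(y[test_idx], np.asarray(ma.predict(X[test_idx])))
            sb = metric(y[test_idx], np.asarray(mb.predict(X[test_idx])))
            diffs[i, j] = sa - sb
            pairs.append((float(sa), float(sb)))
    t, p, infinite = t_from_differences(diffs)
    return PairedTestResult(t, p, 5, pairs, infinite=infinite)


def ordinal_vs_continuous(pred_codes, continuous_ratings) -> dict:
    """Spearman rank correlation plus per-code rating mean/sd.

    Flags the correlation undefined when either input is constant.
    """
    codes = np.asarray(pred_codes)
    ratings = np.asarray(continuous_ratings, dtype=float)
    if len(codes) != len(ratings):
        raise ValueError("inputs must have equal length")
    undefined = len(np.unique(codes)) < 2 or len(np.unique(ratings)) < 2
    if undefined:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(codes, ratings).statistic)
    summary = {}
    for c in np.unique(codes):
        r = ratings[codes == c]
        summary[int(c)] = {"mean": float(r.mean()), "sd": float(r.std(ddof=0)), "n": int(len(r))}
    return {"spearman_rho": rho, "undefined": undefined, "per_code": summary}
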
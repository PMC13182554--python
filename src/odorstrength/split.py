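"""Leakage-aware grouped + stratified data splitting.

Molecules with Tanimoto similarity >= threshold (bit Morgan fingerprints,
radius 3, 2048 bits) are merged into similarity groups (connected components
of the similarity graph) and every group travels atomically: either wholly in
the training set or wholly in the test set / one CV fold. Stratification acts
on each group's majority label (ties broken toward the lower category).

The splitters follow the scikit-learn cross-validator protocol
(``split(X, y, groups)`` yielding index pairs, ``get_n_splits``) so they plug
into sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import BaseCrossValidator

from . import featurize

DEFAULT_SIMILARITY_THRESHOLD = 0.8


@dataclass
class SplitPlan:
    """Similarity groups plus holdout and per-repeat fold membership."""

    group_id: np.ndarray  # (n,)
    holdout: np.ndarray  # (n,) bool
    fold_id: np.ndarray | None  # (n_repeats, n) int, -1 = holdout record
    seed: int
    params: dict

    def to_frame(self, keys: Sequence[str] | None = None) -> pd.DataFrame:
        n = len(self.group_id)
        data = {"key": list(keys) if keys is not None else list(range(n)),
                "group_id": self.group_id, "holdout": self.holdout.astype(int)}
        if self.fold_id is not None:
            for r in range(self.fold_id.shape[0]):
                data[f"fold_repeat{r}"] = self.fold_id[r]
        return pd.DataFrame(data)


def similarity_groups(
    smiles_list: Sequence[str], threshold: float = DEFAULT_SIMILARITY_THRESHOLD
) -> np.ndarray:
    """Connected components of the Tanimoto >= threshold graph.

    Group ids are contiguous integers ordered by first member appearance.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    fps = featurize.fingerprints(smiles_list, kind="morgan_bits")
    n = len(fps)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if featurize.tanimoto(fps[i], fps[j]) >= threshold:
                parent[find(i)] = find(j)
    roots, ids = {}, np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        ids[i] = roots[r]
    return ids


def _group_labels(labels: np.ndarray, groups: np.ndarray) -> dict[int, int]:
    """Majority member label per group; ties resolved to the lower category."""
    out = {}
    for g in np.unique(groups):
        counts = np.bincount(labels[groups == g], minlength=4)
        out[int(g)] = int(np.argmax(counts))  # argmax takes the first (lowest) on ties
    return out


def grouped_stratified_holdout(
    labels: Sequence[int],
    groups: Sequence[int],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Boolean holdout mask assigning groups atomically, stratified by group label.

    Greedy randomized packing: per-class test-count targets are filled by
    groups visited largest-first (seeded shuffle breaks size ties); a group
    joins the test side while at least half its size fits the remaining
    per-class deficit.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups, dtype=int)
    n = len(labels)
    sizes = {int(g): int((groups == g).sum()) for g in np.unique(groups)}
    biggest = max(sizes.values())
    if biggest > max(test_fraction, 1 - test_fraction) * n:
        g = max(sizes, key=sizes.get)
        raise ValueError(
            f"similarity group {g} holds {biggest}/{n} records, exceeding both "
            "split sides; cannot split without leakage"
        )
    glab = _group_labels(labels, groups)
    rng = np.random.Generator(np.random.PCG64(seed))
    order = list(sizes)
    rng.shuffle(order)
    order.sort(key=lambda g: -sizes[g])
    class_totals = np.bincount(labels, minlength=4)
    deficit = np.rint(test_fraction * class_totals).astype(int)
    holdout = np.zeros(n, dtype=bool)
    for g in order:
        lab, size = glab[g], sizes[g]
        if deficit[lab] >= (size + 1) // 2:
            holdout[groups == g] = True
            deficit[lab] -= size
    return holdout


class GroupedStratifiedKFold(BaseCrossValidator):
    """K folds over similarity groups, stratified on group majority labels.

    Greedy packing, largest group first (seeded tie shuffle): each group goes
    to the currently smallest fold, ties broken by the largest remaining
    per-class deficit for the group's label.
    """

    def __init__(self, n_splits: int = 10, seed: int = 0):
        self.n_splits = n_splits
        self.seed = seed

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def fold_assignment(self, y, groups) -> np.ndarray:
        y = np.asarray(y, dtype=int)
        groups = np.asarray(groups, dtype=int)
        uniq = np.unique(groups)
        if self.n_splits > len(uniq):
            raise ValueError(f"n_splits={self.n_splits} exceeds the {len(uniq)} similarity groups")
        sizes = {int(g): int((groups == g).sum()) for g in uniq}
        glab = _group_labels(y, groups)
        rng = np.random.Generator(np.random.PCG64(self.seed))
        order = list(sizes)
        rng.shuffle(order)
        order.sort(key=lambda g: -sizes[g])
        targets = np.bincount(y, minlength=4)[None, :] / self.n_splits  # per-fold per-class
        fold_class = np.zeros((self.n_splits, 4))
        fold_size = np.zeros(self.n_splits)
        gfold = {}
        for g in order:
            lab = glab[g]
            deficit = targets[0, lab] - fold_class[:, lab]
            # balance fold sizes first, then the group label's stratification deficit
            best = np.lexsort((-deficit, fold_size))[0]
            gfold[g] = int(best)
            fold_class[best, lab] += sizes[g]
            fold_size[best] += sizes[g]
        return np.array([gfold[int(g)] for g in groups])

    def _iter_test_masks(self, X=None, y=None, groups=None):
        folds = self.fold_assignment(y, groups)
        for f in range(self.n_splits):
            yield folds == f

    def split(self, X, y=None, groups=None) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        indices = np.arange(len(np.asarray(y)))
        for mask in self._iter_test_masks(X, y, groups):
            yield indices[~mask], indices[mask]


class RepeatedGroupedStratifiedKFold(BaseCrossValidator):
    """n_repeats independent grouped+stratified K-fold partitions, derived seeds."""

    def __init__(self, n_splits: int = 10, n_repeats: int = 10, seed: int = 0):
        self.n_splits = n_splits
        self.n_repeats = n_repeats
        self.seed = seed

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits * self.n_repeats

    def _repeat_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.seed).spawn(self.n_repeats)
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    def fold_assignments(self, y, groups) -> np.ndarray:
        return np.stack(
            [
                GroupedStratifiedKFold(self.n_splits, seed=s).fold_assignment(y, groups)
                for s in self._repeat_seeds()
            ]
        )

    def split(self, X, y=None, groups=None) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        indices = np.arange(len(np.asarray(y)))
        for assignment in self.fold_assignments(y, groups):
            for f in range(self.n_splits):
                mask = assignment == f
                yield indices[~mask], indices[mask]


def make_split_plan(
    smiles_list: Sequence[str],
    labels: Sequence[int],
    test_fraction: float = 0.2,
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Complete split plan: groups, 80/20 holdout, repeated K-fold on the rest."""
    labels = np.asarray(labels, dtype=int)
    groups = similarity_groups(smiles_list, similarity_threshold)
    holdout = grouped_stratified_holdout(labels, groups, test_fraction, seed)
    train_idx = np.where(~holdout)[0]
    cv = RepeatedGroupedStratifiedKFold(n_folds, n_repeats, seed=seed + 1)
    sub = cv.fold_assignments(labels[train_idx], groups[train_idx])
    fold_id = -np.ones((n_repeats, len(labels)), dtype=int)
    fold_id[:, train_idx] = sub
    return SplitPlan(
        group_id=groups,
        holdout=holdout,
        fold_id=fold_id,
        seed=seed,
        params={
            "test_fraction": test_fraction,
            "n_folds": n_folds,
            "n_repeats": n_repeats,
            "similarity_threshold": similarity_threshold,
        },
    )
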
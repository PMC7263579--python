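"""Sequential forward feature selection with cross-validated accuracy.

Greedy wrapper selection: at each step the candidate feature whose
inclusion maximizes stratified 10-fold cross-validated accuracy of a
linear maximum-margin classifier is added, ties broken by lowest
feature index. Fold assignment is seeded and reused across all
candidate evaluations within a run, so results are reproducible.

Normalization: by default the mean/variance scaler is fit on the
training folds only (no leakage into the held-out fold); ``paper_mode``
switches to one global normalization of the whole table before
cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

__all__ = ["SelectionResult", "sfs"]


@dataclass(frozen=True)
class SelectionResult:
    """Ordered selected feature indices with the CV accuracy after each step."""

    ordered_indices: tuple[int, ...]
    step_accuracies: tuple[float, ...]
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.ordered_indices)) != len(self.ordered_indices):
            raise ValueError("selected indices must be unique")
        if len(self.step_accuracies) != len(self.ordered_indices):
            raise ValueError("one step accuracy per selected feature required")

    @property
    def k(self) -> int:
        return len(self.ordered_indices)


def _check_class_sizes(y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    for c, n in zip(classes, counts):
        if n < folds:
            raise ValueError(
                f"class {c!r} has only {n} samples; needs at least {folds} for {folds}-fold CV"
            )


def _scaled(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, splits, scale_per_fold: bool, seed: int
) -> float:
    correct = 0
    for train, test in splits:
        Xtr, Xte = X[train], X[test]
        if scale_per_fold:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        clf = LinearSVC(C=1.0, tol=1e-3, max_iter=5000, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Xtr, y[train])
        correct += int((clf.predict(Xte) == y[test]).sum())
    return correct / len(y)


def sfs(
    X,
    y,
    k: int = 7,
    folds: int = 10,
    seed: int = 0,
    early_stop: bool = False,
    paper_mode: bool = False,
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Sequential forward selection of up to ``k`` features.

    Parameters
    ----------
    X : (n, p) array or DataFrame of feature values.
    y : (n,) labels (any hashable classes).
    k : maximum number of features to select (default 7).
    folds : stratified CV folds used to score each candidate set.
    seed : controls fold assignment (and the classifier's internal state).
    early_stop : stop as soon as no candidate improves the accuracy.
    paper_mode : normalize the whole table once, globally, instead of
        per training fold.
    """
    if hasattr(X, "columns") and feature_names is None:
        feature_names = [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 0 or k > X.shape[1]:
        raise ValueError(f"k must be in 0..{X.shape[1]}")
    _check_class_sizes(y, folds)
    if k == 0:
        return SelectionResult((), ())

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    if paper_mode:
        X = _scaled(X)

    selected: list[int] = []
    accs: list[float] = []
    remaining = list(range(X.shape[1]))
    for _ in range(k):
        best_idx, best_acc = None, -1.0
        for cand in remaining:  # ascending index -> lowest-index tie-break
            acc = _cv_accuracy(
                X[:, selected + [cand]], y, splits,
                scale_per_fold=not paper_mode, seed=seed,
            )
            if acc > best_acc:
                best_idx, best_acc = cand, acc
        if early_stop and accs and best_acc <= accs[-1]:
            break
        selected.append(best_idx)
        accs.append(best_acc)
        remaining.remove(best_idx)
    names = tuple(feature_names[i] for i in selected) if feature_names else ()
    return SelectionResult(tuple(selected), tuple(accs), names)
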
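"""Classifier evaluation, the texture index, DeLong AUC comparison, t-SNE.

Multiclass evaluation pools out-of-fold predictions of a stratified
10-fold cross-validation into one confusion matrix; one-vs-all ROC
curves are built from the pooled decision scores and their AUCs carry
DeLong (placement-value) normal confidence intervals.

The texture index ``Tx = b0 + b1*x1 + ... + bn*xn`` is an ordinary
least-squares fit of a +/-1 cohort coding on the selected features; a
positive Tx indicates the first-listed (+1) cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_NAMES",
    "EvalReport",
    "TextureIndexModel",
    "cross_validated_eval",
    "texture_index_fit",
    "texture_index_apply",
    "delong_test",
    "delong_auc_ci",
    "embed_2d",
]

CLASSIFIER_NAMES = ("linear-svm", "rbf-svm", "knn", "ensemble-trees")


def _make_classifier(name: str, seed: int):
    # SVC: one-vs-one voting for prediction, one-vs-all-shaped decision scores.
    if name == "linear-svm":
        return SVC(kernel="linear", C=1.0, decision_function_shape="ovr", random_state=seed)
    if name == "rbf-svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", decision_function_shape="ovr",
                   random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "ensemble-trees":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


@dataclass(frozen=True)
class EvalReport:
    """Pooled cross-validated multiclass results for one classifier."""

    classifier: str
    classes: tuple
    accuracy: float
    confusion: np.ndarray                     # (C, C), rows = true class
    sensitivity: dict
    specificity: dict
    roc_curves: dict                          # class -> (fpr, tpr)
    auc: dict                                 # class -> (auc, lo, hi)
    seed: int
    n: int
    scores: np.ndarray = field(repr=False, default=None)   # (n, C) pooled OOF scores
    y_true: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "classes": [str(c) for c in self.classes],
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "sensitivity": {str(k): v for k, v in self.sensitivity.items()},
            "specificity": {str(k): v for k, v in self.specificity.items()},
            "auc": {str(k): list(v) for k, v in self.auc.items()},
            "seed": self.seed,
            "n": self.n,
        }


def cross_validated_eval(
    X,
    y,
    classifier: str = "linear-svm",
    folds: int = 10,
    seed: int = 0,
    paper_mode: bool = False,
) -> EvalReport:
    """Stratified k-fold evaluation with per-fold mean/variance normalization.

    Out-of-fold predictions and decision scores are pooled over all
    folds; deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < folds):
        small = classes[counts < folds][0]
        raise ValueError(f"class {small!r} has fewer samples than folds={folds}")

    if paper_mode:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    n = len(y)
    scores = np.zeros((n, len(classes)))
    preds = np.empty(n, dtype=y.dtype)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        Xtr, Xte = X[train], X[test]
        if not paper_mode:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
        clf = _make_classifier(classifier, seed)
        clf.fit(Xtr, y[train])
        preds[test] = clf.predict(Xte)
        if hasattr(clf, "decision_function"):
            s = clf.decision_function(Xte)
            if s.ndim == 1:  # binary: expand to per-class columns
                s = np.column_stack([-s, s])
        else:
            s = clf.predict_proba(Xte)
        # align score columns with the global class order
        order = [list(clf.classes_).index(c) for c in classes]
        scores[test] = s[:, order]

    conf = confusion_matrix(y, preds, labels=classes)
    accuracy = float(np.trace(conf)) / n
    sens, spec, rocs, aucs = {}, {}, {}, {}
    for ci, c in enumerate(classes):
        tp = conf[ci, ci]
        fn = conf[ci].sum() - tp
        fp = conf[:, ci].sum() - tp
        tn = conf.sum() - tp - fn - fp
        sens[c] = tp / (tp + fn) if tp + fn else 0.0
        spec[c] = tn / (tn + fp) if tn + fp else 0.0
        y_bin = (y == c).astype(int)
        fpr, tpr, _ = roc_curve(y_bin, scores[:, ci])
        rocs[c] = (fpr, tpr)
        aucs[c] = delong_auc_ci(scores[:, ci], y_bin)
    return EvalReport(
        classifier=classifier, classes=tuple(classes), accuracy=accuracy,
        confusion=conf, sensitivity=sens, specificity=spec, roc_curves=rocs,
        auc=aucs, seed=seed, n=n, scores=scores, y_true=y,
    )


# ---------------------------------------------------------------- texture index

@dataclass(frozen=True)
class TextureIndexModel:
    """OLS texture-index model: Tx = beta0 + sum_i beta_i x_i."""

    beta0: float
    betas: np.ndarray
    positive_class: object = None
    negative_class: object = None


def texture_index_fit(X_sel, y_binary, classes: tuple | None = None) -> TextureIndexModel:
    """Least-squares fit of a +/-1 cohort coding on the selected features.

    ``y_binary`` must be coded +1 (first-listed cohort) and -1; with
    fewer samples than features + 1 the minimum-norm solution is used.
    """
    X = np.asarray(X_sel, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y_binary, dtype=float)
    uniq = np.unique(y)
    if len(uniq) < 2:
        raise ValueError("texture index needs both cohorts present")
    if not np.all(np.isin(uniq, (-1.0, 1.0))):
        raise ValueError("y must be coded +1/-1")
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    pos, neg = (classes if classes else (None, None))
    return TextureIndexModel(float(coef[0]), coef[1:], pos, neg)


def texture_index_apply(model: TextureIndexModel, X) -> np.ndarray:
    """Tx scores of one or more subjects; positive favors the +1 cohort."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :] if X.size == model.betas.size else X[:, None]
    return model.beta0 + X @ model.betas


# ------------------------------------------------------------------ DeLong AUC

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    mid = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        mid[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = mid
    return out


def _delong_components(scores: np.ndarray, y_pos: np.ndarray):
    """AUC and per-positive / per-negative placement values (one score vector)."""
    pos = scores[y_pos]
    neg = scores[~y_pos]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n            # placements of positives
    v01 = 1.0 - (all_r[m:] - neg_r) / m      # placements of negatives
    return auc, v10, v01


def delong_auc_ci(scores, y_binary, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC with a DeLong-variance normal confidence interval, clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    y_pos = np.asarray(y_binary).astype(bool)
    auc, v10, v01 = _delong_components(scores, y_pos)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_test(scores_a, scores_b, y_binary) -> tuple[float, float, float, float]:
    """Two-sided DeLong comparison of two correlated AUCs on the same subjects.

    Returns ``(auc_a, auc_b, delta, p_value)``. Midranks handle ties;
    identical score vectors give delta 0 and p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y_pos = np.asarray(y_binary).astype(bool)
    if a.shape != b.shape or a.shape[0] != y_pos.shape[0]:
        raise ValueError("score vectors and labels must share one length")
    auc_a, v10a, v01a = _delong_components(a, y_pos)
    auc_b, v10b, v01b = _delong_components(b, y_pos)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    delta = auc_a - auc_b
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 1e-16:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return float(auc_a), float(auc_b), float(delta), p


# ----------------------------------------------------------------------- t-SNE

def embed_2d(X, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """2-D t-SNE embedding for visualization; deterministic given seed."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples")
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(X)
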
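"""Patient-control discrimination from altered links: LOOCV SVM, permutations, ROC.

Altered-link Fisher-z strengths feed a linear support vector machine
evaluated with leave-one-out cross-validation: for each subject the
model is trained on all others (feature standardization refit inside
every fold, so no information leaks from the held-out subject) and the
held-out decision value and predicted label are recorded.  Accuracy,
sensitivity and specificity come from the pooled held-out predictions;
the decision values give the ROC curve; wholesale label permutation
yields the significance of the observed accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC


@dataclass
class ClassificationReport:
    scope: str
    accuracy: float
    sensitivity: float
    specificity: float
    decision_values: np.ndarray
    predictions: np.ndarray
    roc_points: np.ndarray = field(default=None)  # (m, 2) of (fpr, tpr)
    auc: float = float("nan")
    best_cutoff: float = float("nan")
    permutation_p: float = float("nan")
    n_permutations: int = 0


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def loocv_decision_values(X: np.ndarray, y: np.ndarray, c: float = 1.0):
    """Held-out decision values and predictions for every subject."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("labels must match feature rows")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    decisions = np.empty(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError("single-class training fold")
        xtr, xte = _standardize(X[mask], X[i : i + 1])
        model = SVC(kernel="linear", C=c)
        model.fit(xtr, y[mask])
        decisions[i] = model.decision_function(xte)[0]
        preds[i] = model.predict(xte)[0]
    return decisions, preds


def loocv_classify(
    X: np.ndarray,
    y: np.ndarray,
    scope: str = "pooled",
    c: float = 1.0,
    site_labels=None,
) -> ClassificationReport:
    """LOOCV linear-SVM discrimination with ROC summary.

    ``y`` is 1 = patient (positive class), 0 = control.  With
    ``site_labels`` given, features are site-mean-centered first (the
    pooled multi-site protocol); per-site analyses simply pass the
    subset of one site.  Deterministic given the inputs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    if site_labels is not None:
        X = X.copy()
        for s in np.unique(np.asarray(site_labels)):
            sel = np.asarray(site_labels) == s
            X[sel] -= X[sel].mean(axis=0)
    decisions, preds = loocv_decision_values(X, y, c)
    acc = float((preds == y).mean())
    sens = float((preds[y == 1] == 1).mean())
    spec = float((preds[y == 0] == 0).mean())
    fpr, tpr, thresholds = roc_curve(decisions, y)
    auc_val = auc_trapezoid(fpr, tpr)
    best = best_cutoff(decisions, y)
    return ClassificationReport(
        scope=scope,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        decision_values=decisions,
        predictions=preds,
        roc_points=np.column_stack([fpr, tpr]),
        auc=auc_val,
        best_cutoff=best,
    )


def roc_curve(decision_values: np.ndarray, labels: np.ndarray):
    """ROC sweep over the unique decision thresholds.

    Returns (fpr, tpr, thresholds) with fpr/tpr nondecreasing, starting
    at (0, 0) and ending at (1, 1).  Constant decision values give the
    degenerate diagonal {(0,0),(1,1)}.
    """
    scores = np.asarray(decision_values, dtype=float).ravel()
    y = np.asarray(labels).astype(int).ravel()
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_y = y[order]
    sorted_s = scores[order]
    tps = np.cumsum(sorted_y == 1)
    fps = np.cumsum(sorted_y == 0)
    # keep only the last point of each tied-score run
    distinct = np.r_[np.flatnonzero(np.diff(sorted_s)), len(sorted_s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thresholds = np.r_[np.inf, sorted_s[distinct]]
    return fpr, tpr, thresholds


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def best_cutoff(decision_values: np.ndarray, labels: np.ndarray) -> float:
    """Decision threshold maximizing Youden's J = tpr - fpr."""
    fpr, tpr, thresholds = roc_curve(decision_values, labels)
    j = tpr - fpr
    return float(thresholds[int(np.argmax(j))])


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 199,
    seed: int = 0,
    c: float = 1.0,
    observed_accuracy: float | None = None,
) -> float:
    """Permutation p-value of the LOOCV accuracy.

    Labels are permuted wholesale; the whole LOOCV is re-run on each
    permutation.  p = (1 + #{perm acc >= observed}) / (n_permutations + 1),
    so the smallest achievable p is 1/(n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    if observed_accuracy is None:
        _, preds = loocv_decision_values(X, y, c)
        observed_accuracy = float((preds == y).mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        _, preds = loocv_decision_values(X, perm, c)
        if (preds == perm).mean() >= observed_accuracy:
            count += 1
    return (1 + count) / (n_permutations + 1)
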
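"""Depressed-state detection: class-weighted linear SVM under LOOCV.

Per leave-one-subject-out fold: standardize features with the training
rows' mean/SD, optionally reduce to 6 features by recursive feature
elimination (drop the smallest-|coefficient| feature one at a time), pick
the cost C from {1e-3 .. 1e3} by stratified 3-fold inner CV on accuracy
(ties to the smallest C), fit the class-weighted squared-hinge L2 linear
SVM, and score the held-out subject by its decision value.  Pooled
decision scores give the ROC AUC; significance comes from re-running the
entire procedure under label permutations, p = (#{null >= observed}+1) /
(n_perm+1).

The SVM solver minimizes the liblinear primal objective

    0.5 ||u||^2  +  sum_i C_i max(0, 1 - y_i u.z_i)^2,   z_i = [x_i, 1]

(class-weighted C_i = C * N/(K n_k), regularized intercept) by damped
Newton steps -- the objective is piecewise quadratic and strictly convex,
so a handful of iterations reach machine precision.  This keeps the
~10^6 fits of the permutation test tractable; tests cross-check the
coefficients against scikit-learn's LinearSVC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io_core import PipelineConfig
from .components import feature_matrix


@dataclass
class FoldResult:
    subject_id: str
    true_label: int
    decision_score: float
    predicted_label: int
    selected_features: list
    chosen_c: float
    coefficients: dict          # feature name -> coefficient (selected only)


@dataclass
class ClassificationReport:
    feature_set: str
    auc: float
    tp: int
    fn: int
    tn: int
    fp: int
    tpr: float
    tnr: float
    mean_abs_coef: dict = field(default_factory=dict)
    permutation_p: float | None = None
    null_aucs: np.ndarray | None = None


def class_weights(labels) -> dict:
    """weight_k = N / (K * n_k) (balanced weighting of the error costs)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    n, k = labels.size, classes.size
    return {int(c): n / (k * cnt) for c, cnt in zip(classes, counts)}


def fit_linear_svm(X, y, C: float, weights: dict | None = None,
                   tol: float = 1e-9, max_iter: int = 100):
    """Primal Newton solver for the class-weighted squared-hinge L2 SVM.

    Returns (coef vector, intercept).  ``y`` is 0/1; ``weights`` maps class
    label -> multiplier on C (defaults to balanced weights).
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y)
    n, d = X.shape
    ysign = np.where(y01 == 1, 1.0, -1.0)
    if weights is None:
        weights = class_weights(y01)
    Ci = C * np.array([weights[int(c)] for c in y01])
    Z = np.hstack([X, np.ones((n, 1))])
    u = np.zeros(d + 1)

    def objective(v):
        m = np.clip(1.0 - ysign * (Z @ v), 0.0, None)
        return 0.5 * v @ v + np.sum(Ci * m * m)

    for _ in range(max_iter):
        margin = 1.0 - ysign * (Z @ u)
        active = margin > 0
        grad = u - 2.0 * Z[active].T @ (Ci[active] * ysign[active] * margin[active])
        if np.linalg.norm(grad) <= tol * max(1.0, np.linalg.norm(u)):
            break
        Za = Z[active] * np.sqrt(2.0 * Ci[active])[:, None]
        H = np.eye(d + 1) + Za.T @ Za
        step = np.linalg.solve(H, grad)
        f0 = objective(u)
        t = 1.0
        while objective(u - t * step) > f0 - 1e-4 * t * (grad @ step) and t > 1e-8:
            t *= 0.5
        u = u - t * step
    return u[:-1], float(u[-1])


def decision_scores(X, coef, intercept) -> np.ndarray:
    return np.asarray(X, dtype=float) @ coef + intercept


def standardize(train: np.ndarray, apply_to: np.ndarray):
    """Standardize with the training rows' mean/SD (constant columns scale 1).

    Returns (standardized train, standardized apply_to, mean, sd).
    """
    train = np.asarray(train, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need >= 2 training rows to standardize")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mean) / sd, (np.asarray(apply_to, dtype=float) - mean) / sd, mean, sd


def rfe_select(X, y, n_keep: int, C: float = 1.0) -> list:
    """Recursive feature elimination to ``n_keep`` features.

    Repeatedly fit the class-weighted SVM and drop the feature with the
    smallest |coefficient| (ties: the later column is dropped).  Returns
    surviving column indices in original order.
    """
    X = np.asarray(X, dtype=float)
    if n_keep > X.shape[1]:
        raise ValueError("n_keep exceeds the number of features")
    remaining = list(range(X.shape[1]))
    while len(remaining) > n_keep:
        coef, _ = fit_linear_svm(X[:, remaining], y, C)
        order = np.abs(coef)
        # smallest |coef|; np.argmin takes the first on exact ties, so flip
        # to drop the later column instead
        drop_pos = len(order) - 1 - int(np.argmin(order[::-1]))
        remaining.pop(drop_pos)
    return remaining


def grid_search_c(X, y, c_grid, inner_folds: int = 3, rng=None) -> float:
    """Best C by stratified k-fold accuracy of class-weighted fits.

    Ties resolve to the smallest C.  ``rng`` (a Generator) seeds the fold
    shuffling.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    seed = int(rng.integers(2 ** 31)) if rng is not None else 0
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_c, best_acc = None, -np.inf
    for C in c_grid:
        accs = []
        for tr, te in folds:
            coef, b = fit_linear_svm(X[tr], y[tr], C)
            pred = (decision_scores(X[te], coef, b) > 0).astype(int)
            accs.append(np.mean(pred == y[te]))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:   # strict improvement keeps the smallest C on ties
            best_acc, best_c = acc, C
    return best_c


def compute_auc(scores, labels) -> float:
    """ROC AUC of decision scores (ties between scores count 1/2)."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores)))


def confusion_rates(tp: int, fn: int, tn: int, fp: int):
    return tp / (tp + fn), tn / (tn + fp)


def _n_features_used(config: PipelineConfig, n_features: int) -> int | None:
    if config.feature_set == "subjective_only":
        return None  # no selection for the 6 rating features
    return min(config.n_selected, n_features)


def loocv_classify(features: pd.DataFrame, config: PipelineConfig,
                   rng=None, labels_override=None):
    """Leave-one-subject-out classification of depressed vs non-depressed.

    Returns (list of FoldResult, ClassificationReport).  ``labels_override``
    substitutes permuted labels while keeping the identical pipeline (used
    by the permutation test).
    """
    X_all, y_all, names = feature_matrix(features, config.feature_set)
    if labels_override is not None:
        y_all = np.asarray(labels_override).astype(int)
    if min((y_all == 1).sum(), (y_all == 0).sum()) < 2:
        raise ValueError("need >= 2 subjects per class")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    subject_ids = features["subject_id"].to_numpy()
    n = len(y_all)
    n_keep = _n_features_used(config, len(names))
    folds = []
    for i in range(n):
        tr = np.arange(n) != i
        Xtr, Xte, _, _ = standardize(X_all[tr], X_all[[i]])
        ytr = y_all[tr]
        if n_keep is not None and n_keep < Xtr.shape[1]:
            sel = rfe_select(Xtr, ytr, n_keep, config.rfe_c)
        else:
            sel = list(range(Xtr.shape[1]))
        Xtr_s, Xte_s = Xtr[:, sel], Xte[:, sel]
        C = grid_search_c(Xtr_s, ytr, config.c_grid, config.inner_folds, rng)
        coef, b = fit_linear_svm(Xtr_s, ytr, C)
        score = float(decision_scores(Xte_s, coef, b)[0])
        folds.append(FoldResult(
            subject_id=str(subject_ids[i]), true_label=int(y_all[i]),
            decision_score=score, predicted_label=int(score > 0),
            selected_features=[names[j] for j in sel], chosen_c=float(C),
            coefficients={names[j]: float(c) for j, c in zip(sel, coef)}))
    scores = np.array([f.decision_score for f in folds])
    preds = np.array([f.predicted_label for f in folds])
    tp = int(np.sum((preds == 1) & (y_all == 1)))
    fn = int(np.sum((preds == 0) & (y_all == 1)))
    tn = int(np.sum((preds == 0) & (y_all == 0)))
    fp = int(np.sum((preds == 1) & (y_all == 0)))
    tpr, tnr = confusion_rates(tp, fn, tn, fp)
    report = ClassificationReport(
        feature_set=config.feature_set, auc=compute_auc(scores, y_all),
        tp=tp, fn=fn, tn=tn, fp=fp, tpr=tpr, tnr=tnr,
        mean_abs_coef=aggregate_coefficients(folds, names))
    return folds, report


def permutation_test(features: pd.DataFrame, config: PipelineConfig,
                     observed_auc: float, n_permutations: int | None = None,
                     rng=None):
    """Label-permutation significance of the observed pooled AUC.

    Each randomization permutes the subject labels once, re-runs the whole
    LOOCV pipeline (standardization, RFE, grid search, fitting) with those
    labels, and records the pooled AUC against the permuted labels.
    p = (#{null >= observed} + 1) / (n_permutations + 1).
    """
    n_perm = config.n_permutations if n_permutations is None else n_permutations
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    _, y_all, _ = feature_matrix(features, config.feature_set)
    null_aucs = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y_all)
        _, rep = loocv_classify(features, config, rng=rng, labels_override=y_perm)
        null_aucs[b] = rep.auc
    p = (np.sum(null_aucs >= observed_auc) + 1.0) / (n_perm + 1.0)
    return float(p), null_aucs


def aggregate_coefficients(folds: list, feature_names: list) -> dict:
    """Mean |coefficient| per feature across folds (zero for unselected),
    min-max normalized to [0, 1] for reporting."""
    acc = {name: 0.0 for name in feature_names}
    for f in folds:
        for name in feature_names:
            acc[name] += abs(f.coefficients.get(name, 0.0))
    mean_abs = {name: v / len(folds) for name, v in acc.items()}
    vals = np.array(list(mean_abs.values()))
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        return {k: float((v - lo) / (hi - lo)) for k, v in mean_abs.items()}
    return {k: 0.0 for k in mean_abs}


def report_to_frame(report: ClassificationReport) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_set": report.feature_set, "auc": report.auc,
        "tp": report.tp, "fn": report.fn, "tn": report.tn, "fp": report.fp,
        "tpr": report.tpr, "tnr": report.tnr,
        "permutation_p": report.permutation_p,
    }])
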
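"""SVM identification and treatment-efficacy models with LOOCV inference.

Classification: RBF-kernel support-vector classifier, leave-one-out
cross-validation with per-fold standardization and inner grid search
over (C, gamma), performance as mean held-out accuracy and the AUC of
pooled held-out decision values, significance by label-permutation.

Regression: epsilon-SVR on per-subject FCD change ratios predicting the
symptom-improvement ratio, evaluated as the Pearson correlation between
actual and LOOCV-predicted values, with the same permutation scheme.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC, SVR

from .types import FeatureMatrix, SVCResult, SVRResult

__all__ = [
    "loocv_svc",
    "loocv_svr",
    "roc_auc",
    "permutation_test_classifier",
    "permutation_test_regressor",
    "change_ratios",
]


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(features, dtype=float)


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(0)
    sd = train.std(0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def _cv_splits(n: int, k: int, y: Optional[np.ndarray], rng) -> list[np.ndarray]:
    """k roughly equal folds; stratified by label when y is given."""
    idx = np.arange(n)
    if y is not None:
        folds = [[] for _ in range(k)]
        for cls in np.unique(y):
            members = idx[y == cls]
            members = members[rng.permutation(members.size)]
            for i, m in enumerate(members):
                folds[i % k].append(m)
        return [np.asarray(sorted(f), dtype=int) for f in folds if len(f) > 0]
    perm = rng.permutation(n)
    return [np.asarray(sorted(f), dtype=int) for f in np.array_split(perm, k)]


def _grid_search(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: Sequence[float],
    gamma_grid: Sequence[float],
    inner_cv: int,
    rng,
    regression: bool = False,
    epsilon: float = 0.1,
    standardize: bool = True,
) -> tuple[float, float]:
    """Inner cross-validated grid search on a training fold.

    Selection score: accuracy (SVC) or negative MSE (SVR). Candidates are
    scanned in ascending (C, gamma) order, ties broken toward smaller C
    then smaller gamma. A singleton grid short-circuits the search.
    """
    c_grid = sorted(float(c) for c in c_grid)
    gamma_grid = sorted(float(g) for g in gamma_grid)
    if len(c_grid) == 1 and len(gamma_grid) == 1:
        return c_grid[0], gamma_grid[0]
    n = X.shape[0]
    k = min(inner_cv, n)
    splits = _cv_splits(n, k, None if regression else y, rng)
    best = (-np.inf, None)
    for C in c_grid:
        for gamma in gamma_grid:
            score = 0.0
            total = 0
            for test_idx in splits:
                train_idx = np.setdiff1d(np.arange(n), test_idx)
                if not regression and np.unique(y[train_idx]).size < 2:
                    continue
                if standardize:
                    Xtr, Xte = _standardize(X[train_idx], X[test_idx])
                else:
                    Xtr, Xte = X[train_idx], X[test_idx]
                if regression:
                    model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
                    model.fit(Xtr, y[train_idx])
                    pred = model.predict(Xte)
                    score -= ((pred - y[test_idx]) ** 2).sum()
                else:
                    model = SVC(kernel="rbf", C=C, gamma=gamma)
                    model.fit(Xtr, y[train_idx])
                    score += (model.predict(Xte) == y[test_idx]).sum()
                total += test_idx.size
            if total:
                score /= total
            if score > best[0]:
                best = (score, (C, gamma))
    if best[1] is None:
        return c_grid[0], gamma_grid[0]
    return best[1]


def loocv_svc(
    features,
    labels,
    c_grid: Sequence[float] = (1.0,),
    gamma_grid: Sequence[float] = (0.1,),
    inner_cv: int = 5,
    standardize: bool = True,
    seed: int = 0,
) -> SVCResult:
    """Leave-one-out cross-validated RBF support-vector classification.

    For each held-out subject the features are standardized on the
    training fold, (C, gamma) are chosen by inner cross-validated
    accuracy on the training fold only, and the held-out prediction and
    signed decision value are recorded. Accuracy, sensitivity,
    specificity and AUC are computed exclusively from the pooled
    held-out predictions.
    """
    X = _as_array(features)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < 6:
        raise ValueError("need at least 6 subjects for LOOCV")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least 2 subjects")
    pos = classes[1]  # decision values signed toward the second class
    rng = np.random.default_rng(seed)
    preds = np.empty(n, dtype=y.dtype)
    dvals = np.empty(n)
    hyper = []
    for i in range(n):
        train = np.setdiff1d(np.arange(n), [i])
        Xtr_raw, Xte_raw = X[train], X[[i]]
        if standardize:
            Xtr, Xte = _standardize(Xtr_raw, Xte_raw)
        else:
            Xtr, Xte = Xtr_raw, Xte_raw
        fold_rng = np.random.default_rng(rng.integers(2**31))
        C, gamma = _grid_search(
            Xtr_raw, y[train], c_grid, gamma_grid, inner_cv, fold_rng,
            standardize=standardize,
        )
        model = SVC(kernel="rbf", C=C, gamma=gamma)
        model.fit(Xtr, y[train])
        preds[i] = model.predict(Xte)[0]
        d = float(model.decision_function(Xte)[0])
        # sklearn orients the decision by its internal class order
        if model.classes_[1] != pos:
            d = -d
        dvals[i] = d
        hyper.append({"C": C, "gamma": gamma})
    correct = preds == y
    acc = float(correct.mean())
    is_pos = y == pos
    sens = float(correct[is_pos].mean()) if is_pos.any() else np.nan
    spec = float(correct[~is_pos].mean()) if (~is_pos).any() else np.nan
    auc = roc_auc(dvals, is_pos.astype(int))
    return SVCResult(
        predicted_labels=preds,
        decision_values=dvals,
        true_labels=y,
        mean_accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        best_hyperparams=hyper,
    )


def roc_auc(decision_values, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic, ties counted half.

    AUC = P(score_pos > score_neg) + 0.5 P(score_pos = score_neg),
    estimated over all positive/negative pairs of pooled decision values.
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    pos = d[y == classes[1]]
    neg = d[y == classes[0]]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def permutation_test_classifier(
    features,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    **loocv_kwargs,
) -> tuple[float, np.ndarray]:
    """Permutation inference on LOOCV accuracy.

    Labels are permuted ``n_perm`` times and the full LOOCV (including
    standardization and inner grid search) is recomputed each round;
    p = (1 + #{perm accuracy >= observed}) / (n_perm + 1), never zero.
    Returns (p, null accuracies).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = loocv_svc(features, y, seed=seed, **loocv_kwargs).mean_accuracy
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = y[rng.permutation(y.size)]
        null[b] = loocv_svc(features, y_perm, seed=seed, **loocv_kwargs).mean_accuracy
    p = (1.0 + (null >= observed).sum()) / (n_perm + 1.0)
    return float(p), null


def change_ratios(
    pre: FeatureMatrix,
    post: FeatureMatrix,
    scores_pre: np.ndarray,
    scores_post: np.ndarray,
):
    """Per-subject change/baseline ratios for features and symptom score.

    Feature ratios are (post − pre)/pre; the symptom label is oriented so
    improvement is positive: (pre − post)/pre (the score decreases when
    symptoms improve). Zero baselines are rejected.
    """
    if pre.subject_ids != post.subject_ids:
        raise ValueError("pre/post subjects must match")
    if pre.values.shape != post.values.shape:
        raise ValueError("pre/post feature shapes must match")
    sp = np.asarray(scores_pre, dtype=float)
    ss = np.asarray(scores_post, dtype=float)
    if sp.size != pre.n_subjects or ss.size != pre.n_subjects:
        raise ValueError("score vectors must match subject count")
    if (pre.values == 0).any():
        raise ValueError("zero baseline feature value; ratio undefined")
    if (sp == 0).any():
        raise ValueError("zero baseline score; ratio undefined")
    feature_ratios = (post.values - pre.values) / pre.values
    improvement = (sp - ss) / sp
    return feature_ratios, improvement


def loocv_svr(
    features,
    target,
    c_grid: Sequence[float] = (1.0,),
    gamma_grid: Sequence[float] = (0.1,),
    inner_cv: int = 5,
    standardize: bool = True,
    epsilon: float = 0.1,
    seed: int = 0,
) -> SVRResult:
    """Leave-one-out cross-validated RBF epsilon-SVR.

    Per fold: standardize on training subjects, grid-search (C, gamma)
    by inner cross-validated negative MSE, predict the held-out subject.
    Performance is the Pearson correlation between actual and pooled
    held-out predicted values.
    """
    X = _as_array(features)
    y = np.asarray(target, dtype=float)
    n = X.shape[0]
    if n < 6:
        raise ValueError("need at least 6 subjects for LOOCV")
    if np.allclose(y.std(), 0):
        raise ValueError("constant target; correlation undefined")
    rng = np.random.default_rng(seed)
    preds = np.empty(n)
    hyper = []
    for i in range(n):
        train = np.setdiff1d(np.arange(n), [i])
        if standardize:
            Xtr, Xte = _standardize(X[train], X[[i]])
        else:
            Xtr, Xte = X[train], X[[i]]
        fold_rng = np.random.default_rng(rng.integers(2**31))
        C, gamma = _grid_search(
            X[train], y[train], c_grid, gamma_grid, inner_cv, fold_rng,
            regression=True, epsilon=epsilon, standardize=standardize,
        )
        model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
        model.fit(Xtr, y[train])
        preds[i] = model.predict(Xte)[0]
        hyper.append({"C": C, "gamma": gamma})
    if np.allclose(preds.std(), 0):
        r = 0.0  # degenerate predictions carry no linear association
    else:
        r = float(np.corrcoef(y, preds)[0, 1])
    return SVRResult(
        predicted=preds,
        actual=y,
        pearson_r=r,
        best_hyperparams=hyper,
    )


def permutation_test_regressor(
    features,
    target,
    n_perm: int = 1000,
    seed: int = 0,
    **svr_kwargs,
) -> tuple[float, np.ndarray]:
    """Permutation inference on the pooled-fold Pearson r of the SVR.

    p = (1 + #{perm r >= observed}) / (n_perm + 1). The full LOOCV is
    recomputed for every permuted target.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(target, dtype=float)
    rng = np.random.default_rng(seed)
    observed = loocv_svr(features, y, seed=seed, **svr_kwargs).pearson_r
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = y[rng.permutation(y.size)]
        null[b] = loocv_svr(features, y_perm, seed=seed, **svr_kwargs).pearson_r
    p = (1.0 + (null >= observed).sum()) / (n_perm + 1.0)
    return float(p), null
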
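"""Biomarker panel selection by recursive feature elimination (RFE).

Features are ranked by a random-forest impurity importance (or the
absolute weights of a linear SVM), the lowest-ranked are eliminated down
a candidate-size schedule, and each candidate panel size is scored by
stratified k-fold cross-validated ROC AUC; the best size (ties resolved
toward the smaller panel) is refit on all training data.  A held-out
split then yields the ROC curve and AUROC of the selected panel, with
AUROC computed by the concordant-pair formula so it is invariant to any
monotone rescaling of classifier scores.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import PeakTable, SampleMeta
from .stats import univariate_auc

__all__ = ["RFEResult", "rfe_select", "evaluate_model"]


@dataclasses.dataclass
class RFEResult:
    """Outcome of RFE selection and/or held-out evaluation."""

    profile: list[tuple[int, float]]          # (panel size, mean CV ROC AUC)
    selected_features: list[str]
    estimator: str
    roc_points: list[tuple[float, float]] | None = None  # (fpr, tpr)
    auroc: float | None = None


def _make_estimator(name: str, seed: int):
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed, n_jobs=1
        )
    if name == "svm":
        from sklearn.svm import SVC

        return SVC(kernel="linear", probability=False, random_state=seed)
    raise ValueError(f"unknown estimator {name!r}; use 'rf' or 'svm'")


def _importance(model, name: str) -> np.ndarray:
    if name == "rf":
        return model.feature_importances_
    return np.abs(np.asarray(model.coef_).ravel())


def _scores(model, X: np.ndarray, name: str) -> np.ndarray:
    if name == "rf":
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _design(pt: PeakTable, meta: SampleMeta):
    klass = meta.classes(pt.sample_ids)
    keep = np.array([k is not None for k in klass], dtype=bool)
    groups = list(dict.fromkeys(k for k in klass if k is not None))
    if len(groups) != 2:
        raise ValueError(f"biomarker analysis needs exactly two non-QC groups, found {groups}")
    cols = np.where(keep)[0]
    y = np.array([1 if klass[j] == groups[0] else 0 for j in cols])
    X = pt.values[:, cols].T  # samples x features
    if np.isnan(X).any():
        raise ValueError("biomarker analysis requires a complete matrix; impute first")
    return X, y, cols


def rfe_select(
    pt: PeakTable,
    meta: SampleMeta,
    estimator: str = "rf",
    cv_folds: int = 5,
    sizes: list[int] | None = None,
    seed: int = 0,
) -> RFEResult:
    """Recursive feature elimination with cross-validated panel scoring.

    ``sizes`` defaults to a halving schedule from the full feature count
    down to 1.  For each size, the feature ranking (refit after each
    elimination step) keeps the top features and the panel is scored by
    stratified ``cv_folds``-fold CV ROC AUC; the best mean score wins,
    ties going to the smaller panel.  The final ranking and refit use all
    samples, so the same seed reproduces the profile exactly.
    """
    from sklearn.model_selection import StratifiedKFold

    X, y, _ = _design(pt, meta)
    p = X.shape[1]
    if sizes is None:
        sizes = []
        s = p
        while s >= 1:
            sizes.append(s)
            s //= 2
    sizes = sorted(set(int(s) for s in sizes), reverse=True)
    if sizes[0] > p:
        raise ValueError(f"candidate size {sizes[0]} exceeds feature count {p}")

    counts = np.bincount(y)
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {cv_folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    # elimination schedule on the full data: refit and re-rank at each size
    keep = np.arange(p)
    panels: dict[int, np.ndarray] = {}
    for size in sizes:
        if keep.size > size:
            model = _make_estimator(estimator, seed)
            model.fit(X[:, keep], y)
            ranking = np.argsort(-_importance(model, estimator), kind="mergesort")
            keep = np.sort(keep[ranking[:size]])
        panels[size] = keep.copy()

    profile: list[tuple[int, float]] = []
    for size in sizes:
        cols = panels[size]
        aucs = []
        for f, (train, test) in enumerate(splits):
            if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
                raise ValueError("a CV fold is missing a class; use fewer folds")
            model = _make_estimator(estimator, seed + f + 1)
            model.fit(X[np.ix_(train, cols)], y[train])
            s = _scores(model, X[np.ix_(test, cols)], estimator)
            aucs.append(univariate_auc(s[y[test] == 1], s[y[test] == 0]))
        profile.append((size, float(np.mean(aucs))))

    best_score = max(score for _, score in profile)
    best_size = min(size for size, score in profile if score >= best_score - 1e-12)
    selected = panels[best_size]
    return RFEResult(
        profile=profile,
        selected_features=[str(f) for f in pt.feature_ids[selected]],
        estimator=estimator,
    )


def evaluate_model(
    pt: PeakTable,
    meta: SampleMeta,
    features: list[str],
    estimator: str = "rf",
    train_frac: float | None = 0.5,
    train_samples: list[str] | None = None,
    test_samples: list[str] | None = None,
    seed: int = 0,
) -> RFEResult:
    """Held-out ROC evaluation of a fixed feature panel.

    The split is either a stratified random ``train_frac`` or explicit
    train/test sample lists (to mirror a published design).  The ROC
    curve sweeps score thresholds; AUROC uses the concordant-pair
    formula (ties count one half).
    """
    X, y, cols = _design(pt, meta)
    sample_ids = [str(s) for s in pt.sample_ids[cols]]
    fidx = pt.feature_index(features)
    # map full-table feature positions onto the design matrix columns
    Xp = pt.values[fidx][:, cols].T

    if train_samples is not None or test_samples is not None:
        if train_samples is None or test_samples is None:
            raise ValueError("provide both train_samples and test_samples")
        pos = {s: i for i, s in enumerate(sample_ids)}
        train = np.array([pos[s] for s in train_samples])
        test = np.array([pos[s] for s in test_samples])
    else:
        rng = np.random.default_rng(seed)
        train_list: list[int] = []
        for value in np.unique(y):
            idx = np.where(y == value)[0]
            rng.shuffle(idx)
            n_train = int(round(train_frac * idx.size))
            train_list.extend(idx[:n_train])
        train = np.sort(np.array(train_list))
        test = np.setdiff1d(np.arange(len(y)), train)
    if len(np.unique(y[test])) < 2:
        raise ValueError("test split contains a single class")
    if len(np.unique(y[train])) < 2:
        raise ValueError("train split contains a single class")

    model = _make_estimator(estimator, seed)
    model.fit(Xp[train], y[train])
    s = _scores(model, Xp[test], estimator)
    y_test = y[test]
    auroc = univariate_auc(s[y_test == 1], s[y_test == 0])

    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    n_pos = int((y_test == 1).sum())
    n_neg = int((y_test == 0).sum())
    roc = []
    for th in thresholds:
        called = s >= th
        tpr = float((called & (y_test == 1)).sum()) / n_pos
        fpr = float((called & (y_test == 0)).sum()) / n_neg
        roc.append((fpr, tpr))
    roc = sorted(set(roc))
    return RFEResult(
        profile=[],
        selected_features=list(features),
        estimator=estimator,
        roc_points=roc,
        auroc=float(auroc),
    )
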
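"""Seeded random-forest classifier with ranger-style permutation
importance.

The ensemble is a hand-rolled bagging loop over sklearn decision trees so
that per-tree bootstrap/out-of-bag (OOB) membership is explicit: that is
what makes casewise (local) permutation importance computable.  Entry
(i, j) of the casewise matrix is the mean, over trees where training
sample i is OOB, of [correct-vote indicator before minus after permuting
feature j among that tree's OOB samples]; a feature's global permutation
importance is the matching OOB average, so casewise column means reconcile
with global importance up to Monte-Carlo weighting.

Only the features a tree actually splits on are permuted for that tree:
permuting an unused feature cannot change the tree's predictions, so its
contribution is exactly zero.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .datamodel import ValidationError

DEFAULT_N_TREES = 10_000  # full-scale default; tests use far fewer
TUNING_GRID = {
    "mtry": ("sqrt", "p/5", "p/2"),
    "sample_fraction": (0.632, 0.8, 1.0),
    "min_node_size": (1, 5, 10),
}



def _fast_predict(tree, X32: np.ndarray) -> np.ndarray:
    """Tree prediction without sklearn input validation (X32 must be
    float32 C-contiguous); identical output to ``tree.predict``."""
    proba = tree.tree_.predict(X32)
    if proba.ndim == 3:  # (n_samples, n_outputs, n_classes)
        proba = proba[:, 0, :]
    return tree.classes_[np.argmax(proba, axis=1)]

def _resolve_mtry(mtry, p: int) -> int:
    if mtry is None or mtry == "sqrt":
        return max(1, int(round(math.sqrt(p))))
    if mtry == "p/5":
        return max(1, p // 5)
    if mtry == "p/2":
        return max(1, p // 2)
    return max(1, min(int(mtry), p))


@dataclass
class SeededForest:
    """Bagged randomized decision trees, deterministic given ``seed``.

    Majority vote with ties broken toward the lowest class index.
    """

    n_trees: int = 500
    mtry: int | str | None = "sqrt"
    sample_fraction: float = 0.632
    min_node_size: int = 1
    seed: int = 0

    classes_: np.ndarray = field(default=None, repr=False)
    trees_: list = field(default_factory=list, repr=False)
    oob_masks_: np.ndarray = field(default=None, repr=False)
    used_features_: list = field(default_factory=list, repr=False)
    n_features_: int = 0

    def fit(self, X, y) -> "SeededForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(pd.Series(y).astype(str))
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValidationError("training data must contain >= 2 classes")
        n, p = X.shape
        self.n_features_ = p
        y_codes = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.seed)
        n_boot = max(1, int(round(self.sample_fraction * n)))
        max_features = _resolve_mtry(self.mtry, p)
        self.trees_ = []
        self.oob_masks_ = np.zeros((self.n_trees, n), dtype=bool)
        self.used_features_ = []
        warning_ctx = warnings.catch_warnings()
        warning_ctx.__enter__()
        # many-class/small-bootstrap fits trip a spurious sklearn warning
        warnings.filterwarnings("ignore", message="The number of unique classes")
        for t in range(self.n_trees):
            idx = rng.integers(0, n, n_boot)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            # a bootstrap sample can miss a class; resample until not
            tries = 0
            while len(np.unique(y_codes[idx])) < 2 and tries < 50:
                idx = rng.integers(0, n, n_boot)
                oob = np.ones(n, dtype=bool)
                oob[idx] = False
                tries += 1
            tree = DecisionTreeClassifier(
                max_features=max_features,
                min_samples_leaf=self.min_node_size,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y_codes[idx])
            self.trees_.append(tree)
            self.oob_masks_[t] = oob
            used = np.unique(tree.tree_.feature)
            self.used_features_.append(used[used >= 0])
        warning_ctx.__exit__(None, None, None)
        return self

    def _vote_matrix(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=np.int32)
        for tree in self.trees_:
            pred = self._tree_codes(tree, X)
            votes[np.arange(X.shape[0]), pred] += 1
        return votes

    def _tree_codes(self, tree, X: np.ndarray) -> np.ndarray:
        # trees were fit on class codes; map tree-local classes back
        local = tree.predict(X)
        return local.astype(np.intp)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = self._vote_matrix(X)
        return self.classes_[votes.argmax(axis=1)]  # argmax -> lowest index on ties

    def oob_predictions(self, X) -> np.ndarray:
        """OOB majority-vote predictions; samples never OOB get the
        lowest class label by the tie-break convention."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        votes = np.zeros((n, len(self.classes_)), dtype=np.int32)
        for t, tree in enumerate(self.trees_):
            oob = self.oob_masks_[t]
            if not oob.any():
                continue
            pred = self._tree_codes(tree, X[oob])
            votes[np.flatnonzero(oob), pred] += 1
        return self.classes_[votes.argmax(axis=1)]

    def oob_error(self, X, y) -> float:
        y = np.asarray(pd.Series(y).astype(str))
        seen = self.oob_masks_.any(axis=0)
        pred = self.oob_predictions(X)
        if not seen.any():
            return float("nan")
        return float((pred[seen] != y[seen]).mean())


def fit_forest(
    X,
    y,
    n_trees: int = 500,
    seed: int = 0,
    tune: bool = True,
    tuning_trees: int = 100,
    hyperparameters: dict | None = None,
) -> SeededForest:
    """Fit a seeded forest, optionally tuning mtry / sample fraction /
    minimum node size by out-of-bag error over a small grid.

    The grid follows the documented tuning contract
    (mtry in {sqrt(p), p/5, p/2}, sample_fraction in {0.632, 0.8, 1.0},
    min_node_size in {1, 5, 10}); tuning forests use ``tuning_trees``
    trees and the winner is refit with ``n_trees``.  Passing
    ``hyperparameters`` skips tuning.
    """
    X = np.asarray(X, dtype=float)
    if hyperparameters is not None:
        tune = False
    params = {"mtry": "sqrt", "sample_fraction": 0.632, "min_node_size": 1}
    if hyperparameters:
        params.update(hyperparameters)
    if tune:
        best, best_err = None, np.inf
        for mtry, sf, mns in itertools.product(
            TUNING_GRID["mtry"],
            TUNING_GRID["sample_fraction"],
            TUNING_GRID["min_node_size"],
        ):
            trial = SeededForest(
                n_trees=tuning_trees,
                mtry=mtry,
                sample_fraction=sf,
                min_node_size=mns,
                seed=seed,
            ).fit(X, y)
            err = trial.oob_error(X, y)
            if err < best_err - 1e-12:
                best, best_err = (mtry, sf, mns), err
        params = dict(zip(("mtry", "sample_fraction", "min_node_size"), best))
    forest = SeededForest(n_trees=n_trees, seed=seed, **params)
    return forest.fit(X, y)


def casewise_importance(
    forest: SeededForest, X, y, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Casewise (local) OOB permutation importance.

    Returns the (training sample x feature) casewise matrix and the
    per-feature global permutation importance (mean over trees of the OOB
    accuracy drop).  Rows for samples never out of bag are NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(pd.Series(y).astype(str))
    y_codes = np.searchsorted(forest.classes_, y)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    case_sum = np.zeros((n, p))
    case_cnt = np.zeros(n)
    global_sum = np.zeros(p)
    global_cnt = np.zeros(p)
    for t, tree in enumerate(forest.trees_):
        oob = np.flatnonzero(forest.oob_masks_[t])
        if oob.size == 0:
            continue
        Xo = np.ascontiguousarray(X[oob], dtype=np.float32)
        before = (_fast_predict(tree, Xo).astype(np.intp) == y_codes[oob]).astype(float)
        used = forest.used_features_[t]
        case_cnt[oob] += 1
        # global importance for unused features gets a 0 contribution
        global_cnt += 1
        if used.size:
            m = oob.size
            stacked = np.repeat(Xo[None, :, :], used.size, axis=0)
            for k, j in enumerate(used):
                stacked[k, :, j] = Xo[rng.permutation(m), j]
            preds = _fast_predict(
                tree, np.ascontiguousarray(stacked.reshape(-1, p))
            ).astype(np.intp)
            after = (preds.reshape(used.size, m) == y_codes[oob][None, :]).astype(float)
            delta = before[None, :] - after  # (used, oob)
            case_sum[np.ix_(oob, used)] += delta.T
            global_sum[used] += delta.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        casewise = case_sum / case_cnt[:, None]
    global_imp = np.divide(
        global_sum,
        global_cnt,
        out=np.zeros(p),
        where=global_cnt > 0,
    )
    never = case_cnt == 0
    if never.any():
        casewise[never] = np.nan
    return pd.DataFrame(casewise), global_imp


def vita_select(
    X,
    y,
    seed: int = 0,
    n_folds: int = 5,
    n_trees: int = 100,
    p_threshold: float = 0.05,
    n_repeats: int = 3,
) -> np.ndarray:
    """Vita-style variable selection.

    Cross-validated permutation importance: for each fold, a forest is
    grown on the complement and per-tree permutation importance is
    evaluated on the held-out fold; fold values are averaged over folds
    and over ``n_repeats`` (default 3) independent fold assignments (repeating the
    cross-validation damps fold-assignment noise when classes have few
    samples).  The null distribution is formed by mirroring the
    non-positive importance values around zero, per-feature p-values are
    the null exceedance probabilities, and features with
    p < ``p_threshold`` are retained.

    Returns the indices of the selected features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(pd.Series(y).astype(str))
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ValidationError("vita selection needs >= 2 classes")
    if n_folds > n:
        import logging

        logging.getLogger(__name__).warning(
            "vita: reducing folds from %d to %d (too few samples)", n_folds, n
        )
        n_folds = n
    rng = np.random.default_rng(seed)
    importance = np.zeros(p)
    n_eval = 0
    for _ in range(max(1, n_repeats)):
        order = rng.permutation(n)
        folds = np.array_split(order, n_folds)
        for test_idx in folds:
            train_idx = np.setdiff1d(order, test_idx)
            if len(np.unique(y[train_idx])) < 2 or test_idx.size == 0:
                continue
            forest = SeededForest(
                n_trees=n_trees, seed=int(rng.integers(2**31 - 1))
            ).fit(X[train_idx], y[train_idx])
            class_pos = {c: i for i, c in enumerate(forest.classes_)}
            # labels unseen in this fold's training data can never be predicted
            y_codes = np.array([class_pos.get(lbl, -1) for lbl in y[test_idx]])
            Xt = np.ascontiguousarray(X[test_idx], dtype=np.float32)
            m = Xt.shape[0]
            fold_imp = np.zeros(p)
            for tree, used in zip(forest.trees_, forest.used_features_):
                if used.size == 0:
                    continue
                before = (_fast_predict(tree, Xt).astype(np.intp) == y_codes).astype(float)
                stacked = np.repeat(Xt[None, :, :], used.size, axis=0)
                for k, j in enumerate(used):
                    stacked[k, :, j] = Xt[rng.permutation(m), j]
                preds = _fast_predict(
                    tree, np.ascontiguousarray(stacked.reshape(-1, p))
                ).astype(np.intp)
                after = (preds.reshape(used.size, m) == y_codes[None, :]).astype(float)
                fold_imp[used] += (before[None, :] - after).mean(axis=1)
            importance += fold_imp / len(forest.trees_)
            n_eval += 1
    if n_eval:
        importance /= n_eval
    nonpos = importance[importance <= 0]
    null = np.concatenate([nonpos, -nonpos])
    if null.size == 0 or 1.0 / (1 + null.size) >= p_threshold:
        # the mirrored null is too small for the threshold to be
        # attainable (low-dimensional input): keep features whose
        # importance strictly exceeds every null value
        ceiling = null.max() if null.size else 0.0
        return np.flatnonzero(importance > ceiling)
    pvals = np.array(
        [(1 + (null >= v).sum()) / (1 + null.size) for v in importance]
    )
    return np.flatnonzero(pvals < p_threshold)


def partition(
    labels,
    scheme: str,
    seed: int = 0,
    vintages=None,
    holdout_vintage: str | None = None,
    train_fraction: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Train/test index partition.

    ``split70``: per-class stratified random split (~70:30, at least one
    test sample per class).  ``leave-one-vintage-out``: train on all other
    vintages, test on ``holdout_vintage``.  Every class must appear in the
    training set.
    """
    labels = np.asarray(pd.Series(labels).astype(str))
    n = len(labels)
    if scheme in ("split70", "70:30"):
        rng = np.random.default_rng(seed)
        train, test = [], []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if idx.size < 2:
                raise ValidationError(
                    f"class {cls!r} has {idx.size} sample(s); cannot stratify"
                )
            idx = rng.permutation(idx)
            n_train = int(round(train_fraction * idx.size))
            n_train = min(max(n_train, 1), idx.size - 1)
            train.extend(idx[:n_train])
            test.extend(idx[n_train:])
        return np.sort(np.array(train)), np.sort(np.array(test))
    if scheme in ("leave-one-vintage-out", "lovo"):
        if vintages is None or holdout_vintage is None:
            raise ValidationError("LOVO requires vintages and holdout_vintage")
        vint = np.asarray(pd.Series(vintages).astype(str))
        if len(vint) != n:
            raise ValidationError("vintages must align with labels")
        test = np.flatnonzero(vint == str(holdout_vintage))
        train = np.flatnonzero(vint != str(holdout_vintage))
        if test.size == 0:
            raise ValidationError(f"no samples from vintage {holdout_vintage!r}")
        missing = set(labels) - set(labels[train])
        if missing:
            raise ValidationError(
                f"class(es) absent from training vintages: {sorted(missing)}"
            )
        return train, test
    raise ValidationError(f"unknown partition scheme {scheme!r}")


def confusion_matrix(y_true, y_pred, classes=None) -> pd.DataFrame:
    y_true = np.asarray(pd.Series(y_true).astype(str))
    y_pred = np.asarray(pd.Series(y_pred).astype(str))
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = list(classes)
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    return mat


def kappa_from_confusion(mat: pd.DataFrame | np.ndarray) -> float:
    """Cohen's kappa from a confusion matrix (rows true, columns
    predicted): (p_o - p_e) / (1 - p_e), p_e from marginal products."""
    m = np.asarray(mat, dtype=float)
    total = m.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    p_o = np.trace(m) / total
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if p_e == 1:
        return 1.0 if p_o == 1 else 0.0
    return float((p_o - p_e) / (1 - p_e))


def evaluate(forest: SeededForest, X_test, y_test) -> dict:
    """Confusion matrix, accuracy (trace/total) and Cohen's kappa on a
    held-out test set."""
    y_test = np.asarray(pd.Series(y_test).astype(str))
    if len(y_test) == 0:
        raise ValidationError("empty test set")
    pred = forest.predict(X_test)
    mat = confusion_matrix(y_test, pred, classes=sorted(set(y_test) | set(pred)))
    accuracy = float(np.trace(mat.to_numpy()) / mat.to_numpy().sum())
    return {
        "confusion_matrix": mat,
        "accuracy": accuracy,
        "kappa": kappa_from_confusion(mat),
    }
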
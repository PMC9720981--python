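"""Random-forest ranking of immune/inflammation features for sepsis.

A bootstrap-per-tree forest (ntree = 500, mtry = floor(sqrt(p)) by default)
with out-of-bag (OOB) evaluation and permutation importance: for each tree,
the accuracy on its OOB samples is compared with the accuracy after permuting
one feature's OOB values, and the per-tree decreases are averaged into the
mean decrease in accuracy (MDA) that orders the feature ranking.  The
individual trees are sklearn ``DecisionTreeClassifier``s; the bootstrap, OOB
bookkeeping and MDA are implemented here so that every tree's OOB set is
explicit and the whole fit is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier

from . import stats as _stats

__all__ = ["SepsisForestRanker", "fit_rank", "univariate_feature_tests"]


class SepsisForestRanker(BaseEstimator, ClassifierMixin):
    """Random-forest classifier with OOB mean-decrease-in-accuracy ranking.

    Parameters
    ----------
    n_trees : number of bootstrap trees (default 500).
    mtry : features tried at each split; default ``floor(sqrt(p))``.
    stratified_bootstrap : resample within each class (keeps the bootstrap
        class balance equal to the sample's); default off.
    random_state : integer seed; the fit is deterministic given it.

    Attributes (after ``fit``)
    --------------------------
    feature_names_, mda_, ranking_, oob_accuracy_, confusion_,
    oob_predictions_, n_dropped_ (rows removed for missing values).
    """

    def __init__(
        self,
        n_trees: int = 500,
        mtry: int | None = None,
        stratified_bootstrap: bool = False,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.stratified_bootstrap = stratified_bootstrap
        self.random_state = random_state

    def fit(self, X, y):
        X_arr, y_arr, names, dropped = self._clean(X, y)
        n, p = X_arr.shape
        if p == 0:
            raise ValueError("no features supplied")
        classes, y_enc = np.unique(y_arr, return_inverse=True)
        if classes.size < 2:
            raise ValueError("labels contain a single class")
        counts = np.bincount(y_enc)
        if counts.min() < 2:
            raise ValueError("each class needs >= 2 samples")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        mtry = self.mtry if self.mtry is not None else max(1, int(np.floor(np.sqrt(p))))
        if not (1 <= mtry <= p):
            raise ValueError(f"mtry must be in [1, {p}], got {mtry}")

        ss = np.random.SeedSequence(self.random_state)
        tree_seeds = ss.spawn(self.n_trees)

        mda_sum = np.zeros(p)
        mda_trees = 0
        votes = np.zeros((n, classes.size), dtype=np.int64)
        per_class = [np.flatnonzero(y_enc == c) for c in range(classes.size)]
        trees = []

        for child in tree_seeds:
            rng = np.random.default_rng(child)
            if self.stratified_bootstrap:
                boot = np.concatenate(
                    [rng.choice(idx, size=idx.size, replace=True) for idx in per_class]
                )
            else:
                boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
            tree = DecisionTreeClassifier(
                max_features=mtry,
                random_state=int(rng.integers(0, 2 ** 31 - 1)),
            ).fit(X_arr[boot], y_enc[boot])
            trees.append(tree)
            if oob.size == 0:
                continue
            pred = tree.predict(X_arr[oob])
            votes[oob, pred] += 1
            acc = float(np.mean(pred == y_enc[oob]))
            X_oob = X_arr[oob]
            for j in range(p):
                Xp = X_oob.copy()
                Xp[:, j] = Xp[rng.permutation(oob.size), j]
                acc_perm = float(np.mean(tree.predict(Xp) == y_enc[oob]))
                mda_sum[j] += acc - acc_perm
            mda_trees += 1

        if mda_trees == 0:
            raise RuntimeError("no tree had out-of-bag samples; increase n")

        mda = mda_sum / mda_trees
        order = sorted(range(p), key=lambda j: (-mda[j], names[j]))

        covered = votes.sum(axis=1) > 0
        oob_pred = np.where(covered, votes.argmax(axis=1), -1)
        agree = oob_pred[covered] == y_enc[covered]

        confusion = np.zeros((classes.size, classes.size), dtype=np.int64)
        for true_c, pred_c in zip(y_enc[covered], oob_pred[covered]):
            confusion[true_c, pred_c] += 1

        self.classes_ = classes
        self.feature_names_ = names
        self.mda_ = dict(zip(names, mda))
        self.feature_importances_ = mda
        self.ranking_ = [names[j] for j in order]
        self.oob_accuracy_ = float(np.mean(agree))
        self.confusion_ = confusion
        self.oob_predictions_ = pd.Series(
            [classes[c] if c >= 0 else None for c in oob_pred]
        )
        self.n_dropped_ = dropped
        self._trees = trees
        self._y_encoder = {c: i for i, c in enumerate(classes)}
        return self

    def predict(self, X):
        X_arr = np.asarray(
            X.loc[:, self.feature_names_] if isinstance(X, pd.DataFrame) else X,
            dtype=float,
        )
        votes = np.zeros((X_arr.shape[0], self.classes_.size), dtype=np.int64)
        for tree in self._trees:
            votes[np.arange(X_arr.shape[0]), tree.predict(X_arr)] += 1
        return self.classes_[votes.argmax(axis=1)]

    @staticmethod
    def _clean(X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X_arr = X.to_numpy(dtype=float)
        else:
            X_arr = np.asarray(X, dtype=float)
            if X_arr.ndim != 2:
                raise ValueError("X must be 2-D")
            names = [f"f{j}" for j in range(X_arr.shape[1])]
        y_arr = np.asarray(y)
        if y_arr.shape[0] != X_arr.shape[0]:
            raise ValueError("X and y lengths differ")
        keep = np.all(np.isfinite(X_arr), axis=1)
        dropped = int(np.sum(~keep))
        return X_arr[keep], y_arr[keep], names, dropped


def fit_rank(
    features, labels, n_trees: int = 500, mtry: int | None = None,
    stratified_bootstrap: bool = False, seed: int | None = None,
) -> SepsisForestRanker:
    """Fit the forest and return the fitted ranker (functional front door)."""
    return SepsisForestRanker(
        n_trees=n_trees, mtry=mtry,
        stratified_bootstrap=stratified_bootstrap, random_state=seed,
    ).fit(features, labels)


def univariate_feature_tests(
    features: pd.DataFrame, labels, variant: str = "student"
) -> pd.DataFrame:
    """Per-feature two-group test of sepsis vs non-sepsis, sorted by p.

    Rows with a missing value for a given feature are dropped for that
    feature only.  Returns a DataFrame indexed by feature with columns
    ``statistic`` and ``p_value``.
    """
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("labels contain a single class")
    rows = []
    for name in features.columns:
        col = features[name].astype(float)
        ok = col.notna().to_numpy()
        r = _stats.two_group_test(
            col.to_numpy()[ok & y], col.to_numpy()[ok & ~y],
            variant=variant, labels=("sepsis", "no_sepsis"),
        )
        rows.append({"feature": name, "statistic": r.statistic, "p_value": r.p_value})
    out = pd.DataFrame(rows).set_index("feature")
    return out.sort_values("p_value", kind="mergesort")
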
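"""Random-forest classification of interaction types.

Two independent binary tasks share one 82-column feature matrix:
obligate vs non-obligate, and simultaneously-possible (SP) vs mutually
exclusive (ME).  Each task uses a small random forest (10 trees by
default) trained on a class-balanced subsample: the minority class is
kept whole and the majority class is randomly undersampled until the
minority makes up a target fraction of the training set (0.37 for
obligate/non-obligate, 0.31 for SP/ME by default).

The reported confidence of a prediction is the fraction of trees that
voted for the winning class — with 10 trees a multiple of 0.1.  A 5/5
split is *indecisive* and flagged as such; downstream analyses keep only
predictions whose confidence clears a cutoff (0.6 by default, i.e. a
margin of at least 0.2 between the classes).
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "InteractionTypeClassifier",
    "undersample",
    "crossvalidate",
    "predict_types",
    "apply_cutoff",
    "rank_features_wilcoxon",
    "DEFAULT_RUS_RATIO",
    "CONFIDENCE_GRID",
]

DEFAULT_RUS_RATIO = {"ob": 0.37, "spme": 0.31}
CONFIDENCE_GRID = [round(0.5 + 0.05 * i, 2) for i in range(11)]  # 0.5..1.0


def undersample(y: np.ndarray, ratio: float,
                rng: np.random.Generator) -> np.ndarray:
    """Indices of a random-undersampled two-class set.

    Keeps every minority row and downsamples the majority class without
    replacement so the minority fraction of the result is *ratio*
    (majority size = ceil(n_min * (1 - ratio) / ratio)).  If the input
    minority share already meets *ratio* the call is a no-op.
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"undersampling needs exactly 2 classes, got {list(classes)}")
    minority = classes[np.argmin(counts)]
    n_min = counts.min()
    if n_min / len(y) >= ratio:
        return np.arange(len(y))
    n_maj_target = int(np.ceil(n_min * (1 - ratio) / ratio))
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    keep_maj = rng.choice(maj_idx, size=min(n_maj_target, len(maj_idx)),
                          replace=False)
    return np.sort(np.concatenate([min_idx, keep_maj]))


class InteractionTypeClassifier(BaseEstimator, ClassifierMixin):
    """Random forest with random undersampling and vote-fraction
    confidences.

    Parameters
    ----------
    n_trees : int, default 10
        Number of decision trees in the forest.
    rus_ratio : float in (0, 1], default 0.37
        Target minority-class fraction after undersampling the training
        set (0.37 suits obligate/non-obligate, 0.31 SP/ME).
    random_state : int or None
        Seeds both the undersampling and the forest.

    Fitted attributes
    -----------------
    classes_ : ndarray of the two class labels (sorted).
    forest_ : the underlying RandomForestClassifier.
    medians_ : per-column imputation constants fitted on the
        undersampled training rows.
    sample_indices_ : indices (into the fit X) that survived RUS.
    """

    def __init__(self, n_trees: int = 10, rus_ratio: float = 0.37,
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.rus_ratio = rus_ratio
        self.random_state = random_state

    def _validate_X(self, X, reset: bool):
        if isinstance(X, pd.DataFrame):
            if reset:
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            elif hasattr(self, "feature_names_in_") and (
                    list(X.columns) != list(self.feature_names_in_)):
                raise ValueError("feature columns do not match the fitted model")
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if reset:
            self.n_features_in_ = X.shape[1]
        elif X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}")
        return X

    def fit(self, X, y):
        if not (isinstance(self.n_trees, numbers.Integral) and self.n_trees >= 1):
            raise ValueError("n_trees must be a positive integer")
        X = self._validate_X(X, reset=True)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly 2 classes required, got {list(self.classes_)}")
        rng = np.random.default_rng(self.random_state)
        idx = undersample(y, self.rus_ratio, rng)
        Xs, ys = X[idx], y[idx]
        if min(np.bincount(np.searchsorted(self.classes_, ys))) < 2:
            raise ValueError("need >= 2 rows per class after undersampling")
        self.sample_indices_ = idx
        with np.errstate(all="ignore"):
            med = np.nanmedian(Xs, axis=0)
        self.medians_ = np.where(np.isnan(med), 0.0, med)
        Xs = self._impute(Xs)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            random_state=int(rng.integers(2**31 - 1)))
        self.forest_.fit(Xs, ys)
        return self

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = X.copy()
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.take(self.medians_, np.nonzero(nan)[1])
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Vote fractions per class (columns ordered as ``classes_``).

        Unlike probability averaging, each tree casts one hard vote, so
        with n trees every value is a multiple of 1/n and the two
        columns sum to 1.
        """
        check_is_fitted(self, "forest_")
        X = self._impute(self._validate_X(X, reset=False))
        votes = np.zeros((len(X), 2))
        for tree in self.forest_.estimators_:
            pred = self.forest_.classes_[
                np.argmax(tree.predict_proba(X), axis=1)]
            for ci, c in enumerate(self.classes_):
                votes[pred == c, ci] += 1
        return votes / self.n_trees

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def confidence(self, X) -> np.ndarray:
        """Winning-class vote fraction per row (0.5 for a split vote)."""
        return self.predict_proba(X).max(axis=1)

    def indecisive(self, X) -> np.ndarray:
        """True where the vote is split exactly 0.5/0.5."""
        proba = self.predict_proba(X)
        return np.isclose(proba[:, 0], proba[:, 1])


def predict_types(model_ob: InteractionTypeClassifier,
                  model_sm: InteractionTypeClassifier,
                  X) -> pd.DataFrame:
    """Joint per-interaction predictions for both tasks.

    Returns a frame with class/confidence per task, indecisive flags,
    and the four-way combination label (``SP/obligate`` etc.; NaN when
    either task is indecisive).
    """
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    out = pd.DataFrame(index=index)
    for name, model in (("ob", model_ob), ("sm", model_sm)):
        out[f"class_{name}"] = model.predict(X)
        out[f"conf_{name}"] = model.confidence(X)
        out[f"indecisive_{name}"] = model.indecisive(X)
    combined = out["class_sm"].astype(str) + "/" + out["class_ob"].astype(str)
    combined[out["indecisive_ob"] | out["indecisive_sm"]] = np.nan
    out["combined"] = combined
    return out


def apply_cutoff(preds: pd.DataFrame, cutoff: float = 0.6,
                 ) -> tuple[pd.DataFrame, dict]:
    """Keep predictions whose confidence reaches *cutoff* in both tasks.

    The comparison is >= (a row exactly at the cutoff is kept).  Returns
    the filtered frame and counts per class and per four-way combination.
    """
    if not 0.5 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0.5, 1.0]")
    kept = preds[(preds["conf_ob"] >= cutoff) & (preds["conf_sm"] >= cutoff)
                 & ~preds["indecisive_ob"] & ~preds["indecisive_sm"]]
    counts = {
        "n_kept": int(len(kept)),
        "by_class_ob": kept["class_ob"].value_counts().to_dict(),
        "by_class_sm": kept["class_sm"].value_counts().to_dict(),
        "by_combination": kept["combined"].value_counts().to_dict(),
    }
    return kept, counts


def crossvalidate(X, y, estimator: InteractionTypeClassifier | None = None,
                  k: int = 10, seed: int | None = None,
                  cutoff_grid: list[float] = CONFIDENCE_GRID) -> dict:
    """Stratified k-fold cross-validation with pooled out-of-fold votes.

    Returns auROC (on vote-fraction scores for the second class in
    sorted order), per-class F-measure at the majority-vote threshold,
    and per-class precision at every confidence cutoff of the grid.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if estimator is None:
        estimator = InteractionTypeClassifier(random_state=seed)
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("cross-validation needs exactly 2 classes")
    if np.min(np.bincount(np.searchsorted(classes, y))) < k:
        raise ValueError("each class needs at least k rows for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof_proba = np.full((len(y), 2), np.nan)
    for fold, (tr, te) in enumerate(skf.split(Xdf, y)):
        model = clone(estimator)
        model.random_state = (seed or 0) * 1000 + fold
        model.fit(Xdf.iloc[tr], y[tr])
        oof_proba[te] = model.predict_proba(Xdf.iloc[te])
    scores = oof_proba[:, 1]           # vote fraction for classes[1]
    pred = classes[np.argmax(oof_proba, axis=1)]
    conf = oof_proba.max(axis=1)
    metrics = {
        "auroc": float(roc_auc_score(y == classes[1], scores)),
        "f_measure": {
            str(c): float(f1_score(y, pred, pos_label=c)) for c in classes},
        "precision_by_cutoff": {},
    }
    for cut in cutoff_grid:
        per_class = {}
        for ci, c in enumerate(classes):
            sel = (pred == c) & (conf >= cut)
            per_class[str(c)] = (
                float(np.mean(y[sel] == c)) if sel.any() else None)
        metrics["precision_by_cutoff"][f"{cut:.2f}"] = per_class
    return metrics


def rank_features_wilcoxon(X, y) -> pd.DataFrame:
    """Rank features by two-sided Wilcoxon rank-sum (Mann-Whitney U)
    p-value between the two classes.

    Returns a frame sorted by ascending p-value with the per-class
    means; features constant across both classes get p = 1 and a
    ``constant`` flag.  NaNs are ignored column-wise.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("feature ranking needs exactly 2 classes")
    rows = []
    for col in Xdf.columns:
        a = Xdf.loc[y == classes[0], col].dropna().to_numpy()
        b = Xdf.loc[y == classes[1], col].dropna().to_numpy()
        constant = len(np.unique(np.concatenate([a, b]))) <= 1
        if constant or len(a) == 0 or len(b) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({
            "feature": col,
            f"mean_{classes[0]}": float(a.mean()) if len(a) else np.nan,
            f"mean_{classes[1]}": float(b.mean()) if len(b) else np.nan,
            "p_value": p,
            "constant": bool(constant),
        })
    out = pd.DataFrame(rows).sort_values("p_value", kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
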
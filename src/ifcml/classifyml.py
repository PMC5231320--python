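"""Imbalance-aware multiclass training and evaluation.

The populations this toolkit targets are extremely imbalanced (thousands
of interphase cells against tens of anaphase/telophase cells), so training
sets are built by undersampling: classes above a cap are subsampled to the
cap, minority classes are kept whole.  Two tree-ensemble learners are
supported — gradient boosting (stage-wise shallow trees on multiclass
log-loss) and random forests (bootstrap-bagged deep trees with random
feature subsets) — evaluated by stratified k-fold cross-validation,
row-normalized percentage confusion matrices and per-class true positive
rates, plus impurity-based feature-importance rankings.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .containers import PHASES

ALGORITHMS = ("gradient_boosting", "random_forest")

#: Location/orientation features carry no phenotype signal.
DEFAULT_EXCLUDE_PATTERNS = ("*Orientation*", "*Location*", "*Center*")


# ---------------------------------------------------------------------------
# feature filtering and training-set construction
# ---------------------------------------------------------------------------

def _matches(name: str, pattern: str) -> bool:
    if any(ch in pattern for ch in "*?["):
        return fnmatch.fnmatch(name, pattern)
    return pattern in name


def filter_features(
    table: pd.DataFrame, exclude_patterns=DEFAULT_EXCLUDE_PATTERNS
) -> pd.DataFrame:
    """Drop feature columns matching any exclusion pattern (glob or
    substring); rows are untouched.  Excluding everything is an error."""
    drop = [
        col
        for col in table.columns
        if any(_matches(col, pat) for pat in exclude_patterns)
    ]
    kept = table.drop(columns=drop)
    if kept.shape[1] == 0:
        raise ValueError("exclusion patterns removed every feature column")
    return kept


@dataclass
class TrainingSet:
    cell_ids: list[str]
    labels: dict[str, str]
    counts_before: dict[str, int]
    counts_after: dict[str, int]
    cap: int
    seed: int


def build_training_set(
    labels: dict[str, str] | pd.Series, cap: int, seed: int = 0
) -> TrainingSet:
    """Undersample overrepresented classes to ``cap`` members (without
    replacement, seeded); minority classes keep every member."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    by_class: dict[str, list[str]] = {}
    for cid, lab in labels.items():
        by_class.setdefault(lab, []).append(cid)
    if len(by_class) < 2:
        raise ValueError("need at least two classes to build a training set")

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    counts_before, counts_after = {}, {}
    order = [p for p in PHASES if p in by_class] + sorted(
        set(by_class) - set(PHASES)
    )
    for lab in order:
        members = by_class[lab]
        counts_before[lab] = len(members)
        if len(members) > cap:
            picked = list(rng.choice(members, size=cap, replace=False))
        else:
            picked = list(members)
        counts_after[lab] = len(picked)
        chosen.extend(picked)
    return TrainingSet(
        chosen, {cid: labels[cid] for cid in chosen}, counts_before, counts_after,
        cap, seed,
    )


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

class PhaseClassifier(ClassifierMixin, BaseEstimator):
    """Cell-cycle phase classifier over extracted image features.

    Parameters
    ----------
    algorithm : "gradient_boosting" or "random_forest"
    cap : int or None
        Undersampling cap applied inside ``fit``; ``None`` trains on all
        rows as given.
    exclude_patterns : sequence of str
        Feature-name patterns removed before training (location and
        orientation features by default).
    n_estimators, max_depth, learning_rate
        Ensemble size and tree shape.  Gradient boosting defaults to 300
        shallow (depth-3) stages at learning rate 0.1; random forests to
        500 fully grown trees with sqrt(p) features per split.

    Fitted attributes: ``estimator_``, ``classes_`` (fixed phase order),
    ``feature_names_``, ``training_ids_``, ``counts_before_``,
    ``counts_after_``.
    """

    def __init__(
        self,
        algorithm: str = "gradient_boosting",
        cap: int | None = None,
        exclude_patterns=DEFAULT_EXCLUDE_PATTERNS,
        n_estimators: int | None = None,
        max_depth: int | None = None,
        learning_rate: float = 0.1,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.cap = cap
        self.exclude_patterns = exclude_patterns
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _make_estimator(self):
        if self.algorithm == "gradient_boosting":
            return GradientBoostingClassifier(
                n_estimators=self.n_estimators or 300,
                max_depth=self.max_depth or 3,
                learning_rate=self.learning_rate,
                random_state=self.random_state,
            )
        if self.algorithm == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_estimators or 500,
                max_depth=self.max_depth,
                max_features="sqrt",
                random_state=self.random_state,
            )
        raise ValueError(
            f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
        )

    def fit(self, X: pd.DataFrame, y):
        """Fit on a feature table indexed by cell_id.

        ``y`` is a label Series/array aligned with ``X``.  When ``cap`` is
        set, overrepresented classes are undersampled first and the chosen
        ids recorded in ``training_ids_``.
        """
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [str(c) for c in X.columns]
        y = pd.Series(np.asarray(y), index=X.index)
        present = y.unique()
        if len(present) < 2:
            raise ValueError("training set contains a single class")

        X = filter_features(X, self.exclude_patterns)
        if self.cap is not None:
            ts = build_training_set(y.to_dict(), self.cap, self.random_state)
            self.counts_before_ = ts.counts_before
            self.counts_after_ = ts.counts_after
            X, y = X.loc[ts.cell_ids], y.loc[ts.cell_ids]
        else:
            counts = y.value_counts().to_dict()
            self.counts_before_ = counts
            self.counts_after_ = dict(counts)

        self.classes_ = np.array(
            [p for p in PHASES if p in set(y)]
            + sorted(set(y) - set(PHASES))
        )
        self.feature_names_ = list(X.columns)
        self.training_ids_ = list(X.index)
        self.estimator_ = self._make_estimator()
        self.estimator_.fit(X.to_numpy(dtype=float), y.to_numpy())
        return self

    def _check_table(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names_ if f not in X.columns]
            if missing:
                raise ValueError(f"missing feature column(s): {missing[:5]}")
            return X[self.feature_names_].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities in this classifier's ``classes_`` order."""
        arr = self._check_table(X)
        proba = self.estimator_.predict_proba(arr)
        order = [list(self.estimator_.classes_).index(c) for c in self.classes_]
        return proba[:, order]

    def predict(self, X) -> np.ndarray:
        """Argmax prediction; ties broken by the fixed phase order."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    @property
    def feature_importances_(self) -> pd.Series:
        check_is_fitted(self, "estimator_")
        return pd.Series(
            self.estimator_.feature_importances_, index=self.feature_names_
        )


def train_classifier(
    ts: TrainingSet,
    table: pd.DataFrame,
    algorithm: str = "gradient_boosting",
    params: dict | None = None,
    seed: int = 0,
) -> PhaseClassifier:
    """Train on the rows named by a prebuilt TrainingSet."""
    clf = PhaseClassifier(
        algorithm=algorithm, cap=None, random_state=seed, **(params or {})
    )
    X = table.loc[ts.cell_ids]
    y = pd.Series([ts.labels[cid] for cid in ts.cell_ids], index=ts.cell_ids)
    return clf.fit(X, y)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Row-normalized percentage confusion matrix and per-class TPR.

    Rows with zero support hold NaN and are excluded from macro averages;
    the diagonal equals the per-class true positive rate.
    """

    confusion: pd.DataFrame  # class_order x class_order, percentages
    tpr: pd.Series
    n_per_class: pd.Series
    note: str = ""

    @property
    def macro_tpr(self) -> float:
        return float(self.tpr.dropna().mean())

    def to_json_dict(self) -> dict:
        return {
            "confusion_pct": self.confusion.where(self.confusion.notna(), None)
            .round(4)
            .to_dict(orient="index"),
            "tpr": {k: (None if pd.isna(v) else round(float(v), 6))
                    for k, v in self.tpr.items()},
            "n_per_class": {k: int(v) for k, v in self.n_per_class.items()},
            "macro_tpr": round(self.macro_tpr, 6),
            "note": self.note,
        }


def confusion_matrix_pct(
    true_labels, predicted, class_order=PHASES, note: str = ""
) -> EvaluationReport:
    """Entry (i, j) = 100 * |true=i and pred=j| / |true=i|."""
    true_labels = np.asarray(true_labels)
    predicted = np.asarray(predicted)
    if true_labels.shape != predicted.shape:
        raise ValueError("label vectors differ in length")
    unknown = set(true_labels) | set(predicted)
    unknown -= set(class_order)
    if unknown:
        raise ValueError(f"labels outside class order: {sorted(unknown)}")

    class_order = list(class_order)
    counts = pd.DataFrame(0, index=class_order, columns=class_order, dtype=float)
    for t, p in zip(true_labels, predicted):
        counts.loc[t, p] += 1
    support = counts.sum(axis=1)
    confusion = counts.div(support.replace(0, np.nan), axis=0) * 100.0
    tpr = pd.Series(np.diag(confusion) / 100.0, index=class_order)
    return EvaluationReport(confusion, tpr, support.astype(int), note)


def _stratified_folds(
    y: pd.Series, k: int, seed: int
) -> list[np.ndarray]:
    """Round-robin per-class fold assignment after a seeded shuffle; a
    class with fewer than k members lands in that many folds."""
    rng = np.random.default_rng(seed)
    fold_of = pd.Series(-1, index=y.index, dtype=int)
    for lab in sorted(y.unique()):
        members = y.index[y == lab].to_numpy()
        members = members[rng.permutation(len(members))]
        fold_of.loc[members] = np.arange(len(members)) % k
    return [fold_of.index[fold_of == f].to_numpy() for f in range(k)]


def cross_validate(
    ts: TrainingSet,
    table: pd.DataFrame,
    algorithm: str = "gradient_boosting",
    k: int = 10,
    seed: int = 0,
    params: dict | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the training set; the report
    aggregates held-out predictions over all folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ts.cell_ids):
        raise ValueError(f"k={k} exceeds training-set size {len(ts.cell_ids)}")
    y = pd.Series([ts.labels[cid] for cid in ts.cell_ids], index=ts.cell_ids)
    X = table.loc[ts.cell_ids]

    all_true, all_pred = [], []
    for fold_ids in _stratified_folds(y, k, seed):
        if len(fold_ids) == 0:
            continue
        train_ids = y.index.difference(fold_ids, sort=False)
        if y.loc[train_ids].nunique() < 2:
            continue
        clf = PhaseClassifier(
            algorithm=algorithm, cap=None, random_state=seed, **(params or {})
        ).fit(X.loc[train_ids], y.loc[train_ids])
        all_true.extend(y.loc[fold_ids])
        all_pred.extend(clf.predict(X.loc[fold_ids]))
    return confusion_matrix_pct(
        all_true, all_pred, note=f"{k}-fold cross-validation of the training set"
    )


def score_all(model: PhaseClassifier, table: pd.DataFrame) -> pd.Series:
    """Predict every cell not in the training set (exclusion is by id)."""
    check_is_fitted(model, "estimator_")
    missing = [f for f in model.feature_names_ if f not in table.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing[:5]}")
    test_ids = [cid for cid in table.index if cid not in set(model.training_ids_)]
    if not test_ids:
        return pd.Series(dtype=object, name="predicted")
    preds = model.predict(table.loc[test_ids])
    return pd.Series(preds, index=test_ids, name="predicted")


def rank_features(model: PhaseClassifier, k: int = 20) -> pd.DataFrame:
    """Top-k features by importance, ties broken lexicographically."""
    imp = model.feature_importances_
    order = sorted(imp.items(), key=lambda item: (-item[1], item[0]))[:k]
    return pd.DataFrame(
        [
            {"rank": i + 1, "feature": name, "score": float(score)}
            for i, (name, score) in enumerate(order)
        ]
    )
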
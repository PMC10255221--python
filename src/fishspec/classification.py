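"""Per-mode freshness-day classification and accuracy metrics.

Base models span the conventional chemometric set (decision tree, random
forest, naive Bayes, KNN, LDA, QDA, SVC, logistic regression) with
pinned defaults; the stacking ensemble trains LR / RF / KNN base models
and an LDA meta-model on the original spectral features *augmented*
with the base models' predicted labels — not on the predictions alone.
Accuracy is reported exactly, within a +/- day tolerance, and after
collapsing days into freshness grades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .containers import VoxelTable

#: pinned model defaults, so results reproduce across library versions
MODEL_DEFAULTS: dict[str, dict] = {
    "DT": {},
    "RF": {"n_estimators": 100},
    "NB": {},
    "KNN": {"n_neighbors": 5},
    "LDA": {},
    "QDA": {},
    "SVC": {"C": 1.0, "kernel": "rbf"},
    "LR": {"max_iter": 1000},  # raised iteration cap; all else default
}


@dataclass
class ModelSpec:
    """Named classifier with hyperparameter overrides and a seed."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


def _build_estimator(spec: ModelSpec):
    params = {**MODEL_DEFAULTS.get(spec.name, {}), **spec.hyperparameters}
    seeded = {"DT", "RF", "SVC", "LR"}
    if spec.name in seeded:
        params.setdefault("random_state", spec.seed)
    builders = {
        "DT": DecisionTreeClassifier,
        "RF": RandomForestClassifier,
        "NB": GaussianNB,
        "KNN": KNeighborsClassifier,
        "LDA": LinearDiscriminantAnalysis,
        "QDA": QuadraticDiscriminantAnalysis,
        "SVC": SVC,
        "LR": LogisticRegression,
    }
    if spec.name == "STACKING":
        return StackedSpectrumClassifier(random_state=spec.seed)
    if spec.name not in builders:
        raise ValueError(f"unknown model {spec.name!r}")
    return builders[spec.name](**params)


class StackedSpectrumClassifier(BaseEstimator, ClassifierMixin):
    """Stacking ensemble: LR / RF / KNN bases, LDA meta-model.

    The base models are fitted on the training spectra; their predicted
    class labels (as integers) are appended as three extra columns to
    the original feature block, and the LDA meta-model is trained on
    that augmented matrix.  Prediction applies the same augmentation.
    The fitted ``meta_feature_width_`` therefore equals the band count
    plus the number of base models.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def _base_specs(self):
        return [
            ("LR", LogisticRegression(max_iter=1000,
                                      random_state=self.random_state)),
            ("RF", RandomForestClassifier(n_estimators=100,
                                          random_state=self.random_state)),
            ("KNN", KNeighborsClassifier(n_neighbors=5)),
        ]

    def _augment(self, X):
        preds = [
            np.searchsorted(self.classes_, m.predict(X))
            for _, m in self.base_models_
        ]
        return np.column_stack([X, *preds])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.base_models_ = [(n, clone(m).fit(X, y))
                             for n, m in self._base_specs()]
        Xa = self._augment(X)
        self.meta_model_ = LinearDiscriminantAnalysis().fit(Xa, y)
        self.meta_feature_width_ = Xa.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "meta_model_")
        return self.meta_model_.predict(self._augment(np.asarray(X, dtype=float)))


# ---------------------------------------------------------------------------
# table-level operations

def _xy(table: VoxelTable):
    return table.spectra(), table.days()


def split_train_test(table: VoxelTable, train_frac: float = 0.8,
                     seed: int = 0) -> tuple[VoxelTable, VoxelTable]:
    """Disjoint, exhaustive, day-stratified split of the kept voxels."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    frame = table.frame[table.frame["kept"]].reset_index(drop=True)
    counts = frame["day"].value_counts()
    if (counts < 2).any():
        raise ValueError("every day class needs at least 2 rows to split")
    idx_train, idx_test = train_test_split(
        np.arange(len(frame)), train_size=train_frac,
        stratify=frame["day"], random_state=seed,
    )
    return (
        VoxelTable(frame=frame.iloc[np.sort(idx_train)].reset_index(drop=True),
                   mode=table.mode),
        VoxelTable(frame=frame.iloc[np.sort(idx_test)].reset_index(drop=True),
                   mode=table.mode),
    )


def fit_model(spec: ModelSpec, train: VoxelTable):
    """Fit one named classifier on a voxel table's kept spectra."""
    X, y = _xy(train)
    if len(X) == 0:
        raise ValueError("empty training table")
    if len(np.unique(y)) < 2:
        raise ValueError("training table needs at least 2 day classes")
    model = _build_estimator(spec)
    try:
        return model.fit(X, y)
    except np.linalg.LinAlgError as err:
        if spec.name == "QDA":
            raise ValueError(
                "singular within-class covariance for QDA; consider the "
                "reg_param hyperparameter"
            ) from err
        raise


def fit_stacking(train: VoxelTable, seed: int = 0) -> StackedSpectrumClassifier:
    """Fit the LR/RF/KNN -> LDA stacking ensemble on a voxel table."""
    return fit_model(ModelSpec(name="STACKING", seed=seed), train)


def crossval(table: VoxelTable, spec: ModelSpec, k: int = 5,
             seed: int = 0) -> np.ndarray:
    """Stratified k-fold cross-validation accuracies (one per fold)."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    X, y = _xy(table)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError("every class needs at least k rows for k folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        model = _build_estimator(spec).fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[te]) == y[te])))
    return np.array(accs)


# ---------------------------------------------------------------------------
# confusion matrices and accuracy families

@dataclass
class ConfusionMatrix:
    """True-day x predicted-day count matrix over ordered day classes."""

    class_days: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.class_days)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over class_days")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        """Exact-class accuracy: trace over total."""
        return float(np.trace(self.counts)) / self.total


def evaluate_model(model, test: VoxelTable,
                   class_days=None) -> ConfusionMatrix:
    """Confusion matrix of a fitted model on a test voxel table."""
    X, y = _xy(test)
    if len(X) == 0:
        raise ValueError("empty test table")
    pred = model.predict(X)
    days = tuple(class_days) if class_days is not None else tuple(
        sorted(np.unique(y))
    )
    unknown = set(pred) - set(days)
    if unknown:
        raise ValueError(f"predicted labels outside class days: {unknown}")
    counts = _sk_confusion(y, pred, labels=list(days))
    return ConfusionMatrix(class_days=days, counts=counts)


def confusion_from_predictions(true_day, predicted_day,
                               class_days) -> ConfusionMatrix:
    counts = _sk_confusion(true_day, predicted_day, labels=list(class_days))
    return ConfusionMatrix(class_days=tuple(class_days), counts=counts)


def tolerance_accuracy(cm: ConfusionMatrix, tolerance_days: float = 1) -> float:
    """Accuracy counting predictions within ``tolerance_days`` of truth.

    With day classes {1,3,7,9,11} (minimum gap 2), tolerance 1 equals
    exact-class accuracy: the window only matters for denser day grids.
    """
    if tolerance_days < 0:
        raise ValueError("tolerance must be non-negative")
    days = np.asarray(cm.class_days, dtype=float)
    hit = np.abs(days[:, None] - days[None, :]) <= tolerance_days
    return float(cm.counts[hit].sum()) / cm.total


def grouped_accuracy(cm: ConfusionMatrix, grouping: dict) -> float:
    """Accuracy after collapsing days into freshness grades.

    ``grouping`` maps every class day to a grade label (e.g. fresh /
    fairly fresh / spoilt); counts are collapsed on both axes and the
    trace-over-total of the collapsed matrix is returned.
    """
    missing = [d for d in cm.class_days if d not in grouping]
    if missing:
        raise ValueError(f"days missing from grouping: {missing}")
    grades = sorted({grouping[d] for d in cm.class_days}, key=str)
    gi = {g: i for i, g in enumerate(grades)}
    collapsed = np.zeros((len(grades), len(grades)), dtype=cm.counts.dtype)
    for i, di in enumerate(cm.class_days):
        for j, dj in enumerate(cm.class_days):
            collapsed[gi[grouping[di]], gi[grouping[dj]]] += cm.counts[i, j]
    return float(np.trace(collapsed)) / cm.total
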
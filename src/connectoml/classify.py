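"""Discriminative pipeline: split, normalize, select, fit, evaluate, permute.

The protocol mirrors common neuroimaging ML practice: a stratified 4:1
train/test split; per-feature min-max normalization fit on the training set
only; recursive feature elimination (RFE) whose retained-set size is chosen
by 10-fold cross-validated accuracy on the training set; a final refit on
the full training set; evaluation on the untouched test set (accuracy,
sensitivity, specificity, ROC/AUC); and significance by rerunning the whole
pipeline under random permutations of the *training* labels.

Nothing fit here ever sees test rows: normalization parameters and RFE
selections derive from training data alone, which the test suite audits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ContractError

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIER_NAMES",
    "FeatureMatrix",
    "NormalizationParams",
    "ClassificationResult",
    "PipelineConfig",
    "feature_matrix_from_tables",
    "split_train_test",
    "minmax_fit",
    "minmax_apply",
    "rfe_select",
    "train_classifier",
    "evaluate",
    "run_pipeline",
    "permutation_test",
]

CLASSIFIER_NAMES = ("SVM", "RF", "LR", "LDA", "KNN")

#: RFE defaults: drop 10% of remaining features per round; candidate
#: retained-set sizes as fractions of the full feature count.
RFE_STEP_FRACTION = 0.10
RFE_TARGET_GRID = (0.01, 0.02, 0.05, 0.10, 0.20, 0.50, 1.00)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Subjects x features with (modality, roi, metric) annotations."""

    X: np.ndarray
    y: np.ndarray
    annotations: pd.DataFrame  # columns: modality, roi, metric
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ContractError("X must be 2-D (subjects x features)")
        if len(self.y) != self.X.shape[0]:
            raise ContractError("labels must match the number of subjects")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ContractError("labels must be binary 0/1")
        if len(self.annotations) != self.X.shape[1]:
            raise ContractError("annotation length must equal feature count")
        if not np.all(np.isfinite(self.X)):
            raise ContractError("feature values must be finite")
        if len(np.unique(self.y)) < 2:
            raise ContractError("labels must include both classes")
        if self.subject_ids is None:
            self.subject_ids = [f"s{i}" for i in range(self.X.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray | None = None,
               cols: np.ndarray | None = None) -> "FeatureMatrix":
        rows = np.arange(self.n_subjects) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_features) if cols is None else np.asarray(cols)
        return FeatureMatrix(
            X=self.X[np.ix_(rows, cols)],
            y=self.y[rows],
            annotations=self.annotations.iloc[cols].reset_index(drop=True),
            subject_ids=[self.subject_ids[i] for i in rows],
        )


def feature_matrix_from_tables(
    tables: dict[str, pd.DataFrame], labels: dict[str, int]
) -> FeatureMatrix:
    """Assemble a FeatureMatrix from per-subject long-format metric tables.

    ``tables`` maps subject_id to a DataFrame with columns (modality, roi,
    metric, value); ``labels`` maps subject_id to 0/1. Features are ordered
    by (modality, metric, roi) consistently across subjects.
    """
    subject_ids = sorted(tables)
    first = tables[subject_ids[0]].sort_values(
        ["modality", "metric", "roi"], kind="stable"
    )
    annotations = first[["modality", "roi", "metric"]].reset_index(drop=True)
    rows = []
    for sid in subject_ids:
        t = tables[sid].sort_values(["modality", "metric", "roi"], kind="stable")
        if len(t) != len(annotations):
            raise ContractError(f"subject {sid!r} has a mismatched feature set")
        rows.append(t["value"].to_numpy())
    y = np.array([labels[sid] for sid in subject_ids])
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise ContractError(f"need >= 2 subjects in class {cls}")
    return FeatureMatrix(
        X=np.vstack(rows), y=y, annotations=annotations, subject_ids=subject_ids
    )


@dataclass
class NormalizationParams:
    """Per-feature min/max learned from training data."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maximum < self.minimum):
            raise ContractError("max must be >= min per feature")


@dataclass
class ClassificationResult:
    classifier: str
    selected_features: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    permutation_p: float | None = None
    feature_weights: np.ndarray | None = None  # full-length, 0 for eliminated


@dataclass
class PipelineConfig:
    """Everything needed to rerun the classification end to end."""

    classifier: str = "SVM"
    use_rfe: bool = True
    rfe_step: float = RFE_STEP_FRACTION
    rfe_target_grid: tuple[float, ...] = RFE_TARGET_GRID
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIER_NAMES:
            raise ContractError(
                f"unknown classifier {self.classifier!r}; one of {CLASSIFIER_NAMES}"
            )


# ---------------------------------------------------------------------------
# split and normalization
# ---------------------------------------------------------------------------

def split_train_test(
    features: FeatureMatrix, test_fraction: float = 0.2, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified 4:1 split; reproducible under the seed."""
    for cls in (0, 1):
        if np.sum(features.y == cls) < 5:
            raise ContractError(f"class {cls} has fewer than 5 subjects")
    idx = np.arange(features.n_subjects)
    n_test = int(round(features.n_subjects * test_fraction))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=n_test,
        stratify=features.y,
        random_state=seed,
        shuffle=True,
    )
    return features.subset(rows=np.sort(train_idx)), features.subset(
        rows=np.sort(test_idx)
    )


def minmax_fit(train_X: np.ndarray) -> NormalizationParams:
    """Learn per-feature min/max from training data only."""
    train_X = np.asarray(train_X, dtype=float)
    params = NormalizationParams(
        minimum=train_X.min(axis=0), maximum=train_X.max(axis=0)
    )
    n_constant = int(np.sum(params.maximum == params.minimum))
    if n_constant:
        logger.warning(
            "%d constant training feature(s) will be mapped to 0", n_constant
        )
    return params


def minmax_apply(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); values outside the training range are NOT
    clipped, so test data may fall outside [0, 1]. Constant features map to 0."""
    span = params.maximum - params.minimum
    safe = np.where(span > 0, span, 1.0)
    out = (np.asarray(X, dtype=float) - params.minimum) / safe
    out[:, span == 0] = 0.0
    return out


# ---------------------------------------------------------------------------
# estimators and importances
# ---------------------------------------------------------------------------

def train_classifier(name: str, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit one of the five classifiers with conventional fixed hyperparameters."""
    if name == "SVM":
        model = SVC(kernel="linear", C=1.0, random_state=seed)
    elif name == "RF":
        model = RandomForestClassifier(n_estimators=500, random_state=seed)
    elif name == "LR":
        # L2-regularized by default
        model = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    elif name == "LDA":
        model = LinearDiscriminantAnalysis()
    elif name == "KNN":
        model = KNeighborsClassifier(n_neighbors=5)
    else:
        raise ContractError(f"unknown classifier {name!r}")
    return model.fit(X, y)


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous score for ROC analysis (margin or positive-class probability)."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def _importances(name: str, model, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature importance used by RFE ranking.

    Linear models use |coefficient|; RF uses impurity importance; KNN, which
    exposes no importances, falls back to the univariate ANOVA F-score.
    """
    if name in {"SVM", "LR", "LDA"}:
        return np.abs(np.asarray(model.coef_).ravel())
    if name == "RF":
        return np.asarray(model.feature_importances_)
    if name == "KNN":
        f, _ = f_classif(X, y)
        return np.nan_to_num(f, nan=0.0)
    raise ContractError(f"no importance rule for {name!r}")


# ---------------------------------------------------------------------------
# recursive feature elimination
# ---------------------------------------------------------------------------

def _rfe_path(
    name: str, X: np.ndarray, y: np.ndarray, sizes: list[int],
    step: float, seed: int,
) -> dict[int, np.ndarray]:
    """One elimination trajectory, recording the surviving set at each size."""
    active = np.arange(X.shape[1])
    subsets: dict[int, np.ndarray] = {}
    targets = sorted(set(sizes), reverse=True)
    for target in targets:
        while len(active) > target:
            model = train_classifier(name, X[:, active], y, seed=seed)
            imp = _importances(name, model, X[:, active], y)
            n_drop = max(1, int(round(step * len(active))))
            n_drop = min(n_drop, len(active) - target)
            # drop the lowest-importance features; ties broken by index
            order = np.argsort(imp, kind="stable")
            active = np.sort(active[order[n_drop:]])
        subsets[target] = active.copy()
    return subsets


def _cv_accuracy(
    name: str, X: np.ndarray, y: np.ndarray, cols: np.ndarray,
    cv_folds: int, seed: int,
) -> float:
    n_splits = min(cv_folds, int(np.min(np.bincount(y))))
    if n_splits < 2:
        raise ContractError("too few subjects per class for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for fit_idx, val_idx in skf.split(X, y):
        model = train_classifier(name, X[np.ix_(fit_idx, cols)], y[fit_idx],
                                 seed=seed)
        pred = model.predict(X[np.ix_(val_idx, cols)])
        accs.append(float(np.mean(pred == y[val_idx])))
    return float(np.mean(accs))


def rfe_select(
    estimator_name: str,
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 10,
    step: float = RFE_STEP_FRACTION,
    target_grid: tuple[float, ...] = RFE_TARGET_GRID,
    seed: int = 0,
) -> np.ndarray:
    """RFE on training data; retained-set size picked by mean k-fold CV accuracy.

    Each round drops the lowest-importance ``step`` fraction of surviving
    features and refits. Candidate sizes are the ``target_grid`` fractions of
    the full feature count; the size with the best mean CV accuracy wins
    (larger size on ties, erring on the side of keeping features).
    """
    n_features = X.shape[1]
    sizes = sorted({max(1, int(round(f * n_features))) for f in target_grid},
                   reverse=True)
    subsets = _rfe_path(estimator_name, X, y, sizes, step, seed)
    best_cols, best_acc = None, -np.inf
    for size in sizes:  # descending: ties keep the larger feature set
        cols = subsets[size]
        acc = _cv_accuracy(estimator_name, X, y, cols, cv_folds, seed)
        if acc > best_acc:
            best_cols, best_acc = cols, acc
    return best_cols


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(model, X_test: np.ndarray, y_test: np.ndarray) -> dict:
    """Accuracy, sensitivity/specificity (positive class = 1), ROC, AUC."""
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise ContractError("test set must contain both classes for ROC/AUC")
    pred = np.asarray(model.predict(X_test))
    scores = decision_scores(model, X_test)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    fpr, tpr, _ = roc_curve(y_test, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return {
        "accuracy": (tp + tn) / len(y_test),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "roc_fpr": fpr,
        "roc_tpr": tpr,
        "auc": auc,
    }


def run_pipeline(
    config: PipelineConfig, train: FeatureMatrix, test: FeatureMatrix,
    y_train: np.ndarray | None = None,
) -> ClassificationResult:
    """Normalize -> (RFE) -> fit on all training data -> evaluate on test.

    ``y_train`` optionally overrides the training labels (used by the
    permutation test); test rows never influence any fitted component.
    """
    y_tr = train.y if y_train is None else np.asarray(y_train, dtype=int)
    params = minmax_fit(train.X)
    X_tr = minmax_apply(params, train.X)
    X_te = minmax_apply(params, test.X)

    if config.use_rfe:
        cols = rfe_select(
            config.classifier, X_tr, y_tr,
            cv_folds=config.cv_folds, step=config.rfe_step,
            target_grid=config.rfe_target_grid, seed=config.seed,
        )
    else:
        cols = np.arange(train.n_features)

    model = train_classifier(config.classifier, X_tr[:, cols], y_tr,
                             seed=config.seed)
    metrics = evaluate(model, X_te[:, cols], test.y)

    weights = None
    if hasattr(model, "coef_"):
        weights = np.zeros(train.n_features)
        weights[cols] = np.asarray(model.coef_).ravel()
    return ClassificationResult(
        classifier=config.classifier,
        selected_features=cols,
        accuracy=metrics["accuracy"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        roc_fpr=metrics["roc_fpr"],
        roc_tpr=metrics["roc_tpr"],
        auc=metrics["auc"],
        feature_weights=weights,
    )


def permutation_test(
    config: PipelineConfig,
    train: FeatureMatrix,
    test: FeatureMatrix,
    observed_auc: float,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Label-permutation significance of the observed test AUC.

    Each replicate permutes the *training* labels only, reruns the entire
    pipeline (normalization, feature selection, fit) and re-evaluates on the
    untouched test set. The add-one estimator
    ``p = (1 + #{AUC_b >= AUC_obs}) / (B + 1)`` keeps p strictly positive.
    """
    if n_permutations < 1:
        raise ContractError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        permuted = rng.permutation(train.y)
        if len(np.unique(permuted)) < 2:
            continue
        result = run_pipeline(config, train, test, y_train=permuted)
        if result.auc >= observed_auc:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)
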
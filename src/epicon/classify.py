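"""Feature normalization, reduction, model training and evaluation.

Protocol: stratified 80/20 train/test split; z-scoring with train statistics
(population sigma); one of four reductions (ANOVA K-best, PCA, correlation
pruning + ANOVA, none) fitted inside each CV fold; grid-searched SVM / MLP /
RFC / logistic-regression classifiers scored by mean 5-fold CV AUC; test-set
ROC with a 100-permutation surrogate AUC band and a Youden-J optimal cut-off;
optional AND/OR fusion with the clinician's EEG reading.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectKBest, VarianceThreshold, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import (GridSearchCV, StratifiedKFold,
                                     train_test_split)
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

MODEL_KINDS = ("svm", "mlp", "rfc", "logreg")
REDUCTIONS = ("anova", "pca", "corr+anova", "none")


# ---------------------------------------------------------------------------
# splitting and normalization

def split_train_test(X: np.ndarray, y: np.ndarray, ratio: float = 0.8,
                     seed: int = 0):
    """Stratified split preserving class proportions; deterministic by seed."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for a stratified split")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=1 - ratio, stratify=y,
                              random_state=seed)
    return np.sort(tr), np.sort(te)


def normalize(train: np.ndarray, test: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x - mu) / sigma with train statistics (population sigma).

    Zero-variance features are dropped from both sets; returns the kept
    column indices as the third element.
    """
    mu = train.mean(axis=0)
    sigma = train.std(axis=0)  # population
    keep = np.flatnonzero(sigma > 0)
    if keep.size < train.shape[1]:
        logger.warning("dropping %d constant feature(s)",
                       train.shape[1] - keep.size)
    tr = (train[:, keep] - mu[keep]) / sigma[keep]
    te = (test[:, keep] - mu[keep]) / sigma[keep]
    return tr, te, keep


def anova_kbest(train: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the top-k features by one-way ANOVA F; ties to lower index."""
    if k > train.shape[1]:
        raise ValueError("k exceeds the feature count")
    F, _ = f_classif(train, y)
    F = np.nan_to_num(F, nan=0.0)
    order = np.argsort(-F, kind="stable")
    return np.sort(order[:k])


def pca_reduce(train: np.ndarray, test: np.ndarray, n_components: int,
               seed: int = 0):
    """PCA fitted on train only; returns transformed sets and loadings."""
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    tr = pca.fit_transform(train)
    te = pca.transform(test)
    return tr, te, pca.components_


def correlation_prune(train: np.ndarray, threshold: float = 0.92) -> np.ndarray:
    """Retained feature indices after deterministic correlation pruning.

    Iterating in canonical column order, a feature is removed when its |r|
    with any already-retained feature is strictly above the threshold.
    """
    n = train.shape[1]
    if n < 2:
        raise ValueError("need at least 2 features")
    sd = train.std(axis=0)
    centered = train - train.mean(axis=0)
    denom = np.where(sd > 0, sd, 1.0) * np.sqrt(train.shape[0])
    Z = centered / denom
    corr = np.abs(Z.T @ Z)
    retained: list[int] = []
    for j in range(n):
        if sd[j] == 0:
            retained.append(j)  # constant columns are not "correlated"
            continue
        if any(sd[i] > 0 and corr[j, i] > threshold for i in retained):
            continue
        retained.append(j)
    return np.array(retained, dtype=int)


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """sklearn transformer wrapper around :func:`correlation_prune`."""

    def __init__(self, threshold: float = 0.92):
        self.threshold = threshold

    def fit(self, X, y=None):
        self.retained_ = correlation_prune(np.asarray(X), self.threshold)
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.retained_]


# ---------------------------------------------------------------------------
# models and grids

def _make_model(model_kind: str, seed: int):
    if model_kind == "svm":
        return SVC(random_state=seed)
    if model_kind == "mlp":
        return MLPClassifier(max_iter=800, random_state=seed)
    if model_kind == "rfc":
        return RandomForestClassifier(random_state=seed)
    if model_kind == "logreg":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValueError(f"unknown model kind {model_kind!r}")


DEFAULT_GRIDS: dict[str, dict] = {
    "svm": {"clf__C": [0.01, 0.1, 1, 10, 100],
            "clf__kernel": ["linear", "rbf"],
            "clf__gamma": ["scale", "auto"]},
    "mlp": {"clf__hidden_layer_sizes": [(16,), (64,), (128,)]},
    "rfc": {"clf__n_estimators": [100, 300],
            "clf__max_depth": [None, 5, 10]},
    "logreg": {"clf__C": [0.01, 0.1, 1, 10, 100]},
}

REDUCTION_GRIDS: dict[str, dict] = {
    "anova": {"reduce__k": [10, 25, 50, 100, 200]},
    "pca": {"reduce__n_components": [2, 10, 17, 30]},
    "corr+anova": {"reduce__anova__k": [10, 25, 50, 100, 200]},
    "none": {},
}


def _make_pipeline(model_kind: str, reduction: str, seed: int) -> Pipeline:
    steps = [("var", VarianceThreshold(0.0)), ("scale", StandardScaler())]
    if model_kind == "mlp":
        # MLP additionally maps features to [0, 1] with train extrema
        steps.append(("minmax", MinMaxScaler()))
    if reduction == "anova":
        steps.append(("reduce", SelectKBest(f_classif, k=50)))
    elif reduction == "pca":
        steps.append(("reduce", PCA(n_components=17, svd_solver="full",
                                    random_state=seed)))
    elif reduction == "corr+anova":
        steps.append(("reduce", Pipeline([
            ("corr", CorrelationPruner()),
            ("anova", SelectKBest(f_classif, k=50)),
        ])))
    elif reduction != "none":
        raise ValueError(f"unknown reduction {reduction!r}")
    steps.append(("clf", _make_model(model_kind, seed)))
    return Pipeline(steps)


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X))
    return np.asarray(model.predict_proba(X))[:, 1]


def _grid_cap(grid: dict, n_features: int, n_samples: int,
              cv_folds: int) -> dict:
    # PCA inside CV sees only the fold's training portion
    fold_n = (n_samples * (cv_folds - 1)) // cv_folds
    capped = {}
    for key, values in grid.items():
        if key.endswith("k"):
            values = sorted({min(v, n_features) for v in values})
        if key.endswith("n_components"):
            values = sorted({min(v, n_features, fold_n) for v in values})
        capped[key] = values
    return capped


@dataclass
class CVReport:
    model_kind: str
    reduction: str
    best_params: dict
    fold_auc: list[float]
    fold_accuracy: list[float]
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    train_auc: float
    mean_val_auc: float

    @property
    def train_val_gap(self) -> float:
        return self.train_auc - self.mean_val_auc


def train_model(X: np.ndarray, y: np.ndarray, model_kind: str = "svm",
                reduction: str = "pca", grid: dict | None = None,
                cv_folds: int = 5, seed: int = 0
                ) -> tuple[Pipeline, CVReport]:
    """Grid search maximizing mean CV AUC; reduction fitted inside each fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cv_folds:
        raise ValueError(
            "a CV fold would contain a single class; check stratification "
            f"(class counts {counts.tolist()}, folds {cv_folds})"
        )
    pipe = _make_pipeline(model_kind, reduction, seed)
    if grid is None:
        grid = {**DEFAULT_GRIDS[model_kind], **REDUCTION_GRIDS[reduction]}
    grid = _grid_cap(grid, X.shape[1], X.shape[0], cv_folds)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv, refit=True,
                      n_jobs=None)
    gs.fit(X, y)
    best = gs.best_estimator_

    fold_auc, fold_acc, fold_sens, fold_spec = [], [], [], []
    for tr, va in cv.split(X, y):
        m = clone(best)
        m.fit(X[tr], y[tr])
        s = _scores(m, X[va])
        fold_auc.append(float(roc_auc_score(y[va], s)))
        pred = (s >= _youden_threshold(y[tr], _scores(m, X[tr]))).astype(int)
        cmat = confusion_counts(y[va], pred)
        fold_acc.append(accuracy(cmat))
        fold_sens.append(sensitivity(cmat))
        fold_spec.append(specificity(cmat))
    train_auc = float(roc_auc_score(y, _scores(best, X)))
    report = CVReport(
        model_kind=model_kind, reduction=reduction, best_params=gs.best_params_,
        fold_auc=fold_auc, fold_accuracy=fold_acc,
        fold_sensitivity=fold_sens, fold_specificity=fold_spec,
        train_auc=train_auc, mean_val_auc=float(np.mean(fold_auc)),
    )
    return best, report


# ---------------------------------------------------------------------------
# metrics and evaluation

@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def accuracy(c: ConfusionMatrix) -> float:
    total = c.TP + c.TN + c.FP + c.FN
    return (c.TP + c.TN) / total if total else 0.0


def sensitivity(c: ConfusionMatrix) -> float:
    return c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0


def specificity(c: ConfusionMatrix) -> float:
    return c.TN / (c.TN + c.FP) if (c.TN + c.FP) else 0.0


def _youden_threshold(y: np.ndarray, scores: np.ndarray) -> float:
    """Cut-off maximizing J = TPR - FPR; ties resolved to the lower threshold."""
    fpr, tpr, thresholds = roc_curve(y, scores)
    J = tpr - fpr
    ties = np.flatnonzero(J == J.max())
    return float(thresholds[ties[-1]])  # thresholds descend; last tie is lowest


@dataclass
class EvaluationReport:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    optimal_threshold: float
    confusion: ConfusionMatrix
    roc_fpr: list[float]
    roc_tpr: list[float]
    surrogate_auc_p95: float
    surrogate_aucs: list[float]
    inside_surrogate_band: bool
    seed: int
    fusion: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray, seed: int = 0,
             n_surrogates: int = 100) -> EvaluationReport:
    """Test-set ROC/AUC with a label-permutation surrogate band.

    The surrogate band is the 95th percentile of the AUC over
    ``n_surrogates`` random permutations of the test labels; a test AUC at
    or below that percentile is "inside the band" (indistinguishable from
    chance at the 5% level).
    """
    y_test = np.asarray(y_test, dtype=int)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set must contain both classes")
    scores = _scores(model, X_test)
    fpr, tpr, _ = roc_curve(y_test, scores)
    auc = float(roc_auc_score(y_test, scores))
    thr = _youden_threshold(y_test, scores)
    pred = (scores >= thr).astype(int)
    cmat = confusion_counts(y_test, pred)
    rng = np.random.default_rng(seed)
    surr = [float(roc_auc_score(rng.permutation(y_test), scores))
            for _ in range(n_surrogates)]
    p95 = float(np.percentile(surr, 95))
    return EvaluationReport(
        auc=auc, accuracy=accuracy(cmat), sensitivity=sensitivity(cmat),
        specificity=specificity(cmat), optimal_threshold=thr, confusion=cmat,
        roc_fpr=[float(v) for v in fpr], roc_tpr=[float(v) for v in tpr],
        surrogate_auc_p95=p95, surrogate_aucs=surr,
        inside_surrogate_band=bool(auc <= p95), seed=seed,
    )


def fuse_with_clinician(model_pred: np.ndarray, clinician: np.ndarray,
                        y_true: np.ndarray, op: str = "AND") -> dict:
    """Element-wise AND/OR fusion of binary predictions with metrics."""
    model_pred = np.asarray(model_pred).astype(bool)
    clinician = np.asarray(clinician).astype(bool)
    if op.upper() == "AND":
        fused = model_pred & clinician
    elif op.upper() == "OR":
        fused = model_pred | clinician
    else:
        raise ValueError("op must be AND or OR")
    cmat = confusion_counts(y_true, fused.astype(int))
    return {"op": op.upper(), "prediction": fused.astype(int).tolist(),
            "accuracy": accuracy(cmat), "sensitivity": sensitivity(cmat),
            "specificity": specificity(cmat), "confusion": asdict(cmat)}


# ---------------------------------------------------------------------------
# subgroup tasks

def subgroup_tasks(X: np.ndarray, y: np.ndarray, meta, age_cut: float = 50,
                   seed: int = 0, grid: dict | None = None) -> dict:
    """Sex and age subgroup runs of the fixed SVM+ANOVA baseline.

    Subjects aged exactly ``age_cut`` belong to the older subgroup.
    Subgroups with fewer than 10 subjects of either class are skipped.
    """
    masks = {
        "male": np.asarray(meta["sex"] == "M"),
        "female": np.asarray(meta["sex"] == "F"),
        "age<50": np.asarray(meta["age"] < age_cut),
        "age>=50": np.asarray(meta["age"] >= age_cut),
    }
    out: dict[str, dict] = {}
    for name, mask in masks.items():
        ys = y[mask]
        if min(np.sum(ys == 0), np.sum(ys == 1)) < 10:
            logger.warning("subgroup %s skipped: fewer than 10 per class", name)
            out[name] = {"skipped": True}
            continue
        Xs = X[mask]
        tr, te = split_train_test(Xs, ys, seed=seed)
        model, cv_report = train_model(Xs[tr], ys[tr], model_kind="svm",
                                       reduction="anova", grid=grid, seed=seed)
        report = evaluate(model, Xs[te], ys[te], seed=seed)
        out[name] = {"skipped": False, "cv_mean_auc": cv_report.mean_val_auc,
                     "test_auc": report.auc}
    return out
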
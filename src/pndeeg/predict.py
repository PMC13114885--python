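"""Leakage-safe benchmarking of classifiers predicting phenotype from EEG.

Stratified hold-out splits at several train:test ratios and seeds; inside
each training set, hyperparameters are selected by stratified 3-fold grid
search on mean fold AUC with feature scaling fitted per fold; the selected
pipeline is refit on the full training set and evaluated once on the
untouched test set. Metrics (accuracy, precision, recall, F1) are computed
from the confusion matrix, AUC by trapezoidal integration of the ROC curve,
and global feature importance by permutation-Shapley attribution.

The class definition follows the reference cohort: the non-PND class pools
the young-surgery animals (behaviorally preserved reference) with the aged
non-PND animals; the PND class is the aged PND animals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .attribution import shapley_values

logger = logging.getLogger(__name__)

POSITIVE_LABEL = 1  # PND

DEFAULT_RATIOS = (0.6, 0.7, 0.8)
DEFAULT_SEEDS = (42, 300, 600, 800)


class SplitError(ValueError):
    pass


class MetricError(ValueError):
    pass


def _model_registry() -> dict[str, tuple[object, dict]]:
    """The 12 classifier families with small default hyperparameter grids."""
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    return {
        "LR": (LogisticRegression(max_iter=5000),
               {"clf__C": [0.01, 0.1, 1.0, 10.0]}),
        "GB": (HistGradientBoostingClassifier(random_state=0, min_samples_leaf=2),
               {"clf__max_depth": [2, 3]}),
        "DT": (DecisionTreeClassifier(random_state=0),
               {"clf__max_depth": [2, 3, 4]}),
        "RF": (RandomForestClassifier(random_state=0, n_estimators=200),
               {"clf__max_depth": [2, 3, 4]}),
        "AdaBoost": (AdaBoostClassifier(random_state=0),
                     {"clf__n_estimators": [50, 100]}),
        "ET": (ExtraTreesClassifier(random_state=0, n_estimators=200),
               {"clf__max_depth": [2, 3, 4]}),
        "SVM": (SVC(probability=True, random_state=0),
                {"clf__C": [0.1, 1.0, 10.0], "clf__kernel": ["rbf", "linear"]}),
        "NB": (GaussianNB(), {"clf__var_smoothing": [1e-9, 1e-7]}),
        "KNN": (KNeighborsClassifier(),
                {"clf__n_neighbors": [3, 5, 7]}),
        "MLP": (MLPClassifier(max_iter=3000, random_state=0),
                {"clf__hidden_layer_sizes": [(16,), (32,), (16, 8)],
                 "clf__alpha": [1e-4, 1e-2]}),
        "XGBoost": (XGBClassifier(eval_metric="logloss", random_state=0),
                    {"clf__max_depth": [2, 3], "clf__n_estimators": [100]}),
        "LightGBM": (LGBMClassifier(random_state=0, verbose=-1,
                                    min_child_samples=2),
                     {"clf__max_depth": [2, 3], "clf__n_estimators": [100]}),
    }


MODEL_IDS = ("LR", "GB", "DT", "RF", "AdaBoost", "ET", "SVM", "NB", "KNN",
             "MLP", "XGBoost", "LightGBM")


@dataclass
class EvalConfig:
    """Benchmark settings: ratios, seeds, fold count, families, grids."""

    split_ratios: tuple[float, ...] = DEFAULT_RATIOS
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    n_folds: int = 3
    model_ids: tuple[str, ...] = MODEL_IDS
    grids: dict[str, dict] | None = None
    stratified: bool = True

    def validate(self) -> "EvalConfig":
        if not all(0 < r < 1 for r in self.split_ratios):
            raise SplitError("split ratios must lie in (0, 1)")
        if len(self.seeds) < 1:
            raise SplitError("need at least one seed")
        if self.n_folds < 2:
            raise SplitError("n_folds must be >= 2")
        unknown = set(self.model_ids) - set(MODEL_IDS)
        if unknown:
            raise SplitError(f"unknown model id(s): {sorted(unknown)}")
        return self


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ModelReport:
    """One benchmark cell: model x split ratio x seed."""

    model_id: str
    split_ratio: float
    seed: int
    best_hyperparams: dict
    confusion: ConfusionMatrix
    metrics: dict[str, float]
    roc_points: np.ndarray           # (m, 2) of (FPR, TPR)
    shap_ranking: list[tuple[str, float]] | None = None
    topk_curve: list[float] | None = None


# ---------------------------------------------------------------------------
# splitting / fitting


def make_split(features: pd.DataFrame, labels: np.ndarray, ratio: float,
               seed: int, stratified: bool = True):
    """Stratified hold-out split; ``ratio`` is the training share."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise SplitError("need two classes with >= 2 samples each")
    X_tr, X_te, y_tr, y_te = train_test_split(
        features, labels, train_size=ratio, random_state=seed,
        stratify=labels if stratified else None,
    )
    for side, y in (("train", y_tr), ("test", y_te)):
        if np.unique(y).size < 2:
            raise SplitError(f"class missing from the {side} side")
    return X_tr, X_te, y_tr, y_te


def fit_with_cv(X_train, y_train, model_id: str, config: EvalConfig | None = None,
                cv_seed: int = 0):
    """Grid-search a scaled pipeline by mean stratified-fold AUC and refit.

    The StandardScaler sits inside the pipeline, so its statistics are
    fitted exclusively on each fold's training portion; after selection the
    winning pipeline is retrained on the full training set.
    """
    config = (config or EvalConfig()).validate()
    registry = _model_registry()
    est, default_grid = registry[model_id]
    grid = (config.grids or {}).get(model_id, default_grid)
    pipe = Pipeline([("scaler", StandardScaler()), ("clf", est)])
    cv = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                         random_state=cv_seed)
    y = np.asarray(y_train)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < config.n_folds:
        raise SplitError(
            f"class with {counts.min()} samples cannot fill {config.n_folds} "
            "stratified folds")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gs = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv, refit=True)
        gs.fit(np.asarray(X_train, dtype=float), y)
    return gs.best_estimator_, dict(gs.best_params_)


# ---------------------------------------------------------------------------
# metrics


def confusion_and_metrics(predictions, labels,
                          positive=POSITIVE_LABEL):
    """Confusion matrix and accuracy/precision/recall/F1 for binary labels.

    Division-by-zero cases (no predicted positives, no actual positives,
    P + R = 0) yield NaN with a warning, never a silent 0.
    """
    y_pred = np.asarray(predictions)
    y_true = np.asarray(labels)
    if y_pred.shape != y_true.shape:
        raise MetricError("predictions and labels must have equal length")
    uniq = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(uniq - {positive}) > 1:
        raise MetricError(f"non-binary labels: {sorted(uniq)}")
    pos_p = y_pred == positive
    pos_t = y_true == positive
    cm = ConfusionMatrix(
        tp=int(np.sum(pos_p & pos_t)),
        tn=int(np.sum(~pos_p & ~pos_t)),
        fp=int(np.sum(pos_p & ~pos_t)),
        fn=int(np.sum(~pos_p & pos_t)),
    )
    metrics: dict[str, float] = {
        "accuracy": (cm.tp + cm.tn) / cm.total,
    }
    if cm.tp + cm.fp == 0:
        warnings.warn("no predicted positives; precision undefined")
        metrics["precision"] = float("nan")
    else:
        metrics["precision"] = cm.tp / (cm.tp + cm.fp)
    if cm.tp + cm.fn == 0:
        warnings.warn("no actual positives; recall undefined")
        metrics["recall"] = float("nan")
    else:
        metrics["recall"] = cm.tp / (cm.tp + cm.fn)
    p, r = metrics["precision"], metrics["recall"]
    if np.isnan(p) or np.isnan(r) or p + r == 0:
        warnings.warn("F1 undefined (P + R = 0 or undefined components)")
        metrics["f1"] = float("nan")
    else:
        metrics["f1"] = 2 * p * r / (p + r)
    return cm, metrics


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return 2 * precision * recall / (precision + recall)


def roc_auc(scores, labels, positive=POSITIVE_LABEL):
    """ROC curve by threshold sweep and AUC by the trapezoidal rule.

    Thresholds sweep the unique scores from high to low; tied scores cross
    the threshold simultaneously (diagonal ROC segments), which matches the
    ties-count-half convention of the concordant-pair formulation.
    Returns ``(auc, roc_points)`` with points from (0,0) to (1,1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += int(y[j])
            fp += int(~y[j])
            j += 1
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    pts = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return auc, pts


def _score_fn(pipeline):
    """Continuous positive-class score function of a fitted pipeline."""
    if hasattr(pipeline, "predict_proba"):
        return lambda X: pipeline.predict_proba(np.asarray(X, dtype=float))[:, 1]
    return lambda X: pipeline.decision_function(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# attribution + top-k


def shap_rank(pipeline, X_train, feature_names=None, n_permutations: int = 32,
              seed: int = 0):
    """Global importance ranking by mean |Shapley attribution| on the
    training set, with the training set as background distribution.

    Returns an AttributionResult (per-sample values retained for
    swarm-style export).
    """
    X = np.asarray(X_train, dtype=float)
    if feature_names is None and hasattr(X_train, "columns"):
        feature_names = list(X_train.columns)
    return shapley_values(_score_fn(pipeline), X, X,
                          feature_names=feature_names,
                          n_permutations=n_permutations, seed=seed)


def topk_curve(ranking, X_train, y_train, X_test, y_test, model_id: str,
               config: EvalConfig | None = None, k_max: int = 10,
               plateau_tol: float = 0.01):
    """Test AUC as a function of the number of top-ranked features.

    For each k the model is re-selected by full CV on the top-k features
    only and evaluated on the untouched test set. Returns
    ``(aucs, plateau_k)`` where plateau_k is the smallest k whose AUC is
    within ``plateau_tol`` of the k <= k_max maximum.
    """
    if len(ranking) < k_max:
        raise MetricError(f"ranking of {len(ranking)} features < k_max={k_max}")
    names = [name for name, _ in ranking]
    Xtr = pd.DataFrame(np.asarray(X_train, dtype=float), columns=None)
    if hasattr(X_train, "columns"):
        Xtr.columns = X_train.columns
        Xte = pd.DataFrame(np.asarray(X_test, dtype=float),
                           columns=X_train.columns)
    else:
        raise MetricError("topk_curve needs named feature columns")
    aucs = []
    for k in range(1, k_max + 1):
        cols = names[:k]
        pipe, _ = fit_with_cv(Xtr[cols], y_train, model_id, config)
        scores = _score_fn(pipe)(Xte[cols])
        a, _ = roc_auc(scores, y_test)
        aucs.append(a)
    best = max(aucs)
    plateau_k = next(k for k, a in enumerate(aucs, 1) if a >= best - plateau_tol)
    return aucs, plateau_k


# ---------------------------------------------------------------------------
# benchmark model object


def evaluate_cell(features: pd.DataFrame, labels, model_id: str, ratio: float,
                  seed: int, config: EvalConfig | None = None,
                  with_attribution: bool = False) -> ModelReport:
    """Run one benchmark cell end to end."""
    config = (config or EvalConfig()).validate()
    X_tr, X_te, y_tr, y_te = make_split(features, labels, ratio, seed,
                                        stratified=config.stratified)
    pipe, best = fit_with_cv(X_tr, y_tr, model_id, config, cv_seed=seed)
    y_pred = pipe.predict(np.asarray(X_te, dtype=float))
    cm, metrics = confusion_and_metrics(y_pred, y_te)
    scores = _score_fn(pipe)(X_te)
    metrics["auc"], pts = roc_auc(scores, y_te)
    report = ModelReport(model_id=model_id, split_ratio=ratio, seed=seed,
                         best_hyperparams=best, confusion=cm,
                         metrics=metrics, roc_points=pts)
    if with_attribution:
        att = shap_rank(pipe, X_tr, seed=seed)
        report.shap_ranking = att.ranking()
    return report


@dataclass
class ClassifierBench:
    """Benchmark model over a per-animal feature table and phenotype labels.

    ``labels`` may be strings ('PND'/'non-PND') or a binary vector with 1 as
    the PND class.
    """

    features: pd.DataFrame
    labels: np.ndarray
    config: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        y = np.asarray(self.labels)
        if y.dtype.kind in "UOS":
            y = (y == "PND").astype(int)
        self.labels = y
        self.config.validate()

    @classmethod
    def from_cohort(cls, feature_table: pd.DataFrame, phenotypes: pd.Series,
                    config: EvalConfig | None = None) -> "ClassifierBench":
        common = feature_table.index.intersection(phenotypes.index)
        return cls(features=feature_table.loc[common],
                   labels=phenotypes.loc[common].to_numpy(),
                   config=config or EvalConfig())

    def fit(self, with_attribution: bool = False) -> "BenchResults":
        """Full factorial over model families x split ratios x seeds."""
        reports: list[ModelReport] = []
        for model_id in self.config.model_ids:
            for ratio in self.config.split_ratios:
                for seed in self.config.seeds:
                    try:
                        rep = evaluate_cell(self.features, self.labels,
                                            model_id, ratio, seed,
                                            self.config,
                                            with_attribution=with_attribution)
                    except Exception as exc:
                        raise RuntimeError(
                            f"benchmark cell failed: model={model_id} "
                            f"ratio={ratio} seed={seed}") from exc
                    reports.append(rep)
        logger.info(
            "class definition: non-PND = young-surgery + aged non-PND; "
            "PND = aged PND")
        return BenchResults(reports=reports, config=self.config, model=self)


@dataclass
class BenchResults:
    """Collection of per-cell reports with summary utilities."""

    reports: list[ModelReport]
    config: EvalConfig
    model: ClassifierBench | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            rows.append({"model": r.model_id, "ratio": r.split_ratio,
                         "seed": r.seed, **r.metrics})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Mean ± SD of each metric per model family across cells."""
        df = self.to_frame()
        return df.groupby("model")[
            ["accuracy", "precision", "recall", "f1", "auc"]
        ].agg(["mean", "std"])

    def best_cell(self, metric: str = "auc") -> ModelReport:
        return max(self.reports, key=lambda r: (np.nan_to_num(
            r.metrics.get(metric, float("nan")), nan=-1.0)))
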
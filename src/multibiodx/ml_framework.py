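"""The multi-classifier / multi-feature-selection / multi-CV model grid.

The discriminative analysis crosses four input feature sets (GM, Blood,
EEG, Combined) with feature selection in {None, PCA, RFE, ANOVA}, five
classifiers (SVM, RF, LDA, LR, KNN) and four cross-validation schemes
(10-fold, 5-fold, 3-fold, leave-one-out).  PCA and RFE are excluded for
the 12-dimensional Blood set, which yields the canonical grid of
3*5*4*4 + 1*5*2*4 = 280 model configurations.

Subjects are split 3:1 into training and an independent hold-out test
set, stratified by group.  Feature selection is always fit on training
subjects only (and refit inside every CV fold — no leakage), classifiers
operate on z-scored features (random forest excepted, being
scale-invariant), and hold-out performance is summarised by accuracy,
sensitivity (SZ positive), specificity, the ROC curve and its AUC.
Statistical significance of a model is assessed by a label-permutation
test: the full pipeline is rerun under shuffled labels and
p = #(permuted accuracy >= observed) / n_perm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .feature_assembly import INPUT_SETS, FeatureTable

__all__ = [
    "FrameworkSpec",
    "ModelConfig",
    "Evaluation",
    "UnsupportedRankingError",
    "EmptySelectionError",
    "CLASSIFIERS",
    "FS_METHODS",
    "CV_SCHEMES",
    "enumerate_configs",
    "holdout_split",
    "select_features",
    "fit_classifier",
    "decision_scores",
    "cross_validate",
    "roc_auc",
    "evaluate",
    "permutation_test",
    "rank_features",
    "run_framework",
    "best_models",
]

FS_METHODS: tuple[str, ...] = ("None", "PCA", "RFE", "ANOVA")
CLASSIFIERS: tuple[str, ...] = ("SVM", "RF", "LDA", "LR", "KNN")
CV_SCHEMES: tuple[str, ...] = ("10fold", "5fold", "3fold", "LOO")
#: Selection methods unusable on the low-dimensional blood panel.
BLOOD_EXCLUDED_FS: frozenset[str] = frozenset({"PCA", "RFE"})

DEFAULT_PARAMS: dict[str, object] = {
    "svm_C": 1.0,
    "svm_kernel": "linear",
    "rf_n_estimators": 500,
    "knn_k": 5,
    "lr_C": 1.0,
    "pca_variance": 0.95,
    "rfe_fraction": 0.5,
    "anova_alpha": 0.05,
}


class UnsupportedRankingError(RuntimeError):
    """Feature weights cannot be attributed to input features (e.g. after PCA)."""


class EmptySelectionError(RuntimeError):
    """A selection step retained zero features."""


@dataclass
class FrameworkSpec:
    """One run of the model grid."""

    input_sets: tuple[str, ...] = INPUT_SETS
    fs_methods: tuple[str, ...] = FS_METHODS
    classifiers: tuple[str, ...] = CLASSIFIERS
    cv_schemes: tuple[str, ...] = CV_SCHEMES
    holdout_ratio: float = 3.0
    seed: int = 0
    params: dict[str, object] = field(default_factory=dict)

    def validate(self) -> None:
        for name, values, allowed in (
            ("input_sets", self.input_sets, INPUT_SETS),
            ("fs_methods", self.fs_methods, FS_METHODS),
            ("classifiers", self.classifiers, CLASSIFIERS),
            ("cv_schemes", self.cv_schemes, CV_SCHEMES),
        ):
            if not values:
                raise ValueError(f"{name} must be non-empty")
            bad = [v for v in values if v not in allowed]
            if bad:
                raise ValueError(f"unknown {name}: {bad}")
        if self.holdout_ratio <= 1:
            raise ValueError("holdout ratio (train:test) must exceed 1")


@dataclass
class ModelConfig:
    """One cell of the model grid."""

    input_set: str
    fs_method: str
    classifier: str
    cv_scheme: str
    params: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input_set == "Blood" and self.fs_method in BLOOD_EXCLUDED_FS:
            raise ValueError(f"{self.fs_method} is not applicable to the Blood set")

    def param(self, key: str):
        return self.params.get(key, DEFAULT_PARAMS[key])

    @property
    def label(self) -> str:
        return f"{self.input_set}/{self.fs_method}/{self.classifier}/{self.cv_scheme}"


@dataclass
class Evaluation:
    """Hold-out metrics of one trained model (confusion counts stored)."""

    tp: int
    fn: int
    tn: int
    fp: int
    roc_points: np.ndarray
    auc: float
    cv_mean_accuracy: float = float("nan")
    permutation_p: float = float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def enumerate_configs(spec: FrameworkSpec) -> list[ModelConfig]:
    """Full cross product of the grid minus the Blood x {PCA, RFE} cells.

    Deterministic order: input set, then FS method, classifier, CV scheme.
    """
    spec.validate()
    out: list[ModelConfig] = []
    for inp in spec.input_sets:
        for fs in spec.fs_methods:
            if inp == "Blood" and fs in BLOOD_EXCLUDED_FS:
                continue
            for clf in spec.classifiers:
                for cv in spec.cv_schemes:
                    out.append(ModelConfig(inp, fs, clf, cv, dict(spec.params)))
    return out


def holdout_split(
    ft: FeatureTable, ratio: float = 3.0, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split at ``ratio``:1.

    Per class, floor(n / (ratio + 1)) subjects go to the independent test
    set (the floor remainder stays in training); the assignment is a seeded
    shuffle within class.
    """
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    rng = np.random.default_rng(seed)
    test_ids: list = []
    for group in ("SZ", "HC"):
        ids = ft.data.index[ft.groups == group].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"class {group} has fewer than 2 subjects")
        n_test = int(len(ids) // (ratio + 1))
        perm = rng.permutation(len(ids))
        test_ids.extend(ids[perm[:n_test]])
    test_mask = ft.data.index.isin(test_ids)
    return ft.subset(ft.data.index[~test_mask]), ft.subset(ft.data.index[test_mask])


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

@dataclass
class FittedSelector:
    """A selection transform fit on training data, replayable on test data.

    ``support`` is a boolean mask over the input features for the
    feature-preserving methods (None, ANOVA, RFE) and ``None`` for PCA,
    whose outputs are linear combinations of all inputs.
    """

    method: str
    support: np.ndarray | None = None
    _pipeline: Pipeline | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.method == "PCA":
            return self._pipeline.transform(X)
        return X[:, self.support]

    @property
    def feature_preserving(self) -> bool:
        return self.support is not None


def select_features(
    X: np.ndarray, y: np.ndarray, method: str, params: dict | None = None, seed: int = 0
) -> tuple[np.ndarray, FittedSelector]:
    """Fit a feature-selection transform on training data only.

    None -> identity; ANOVA -> keep features with per-feature F-test
    p < alpha (default 0.05); PCA -> standardized components explaining
    >= 95% of the training variance; RFE -> recursive elimination with a
    linear SVM down to a configured fraction (default 50%) of features.
    """
    params = params or {}

    def p(key):
        return params.get(key, DEFAULT_PARAMS[key])

    X = np.asarray(X, dtype=float)
    if method == "None":
        sel = FittedSelector("None", support=np.ones(X.shape[1], dtype=bool))
    elif method == "ANOVA":
        _, pvals = f_classif(X, y)
        mask = np.nan_to_num(pvals, nan=1.0) < p("anova_alpha")
        if not mask.any():
            raise EmptySelectionError("ANOVA retained zero features")
        sel = FittedSelector("ANOVA", support=mask)
    elif method == "PCA":
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("pca", PCA(n_components=p("pca_variance"), svd_solver="full")),
        ])
        pipe.fit(X)
        sel = FittedSelector("PCA", _pipeline=pipe)
    elif method == "RFE":
        n_keep = max(1, int(math.ceil(p("rfe_fraction") * X.shape[1])))
        scaler = StandardScaler().fit(X)
        rfe = RFE(
            LinearSVC(C=1.0, max_iter=5000),
            n_features_to_select=n_keep,
            step=max(1, X.shape[1] // 10),
        )
        rfe.fit(scaler.transform(X), y)
        sel = FittedSelector("RFE", support=rfe.support_)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return sel.transform(X), sel


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def _make_estimator(kind: str, params: dict | None, seed: int = 0):
    params = params or {}

    def p(key):
        return params.get(key, DEFAULT_PARAMS[key])

    if kind == "SVM":
        clf = SVC(kernel=p("svm_kernel"), C=p("svm_C"), random_state=seed)
    elif kind == "RF":
        # trees are scale-invariant: no standardization step
        return RandomForestClassifier(n_estimators=int(p("rf_n_estimators")),
                                      random_state=seed)
    elif kind == "LDA":
        clf = LinearDiscriminantAnalysis()
    elif kind == "LR":
        clf = LogisticRegression(C=p("lr_C"), max_iter=2000, random_state=seed)
    elif kind == "KNN":
        clf = KNeighborsClassifier(n_neighbors=int(p("knn_k")))
    else:
        raise ValueError(f"unknown classifier {kind!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def fit_classifier(X: np.ndarray, y: np.ndarray, kind: str,
                   params: dict | None = None, seed: int = 0):
    """Train one classifier (z-scoring fit on the training data where needed)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = _make_estimator(kind, params, seed)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous score for ROC analysis: margin, probability or vote fraction."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def _folds(cv_scheme: str, y: np.ndarray, seed: int):
    if cv_scheme == "LOO":
        return LeaveOneOut().split(np.zeros(len(y)), y)
    k = {"10fold": 10, "5fold": 5, "3fold": 3}[cv_scheme]
    counts = np.bincount(y)
    if k > counts[counts > 0].min():
        raise ValueError(f"{cv_scheme}: fold count exceeds the smallest class")
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(
        np.zeros(len(y)), y
    )


def cross_validate(
    ft_train: FeatureTable, config: ModelConfig, seed: int = 0
) -> float:
    """Mean fold accuracy under the config's CV scheme.

    Feature selection is refit inside every fold so no fold's validation
    subjects influence the transform.
    """
    X = ft_train.data.to_numpy(dtype=float)
    y = ft_train.labels()
    accs = []
    for tr, va in _folds(config.cv_scheme, y, seed):
        try:
            Xtr, sel = select_features(X[tr], y[tr], config.fs_method,
                                       config.params, seed)
        except EmptySelectionError:
            accs.append(np.mean(y[va] == np.bincount(y[tr]).argmax()))
            continue
        model = fit_classifier(Xtr, y[tr], config.classifier, config.params, seed)
        accs.append(float(np.mean(model.predict(sel.transform(X[va])) == y[va])))
    return float(np.mean(accs))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC curve (threshold sweep over unique scores) and trapezoidal AUC.

    The AUC equals the Mann-Whitney concordance statistic U / (n1 * n0).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(np.trapezoid(tpr, fpr))


def evaluate(model, selector: FittedSelector, ft_test: FeatureTable) -> Evaluation:
    """Hold-out evaluation with SZ as the positive class."""
    if ft_test.n_subjects == 0:
        raise ValueError("test set is empty")
    y = ft_test.labels()
    if len(np.unique(y)) < 2:
        raise ValueError("test set must contain both classes")
    Xt = selector.transform(ft_test.data.to_numpy(dtype=float))
    pred = model.predict(Xt)
    scores = decision_scores(model, Xt)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    points, auc = roc_auc(scores, y)
    return Evaluation(tp=tp, fn=fn, tn=tn, fp=fp, roc_points=points, auc=auc)


def _fit_eval(
    ft: FeatureTable, config: ModelConfig, seed: int, with_cv: bool = True
) -> tuple[Evaluation, object, FittedSelector, FeatureTable]:
    """Full single-config pipeline: split, select, fit, hold-out evaluation."""
    train, test = holdout_split(ft, seed=seed)
    Xtr, sel = select_features(
        train.data.to_numpy(dtype=float), train.labels(), config.fs_method,
        config.params, seed,
    )
    model = fit_classifier(Xtr, train.labels(), config.classifier, config.params, seed)
    ev = evaluate(model, sel, test)
    if with_cv:
        ev.cv_mean_accuracy = cross_validate(train, config, seed)
    return ev, model, sel, train


def permutation_test(
    ft: FeatureTable,
    config: ModelConfig,
    n_perm: int = 1000,
    seed: int = 0,
    observed_accuracy: float | None = None,
    plus_one: bool = False,
) -> float:
    """Label-permutation significance of one model configuration.

    Labels are shuffled before the hold-out split, and the entire pipeline
    (split, selection, fit, test) is rerun per permutation.  The p value is
    the literal proportion #(permuted accuracy >= observed) / n_perm (which
    can be zero); ``plus_one`` switches to the (r+1)/(n+1) estimator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if observed_accuracy is None:
        observed_accuracy = _fit_eval(ft, config, seed, with_cv=False)[0].accuracy
    rng = np.random.default_rng(seed)
    exceed = 0
    groups = ft.groups.to_numpy()
    for _ in range(n_perm):
        perm_ft = FeatureTable(
            ft.data, dict(ft.modality),
            pd.Series(rng.permutation(groups), index=ft.data.index),
        )
        split_seed = int(rng.integers(2**31))
        try:
            acc = _fit_eval(perm_ft, config, split_seed, with_cv=False)[0].accuracy
        except (EmptySelectionError, ValueError):
            acc = 0.0
        if acc >= observed_accuracy - 1e-12:
            exceed += 1
    if plus_one:
        return (exceed + 1) / (n_perm + 1)
    return exceed / n_perm


def rank_features(
    model,
    selector: FittedSelector,
    ft: FeatureTable,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Features ranked by weight magnitude, truncated to the top fraction.

    Linear models contribute |coefficient| on the standardized features and
    random forests their impurity importances; unselected features get weight
    zero.  Ties are broken by feature name so the order is deterministic.
    The truncation length is ceil(top_fraction * total feature count) — e.g.
    34 features for a 663-column table at 5%.
    """
    if not selector.feature_preserving:
        raise UnsupportedRankingError(
            "weights after PCA are not attributable to input features"
        )
    est = model.named_steps["clf"] if isinstance(model, Pipeline) else model
    if hasattr(est, "coef_"):
        w = np.abs(np.ravel(est.coef_))
    elif hasattr(est, "feature_importances_"):
        w = np.asarray(est.feature_importances_, dtype=float)
    else:
        raise UnsupportedRankingError(
            f"{type(est).__name__} exposes no per-feature weights"
        )
    names = np.asarray(ft.data.columns)
    full = np.zeros(len(names))
    full[selector.support] = w
    order = sorted(range(len(names)), key=lambda i: (-full[i], names[i]))
    n_top = int(math.ceil(top_fraction * len(names)))
    rows = [
        (rank + 1, names[i], ft.modality[names[i]], full[i])
        for rank, i in enumerate(order[:n_top])
    ]
    return pd.DataFrame(rows, columns=["rank", "feature", "modality", "weight"])


def run_framework(
    tables: dict[str, FeatureTable],
    spec: FrameworkSpec,
    with_cv: bool = True,
) -> pd.DataFrame:
    """Run every grid configuration and collect one evaluation row per model.

    ``tables`` maps each requested input set to its assembled feature table.
    Individual config failures are recorded in the ``error`` column and the
    run continues.
    """
    rows = []
    for config in enumerate_configs(spec):
        row: dict[str, object] = {
            "input_set": config.input_set,
            "fs": config.fs_method,
            "classifier": config.classifier,
            "cv": config.cv_scheme,
        }
        try:
            ft = tables[config.input_set]
        except KeyError:
            row["error"] = f"no feature table for {config.input_set}"
            rows.append(row)
            continue
        try:
            ev, _, _, _ = _fit_eval(ft, config, spec.seed, with_cv=with_cv)
            row.update(
                cv_accuracy=ev.cv_mean_accuracy,
                test_accuracy=ev.accuracy,
                sensitivity=ev.sensitivity,
                specificity=ev.specificity,
                auc=ev.auc,
                error="",
            )
        except (EmptySelectionError, ValueError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def best_models(results: pd.DataFrame) -> pd.DataFrame:
    """Best configuration per input set, selected by hold-out AUC."""
    ok = results[results.get("error", "") == ""].copy()
    if ok.empty:
        return ok
    idx = ok.groupby("input_set")["auc"].idxmax()
    return ok.loc[idx].reset_index(drop=True)
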
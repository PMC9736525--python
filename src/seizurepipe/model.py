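"""Classifier training, comparison and evaluation.

The reference model is a gradient-boosted tree ensemble; a comparator suite
(bagged trees, subspace KNN, polynomial SVMs, a single decision tree,
Gaussian naive Bayes, linear discriminant analysis) mirrors the usual
classification-learner zoo. All models are scored by stratified 5-fold
cross-validation, refit on the full training pool, and evaluated on a
held-out set with confusion matrix, per-class true-positive rates and
one-vs-rest AUCs.

Feature importance uses a neighborhood-component-analysis (NCA) variant
that learns one nonnegative weight per feature: the stochastic-neighbor
leave-one-out objective with a weighted L1 feature distance, maximized by
gradient ascent with an L2 penalty on the weights. The top-k (default 8)
features define the reduced model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier, GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import accuracy_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

LABEL_ORDER = ("N", "P", "I")

FAMILIES = (
    "boosted_trees",
    "bagged_trees",
    "knn_subspace",
    "svm_linear",
    "svm_quadratic",
    "svm_cubic",
    "decision_tree",
    "naive_bayes",
    "linear_discriminant",
)


class ModelError(ValueError):
    pass


def _base_estimator(family: str, seed: int, hyperparams: dict | None = None):
    hp = dict(hyperparams or {})
    if family == "boosted_trees":
        return GradientBoostingClassifier(
            learning_rate=hp.get("learning_rate", 0.1),
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", 3),
            random_state=seed,
        )
    if family == "bagged_trees":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=seed
        )
    if family == "knn_subspace":
        return BaggingClassifier(
            KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5)),
            n_estimators=hp.get("n_estimators", 30),
            max_features=hp.get("max_features", 0.5),
            bootstrap=False,
            random_state=seed,
        )
    if family.startswith("svm_"):
        degree = {"svm_linear": 1, "svm_quadratic": 2, "svm_cubic": 3}[family]
        kernel = "linear" if degree == 1 else "poly"
        return SVC(
            kernel=kernel, degree=degree, C=hp.get("C", 1.0),
            probability=True, random_state=seed,
        )
    if family == "decision_tree":
        return DecisionTreeClassifier(max_depth=hp.get("max_depth", None), random_state=seed)
    if family == "naive_bayes":
        return GaussianNB()
    if family == "linear_discriminant":
        return LinearDiscriminantAnalysis()
    raise ModelError(f"unknown model family {family!r}")


@dataclass
class TrainConfig:
    family: str = "boosted_trees"
    k_folds: int = 5
    budget: int = 1  # hyperparameter-search evaluations
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ModelError("k_folds must be >= 2")
        if self.budget < 1:
            raise ModelError("budget must be >= 1")
        if self.family not in FAMILIES:
            raise ModelError(f"unknown model family {self.family!r}")


@dataclass
class ModelReport:
    """Evaluation summary: confusion rows are true N/P/I, columns predicted."""

    accuracy: float
    confusion: np.ndarray
    tpr: dict[str, float]
    auc: dict[str, float]
    cv_fold_accuracy: list[float] | None = None

    @property
    def preictal_sensitivity(self) -> float:
        return self.tpr["P"]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "labels": list(LABEL_ORDER),
            "tpr": self.tpr,
            "auc": {k: (v if np.isfinite(v) else None) for k, v in self.auc.items()},
            "cv_fold_accuracy": self.cv_fold_accuracy,
        }


class SeizureStateClassifier(BaseEstimator, ClassifierMixin):
    """Seizure-state (N/P/I) classifier over the 93-feature window vectors.

    Wraps one of the comparator families behind a single estimator surface;
    ``fit`` runs stratified k-fold cross-validation (scores in
    ``cv_scores_``) and refits the chosen family on all rows.
    """

    def __init__(self, family: str = "boosted_trees", k_folds: int = 5,
                 seed: int = 0, hyperparams: dict | None = None):
        self.family = family
        self.k_folds = k_folds
        self.seed = seed
        self.hyperparams = hyperparams

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ModelError("training needs >= 2 classes")
        base = _base_estimator(self.family, self.seed, self.hyperparams)
        skf = StratifiedKFold(n_splits=self.k_folds, shuffle=True, random_state=self.seed)
        scores = []
        for tr, te in skf.split(X, y):
            m = clone(base).fit(X[tr], y[tr])
            scores.append(float(accuracy_score(y[te], m.predict(X[te]))))
        self.cv_scores_ = scores
        self.cv_accuracy_ = float(np.mean(scores))
        self.estimator_ = clone(base).fit(X, y)
        self.classes_ = self.estimator_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(X)


def crossval_train(
    X: np.ndarray, y: np.ndarray, config: TrainConfig
) -> tuple[SeizureStateClassifier, ModelReport]:
    """Cross-validated training; the returned report carries per-fold
    accuracies and the training-pool confusion summary."""
    clf = SeizureStateClassifier(
        family=config.family, k_folds=config.k_folds, seed=config.seed,
        hyperparams=config.hyperparams,
    ).fit(X, y)
    report = evaluate(clf, X, y)
    report.cv_fold_accuracy = clf.cv_scores_
    return clf, report


def optimize_hyperparams(
    X: np.ndarray, y: np.ndarray, family: str = "boosted_trees",
    budget: int = 20, seed: int = 0, k_folds: int = 5,
) -> TrainConfig:
    """Randomized hyperparameter search at a fixed evaluation budget.

    The default configuration is always among the candidates and all
    candidates are scored on the same folds, so the returned configuration's
    CV accuracy is never below the default's.
    """
    if budget < 1:
        raise ModelError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    candidates: list[dict] = [{}]  # default config first
    if family == "boosted_trees":
        for _ in range(budget - 1):
            candidates.append(
                {
                    "learning_rate": float(10 ** rng.uniform(-2, -0.3)),
                    "n_estimators": int(rng.integers(50, 301)),
                    "max_depth": int(rng.integers(1, 7)),
                }
            )
    else:
        candidates.extend({} for _ in range(budget - 1))

    best_hp, best_score = None, -np.inf
    for hp in candidates[:budget]:
        clf = SeizureStateClassifier(family=family, k_folds=k_folds, seed=seed, hyperparams=hp)
        clf.fit(X, y)
        logger.info("candidate %s -> CV accuracy %.4f", hp, clf.cv_accuracy_)
        if clf.cv_accuracy_ > best_score:
            best_hp, best_score = hp, clf.cv_accuracy_
    return TrainConfig(family=family, k_folds=k_folds, budget=budget, seed=seed,
                       hyperparams=best_hp or {})


# ---------------------------------------------------------------------------
# NCA feature weighting


class NcaFeatureSelector(BaseEstimator, SelectorMixin):
    """Per-feature NCA weights with top-k selection.

    Maximizes the expected leave-one-out stochastic-neighbor accuracy
    F(w) = sum_i p_i - lam * sum_r w_r^2 with
    p_ij proportional to exp(-d_ij), d_ij = sum_r w_r^2 |x_ir - x_jr|,
    by projected gradient ascent on w (weights kept nonnegative). Rows are
    subsampled to ``max_rows`` for the O(n^2) objective.
    """

    def __init__(self, k: int = 8, lam: float = 1.0, max_iter: int = 60,
                 learning_rate: float = 0.05, max_rows: int = 400, seed: int = 0):
        self.k = k
        self.lam = lam
        self.max_iter = max_iter
        self.learning_rate = learning_rate
        self.max_rows = max_rows
        self.seed = seed

    @staticmethod
    def _objective_grad(A, same, w, lam):
        # A: (n, n, p) pairwise |x_ir - x_jr|, zero diagonal
        w2 = w**2
        d = A @ w2
        np.fill_diagonal(d, np.inf)
        logits = -d
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        pij = e / e.sum(axis=1, keepdims=True)
        p_i = (pij * same).sum(axis=1)
        obj = p_i.sum() - lam * np.sum(w2)
        # dF/dw_r = 2 w_r * sum_ij pij (p_i - same_ij) |x_ir - x_jr| - 2 lam w_r
        coef = pij * (p_i[:, None] - same)
        grad = 2 * w * np.einsum("ij,ijr->r", coef, A) - 2 * lam * w
        return obj, grad

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        rng = np.random.default_rng(self.seed)
        n = len(X)
        if n > self.max_rows:
            idx = rng.choice(n, size=self.max_rows, replace=False)
            X, y = X[idx], y[idx]
        same = (y[:, None] == y[None, :]).astype(float)
        np.fill_diagonal(same, 0.0)
        p = X.shape[1]
        A = np.abs(X[:, None, :] - X[None, :, :])
        w = np.ones(p)
        lr = self.learning_rate
        obj, grad = self._objective_grad(A, same, w, self.lam)
        converged = False
        for _ in range(self.max_iter):
            w_new = np.maximum(w + lr * grad / len(X), 0.0)
            obj_new, grad_new = self._objective_grad(A, same, w_new, self.lam)
            if obj_new < obj:
                lr *= 0.5  # backtrack: keep w, shrink the step
                if lr < 1e-8:
                    break
                continue
            if abs(obj_new - obj) < 1e-8 * max(abs(obj), 1.0):
                w, obj = w_new, obj_new
                converged = True
                break
            w, obj, grad = w_new, obj_new, grad_new
            lr *= 1.05
        if not converged:
            logger.warning("NCA did not converge in %d iterations; using last iterate",
                           self.max_iter)
        self.weights_ = w
        self.ranking_ = np.argsort(-w, kind="stable")
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "weights_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[: self.k]] = True
        return mask


@dataclass
class FeatureWeighting:
    weights: np.ndarray
    names: list[str]
    selected: list[str]

    def ranked_names(self) -> list[str]:
        order = np.argsort(-self.weights, kind="stable")
        return [self.names[i] for i in order]


def nca_feature_weights(
    X: np.ndarray, y: np.ndarray, feature_names: list[str] | None = None,
    k: int = 8, seed: int = 0, **kwargs,
) -> FeatureWeighting:
    """Fit the per-feature NCA and return named weights plus the top-k set."""
    sel = NcaFeatureSelector(k=k, seed=seed, **kwargs).fit(X, y)
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    selected = [names[i] for i in sel.ranking_[:k]]
    return FeatureWeighting(weights=sel.weights_, names=names, selected=selected)


# ---------------------------------------------------------------------------
# PCA reduction and evaluation


def pca_reduce(X: np.ndarray, variance_target: float = 0.95) -> tuple[PCA, int]:
    """PCA of the training matrix; k = fewest components whose cumulative
    explained-variance ratio reaches the target."""
    if not (0 < variance_target <= 1):
        raise ModelError("variance_target must be in (0, 1]")
    pca = PCA().fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(cum))
    projection = PCA(n_components=k).fit(X)
    return projection, k


def evaluate(model, X: np.ndarray, y: np.ndarray) -> ModelReport:
    """Confusion matrix, per-class TPR, one-vs-rest AUC and accuracy on a
    labeled set. AUC for a class absent from ``y`` is NaN."""
    y = np.asarray(y, str)
    pred = model.predict(X)
    labels = [l for l in LABEL_ORDER]
    cm = confusion_matrix(y, pred, labels=labels)
    support = cm.sum(axis=1)
    tpr = {
        lab: (float(cm[i, i] / support[i]) if support[i] > 0 else float("nan"))
        for i, lab in enumerate(labels)
    }
    auc: dict[str, float] = {}
    try:
        proba = model.predict_proba(X)
        model_classes = list(model.classes_)
        for lab in labels:
            if lab not in model_classes or (y == lab).sum() in (0, len(y)):
                auc[lab] = float("nan")
                continue
            scores = proba[:, model_classes.index(lab)]
            auc[lab] = float(roc_auc_score((y == lab).astype(int), scores))
    except AttributeError:
        auc = {lab: float("nan") for lab in labels}
    return ModelReport(
        accuracy=float(accuracy_score(y, pred)), confusion=cm, tpr=tpr, auc=auc
    )
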
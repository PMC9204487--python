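"""Classifiers: shrinkage LDA plus the four frozen comparison baselines.

The LDA here is implemented directly from the Gaussian equal-covariance
discriminant

    δ_k(x) = xᵀ Σ⁻¹ μ_k − ½ μ_kᵀ Σ⁻¹ μ_k + log π_k

with class means μ_k, pooled within-class covariance Σ and priors π_k
estimated from the training frames, and Σ shrunk toward its own diagonal,
(1−λ)Σ + λ·diag(Σ), to keep the 68×68 pooled estimate invertible on the
few hundred frames a trial yields.

The comparison classifiers (decision tree, 3-NN, random forest, linear SVM)
are scikit-learn estimators pinned to fixed hyperparameters; they are
baselines, not the core method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .core import FEATURE_MODALITY, FEATURE_NAMES, ValidationError

__all__ = [
    "ShrinkageLDA",
    "fit_lda",
    "predict_lda",
    "ComparatorSpec",
    "COMPARATOR_KINDS",
    "make_comparator",
    "fit_comparator",
    "ImportanceRanking",
    "gini_importance",
    "save_lda",
    "load_lda",
]

COMPARATOR_KINDS = ("DT", "KNN", "RF", "SVM")


class ShrinkageLDA(ClassifierMixin, BaseEstimator):
    """Linear discriminant analysis with diagonal shrinkage.

    Parameters
    ----------
    shrinkage : float in [0, 1]
        λ in (1−λ)Σ + λ·diag(Σ). 0 is the plain pooled covariance; 1 is a
        fully diagonal (naive-Bayes-like) covariance.
    priors : {"empirical", "uniform"}
        Class priors π_k: training frequencies or 1/K.

    Attributes (after ``fit``)
    --------------------------
    classes_ : (K,) class labels in sorted order
    means_ : (K, p) class means μ_k
    covariance_ : (p, p) shrunk pooled covariance Σ
    priors_ : (K,) priors π_k
    coef_ : (K, p) rows Σ⁻¹μ_k, so δ(x) = X·coef_.T + intercept_
    intercept_ : (K,)
    """

    def __init__(self, shrinkage: float = 1e-3, priors: str = "empirical"):
        self.shrinkage = shrinkage
        self.priors = priors

    def fit(self, X, y) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValidationError("X contains non-finite values")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValidationError("shrinkage must be in [0, 1]")
        if self.priors not in ("empirical", "uniform"):
            raise ValidationError("priors must be 'empirical' or 'uniform'")

        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.shape[0] < 2:
            raise ValidationError("need at least 2 classes")
        n, p = X.shape
        counts = np.bincount(y_idx, minlength=classes.shape[0])
        for k, c in enumerate(counts):
            if c < 2:
                raise ValidationError(
                    f"class {classes[k]!r} has {c} frame(s); need at least 2"
                )

        means = np.stack([X[y_idx == k].mean(axis=0) for k in range(len(classes))])
        # pooled within-class scatter
        centered = X - means[y_idx]
        cov = centered.T @ centered / (n - len(classes))
        lam = self.shrinkage
        cov = (1.0 - lam) * cov + lam * np.diag(np.diag(cov))

        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "pooled covariance is singular after shrinkage; "
                "increase the shrinkage parameter"
            ) from exc

        if self.priors == "uniform":
            priors = np.full(len(classes), 1.0 / len(classes))
        else:
            priors = counts / n

        # Σ⁻¹ μ_k via the Cholesky factor, one solve per class
        sol = np.linalg.solve(chol, means.T)          # chol @ sol = means.T
        inv_mu = np.linalg.solve(chol.T, sol).T       # (K, p) rows Σ⁻¹μ_k

        self.classes_ = classes
        self.class_count_ = counts
        self.means_ = means
        self.covariance_ = cov
        self.priors_ = priors
        self.coef_ = inv_mu
        self.intercept_ = -0.5 * np.einsum("kp,kp->k", means, inv_mu) + np.log(priors)
        self.n_features_in_ = p
        return self

    def decision_function(self, X) -> np.ndarray:
        """Discriminant scores δ_k(x), shape (n, K)."""
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"x has {X.shape[1]} features; model was fitted with {self.n_features_in_}"
            )
        return X @ self.coef_.T + self.intercept_

    def predict(self, X):
        """argmax_k δ_k(x); ties resolve to the lowest class index."""
        delta = self.decision_function(X)
        return self.classes_[np.argmax(delta, axis=1)]


def fit_lda(X, y, priors_mode: str = "empirical", shrinkage: float = 1e-3) -> ShrinkageLDA:
    """Functional wrapper over :class:`ShrinkageLDA`."""
    return ShrinkageLDA(shrinkage=shrinkage, priors=priors_mode).fit(X, y)


def predict_lda(model: ShrinkageLDA, x) -> tuple[np.ndarray, np.ndarray]:
    """Predicted label(s) and the per-class scores δ_1..δ_K."""
    scores = model.decision_function(x)
    return model.classes_[np.argmax(scores, axis=1)], scores


# ---------------------------------------------------------------------------
# Comparison classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparatorSpec:
    """A baseline classifier kind with its frozen hyperparameters."""

    kind: str
    random_state: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in COMPARATOR_KINDS + ("LDA",):
            raise ValidationError(f"unknown classifier kind {self.kind!r}")


def make_comparator(kind: str, random_state: int | None = None):
    """A fresh estimator at the frozen settings: DT entropy split; KNN k=3
    Euclidean; RF 40 trees / min-leaf 1; SVM linear kernel C=100."""
    if kind == "LDA":
        return ShrinkageLDA()
    if kind == "DT":
        return DecisionTreeClassifier(criterion="entropy", random_state=random_state)
    if kind == "KNN":
        return KNeighborsClassifier(n_neighbors=3, metric="euclidean")
    if kind == "RF":
        return RandomForestClassifier(
            n_estimators=40, min_samples_leaf=1, random_state=random_state
        )
    if kind == "SVM":
        return SVC(kernel="linear", C=100.0)
    raise ValidationError(f"unknown classifier kind {kind!r}")


def fit_comparator(spec: ComparatorSpec, X, y):
    """Fit a baseline classifier; all expose ``predict(x)``."""
    return make_comparator(spec.kind, spec.random_state).fit(np.asarray(X, float), y)


# ---------------------------------------------------------------------------
# Feature importance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceRanking:
    """Normalized Gini importances, sorted descending, truncated to top_k."""

    indices: tuple[int, ...]
    importances: tuple[float, ...]
    names: tuple[str, ...]
    modalities: tuple[str, ...]
    all_importances: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def gini_importance(X, y, seed: int | None = 0, top_k: int = 10,
                    feature_names=FEATURE_NAMES, modalities=FEATURE_MODALITY
                    ) -> ImportanceRanking:
    """Rank features by random-forest mean impurity (Gini) decrease.

    Uses the frozen forest settings (40 trees, min leaf 1). Importances are
    normalized to sum to 1 before truncation to ``top_k``.
    """
    X = np.asarray(X, dtype=float)
    rf = make_comparator("RF", random_state=seed).fit(X, y)
    imp = rf.feature_importances_.astype(float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp, kind="stable")[:top_k]
    if feature_names is not None and len(feature_names) != X.shape[1]:
        feature_names = tuple(f"f{i + 1}" for i in range(X.shape[1]))
        modalities = ("?",) * X.shape[1]
    return ImportanceRanking(
        indices=tuple(int(i) for i in order),
        importances=tuple(float(imp[i]) for i in order),
        names=tuple(feature_names[i] for i in order),
        modalities=tuple(modalities[i] for i in order),
        all_importances=imp,
    )


# ---------------------------------------------------------------------------
# Model artifact
# ---------------------------------------------------------------------------

def save_lda(model: ShrinkageLDA, path: str | Path) -> Path:
    """Serialize a fitted LDA to diffable JSON."""
    check_is_fitted(model, "coef_")
    payload = {
        "classes": [str(c) for c in model.classes_],
        "means": model.means_.tolist(),
        "covariance": model.covariance_.tolist(),
        "priors": model.priors_.tolist(),
        "shrinkage": model.shrinkage,
        "priors_mode": model.priors,
        "n_features": int(model.n_features_in_),
        "feature_names": list(FEATURE_NAMES) if model.n_features_in_ == len(FEATURE_NAMES) else None,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1) + "\n")
    return path


def load_lda(path: str | Path) -> ShrinkageLDA:
    payload = json.loads(Path(path).read_text())
    model = ShrinkageLDA(shrinkage=payload["shrinkage"], priors=payload["priors_mode"])
    X_stub = np.asarray(payload["means"], dtype=float)
    model.classes_ = np.asarray(payload["classes"])
    model.means_ = X_stub
    model.covariance_ = np.asarray(payload["covariance"], dtype=float)
    model.priors_ = np.asarray(payload["priors"], dtype=float)
    model.n_features_in_ = payload["n_features"]
    chol = np.linalg.cholesky(model.covariance_)
    sol = np.linalg.solve(chol, model.means_.T)
    model.coef_ = np.linalg.solve(chol.T, sol).T
    model.intercept_ = (
        -0.5 * np.einsum("kp,kp->k", model.means_, model.coef_) + np.log(model.priors_)
    )
    model.class_count_ = np.zeros(len(model.classes_), dtype=int)
    return model
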
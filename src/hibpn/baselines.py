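"""Uniform adapters for the ten classical comparison models.

Every baseline exposes the same handle — ``predict_labels`` /
``predict_scores`` — so the comparison table is one call.  Scores are
class-1 probabilities where the estimator supports them and a monotone
decision value otherwise (SVM without probability calibration), which
is all ROC/AUC needs.  Hyperparameters are library defaults unless
overridden in the spec and are recorded in the run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["BASELINE_NAMES", "BaselineSpec", "FittedBaseline", "fit_baseline", "default_specs"]

BASELINE_NAMES = (
    "logistic_regression",
    "random_forest",
    "gradient_boosting",
    "adaboost",
    "svm",
    "naive_bayes",
    "knn",
    "lda",
    "qda",
    "decision_tree",
)


@dataclass
class BaselineSpec:
    """Name + hyperparameters + seed for one comparison model."""

    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(f"unknown baseline {self.name!r}; choose from {BASELINE_NAMES}")


def _build_estimator(spec: BaselineSpec):
    hp = dict(spec.hyperparameters)
    seeded = dict(random_state=spec.seed)
    builders = {
        "logistic_regression": lambda: LogisticRegression(max_iter=1000, **hp),
        "random_forest": lambda: RandomForestClassifier(**seeded, **hp),
        "gradient_boosting": lambda: GradientBoostingClassifier(**seeded, **hp),
        "adaboost": lambda: AdaBoostClassifier(**seeded, **hp),
        "svm": lambda: SVC(**seeded, **hp),
        "naive_bayes": lambda: GaussianNB(**hp),
        "knn": lambda: KNeighborsClassifier(**hp),
        "lda": lambda: LinearDiscriminantAnalysis(**hp),
        "qda": lambda: QuadraticDiscriminantAnalysis(**hp),
        "decision_tree": lambda: DecisionTreeClassifier(**seeded, **hp),
    }
    return builders[spec.name]()


class _RegularizedQDA:
    """Quadratic discriminant with ridge-regularized class covariances.

    Fallback for cohorts where a class has fewer training samples than
    features, which the standard estimator rejects as rank-deficient:
    each class covariance gets ``eps * mean-variance`` added to its
    diagonal, making it positive definite by construction.
    """

    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_RegularizedQDA":
        self.classes_ = np.unique(y)
        self._params = []
        for c in self.classes_:
            xc = x[y == c]
            mu = xc.mean(axis=0)
            cov = np.atleast_2d(np.cov(xc, rowvar=False)) if len(xc) > 1 else np.zeros(
                (x.shape[1], x.shape[1])
            )
            ridge = max(self.eps * float(np.trace(cov)) / x.shape[1], self.eps)
            cov = cov + ridge * np.eye(x.shape[1])
            sign, logdet = np.linalg.slogdet(cov)
            prec = np.linalg.inv(cov)
            prior = float(len(xc)) / len(y)
            self._params.append((mu, prec, logdet, np.log(prior)))
        return self

    def _log_posterior(self, x: np.ndarray) -> np.ndarray:
        scores = []
        for mu, prec, logdet, logprior in self._params:
            d = x - mu
            maha = np.einsum("ij,jk,ik->i", d, prec, d)
            scores.append(-0.5 * (maha + logdet) + logprior)
        return np.column_stack(scores)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        lp = self._log_posterior(np.asarray(x, dtype=float))
        lp = lp - lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._log_posterior(np.asarray(x, dtype=float)), axis=1)]


@dataclass
class FittedBaseline:
    """A fitted comparison model with the uniform predict surface."""

    spec: BaselineSpec
    estimator: object

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(x)).astype(int)

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return np.asarray(est.predict_proba(x))[:, 1]
        return np.asarray(est.decision_function(x))


def fit_baseline(
    spec: BaselineSpec, train_features: np.ndarray, train_labels: Sequence[int]
) -> FittedBaseline:
    """Fit one baseline; seed-deterministic for stochastic estimators.

    QDA falls back to a small covariance regularization (1e-6) when a
    class covariance is singular, which happens routinely with one-hot
    columns.
    """
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    x = np.asarray(train_features, dtype=float)
    est = _build_estimator(spec)
    if spec.name == "qda":
        import warnings

        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                est.fit(x, y)
            singular = any("collinear" in str(w.message).lower() for w in caught)
        except np.linalg.LinAlgError:
            singular = True
        if singular:
            warnings.warn(
                "QDA class covariance singular; using ridge-regularized covariances",
                stacklevel=2,
            )
            est = _RegularizedQDA(eps=1e-6)
            est.fit(x, y)
    else:
        est.fit(x, y)
    return FittedBaseline(spec=spec, estimator=est)


def default_specs(seed: int = 0) -> list[BaselineSpec]:
    """All ten comparison models with library-default hyperparameters."""
    return [BaselineSpec(name=name, seed=seed) for name in BASELINE_NAMES]


def evaluate_all_baselines(
    specs: Sequence[BaselineSpec],
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    chain: str,
    positive_class: str = "",
) -> tuple[list, dict[str, str]]:
    """Fit and score every baseline on one chain's split.

    Returns ``(rows, errors)``: one metrics row per successfully
    fitted model (stable input order, computed by the same evaluation
    code path as the network's metrics) and a name -> message map for
    models whose fit failed.
    """
    from .evaluation import MetricsRow, accuracy, f1_score, roc_and_auc

    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate baseline names")
    rows, errors = [], {}
    for spec in specs:
        try:
            fitted = fit_baseline(spec, x_train, y_train)
            yhat = fitted.predict_labels(x_test)
            scores = fitted.predict_scores(x_test)
            roc, auc_val = roc_and_auc(y_test, scores)
            rows.append(
                MetricsRow(
                    model=spec.name, chain=chain,
                    acc=accuracy(y_test, yhat), f1=f1_score(y_test, yhat),
                    auc=auc_val, roc_points=roc, n_test=int(len(y_test)),
                    positive_class=positive_class,
                )
            )
        except Exception as exc:  # annotate, keep going
            errors[spec.name] = str(exc)
    return rows, errors
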
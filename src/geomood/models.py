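"""Score-estimation and depression-classification models, with their metrics.

Three estimators are provided:

* ordinary least-squares regression of QIDS score on features,
  ``Q = b0 + b1 . f``;
* a bounded quadratic-logistic model
  ``Q = a / (1 + exp(-(b0 + b1 . f + b2 . f^2)))`` fitted by nonlinear least
  squares (:class:`QuadraticLogisticGLM`), whose predictions stay smoothly
  inside (0, a) with a = 27, the QIDS ceiling;
* quadratic discriminant analysis for the depressed / not-depressed
  dichotomy.

The F1 score used throughout is the harmonic mean of sensitivity and
specificity (``f1_sesp``) — deliberately distinct from the precision-recall
F1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.linear_model import LinearRegression
from sklearn.metrics import roc_curve

QIDS_CEILING = 27.0


def fit_linear(f: np.ndarray, q: np.ndarray) -> LinearRegression:
    """Ordinary least squares of scores on one or more feature columns."""
    X = np.asarray(f, float)
    if X.ndim == 1:
        X = X[:, None]
    q = np.asarray(q, float)
    if len(X) < 2:
        raise ValueError("need at least two samples")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant feature: slope undefined")
    return LinearRegression().fit(X, q)


class QuadraticLogisticGLM(RegressorMixin, BaseEstimator):
    """Bounded quadratic model with a logistic link, fit by least squares.

    Predictions are ``a / (1 + exp(-eta))`` with
    ``eta = b0 + sum_j b1_j x_j + sum_j b2_j x_j^2``, so they lie strictly in
    (0, a). Coefficients minimise the squared prediction error from five
    deterministic starting points (sign patterns on the coefficients), which
    makes the fit reproducible without a random seed.

    Parameters
    ----------
    a : float
        Output ceiling (27, the maximum QIDS score).

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (p,)
        Linear coefficients b1.
    quad_coef_ : ndarray of shape (p,)
        Quadratic coefficients b2.
    """

    def __init__(self, a: float = QIDS_CEILING, max_nfev: int = 2000):
        self.a = a
        self.max_nfev = max_nfev

    def _eta(self, X: np.ndarray, theta: np.ndarray) -> np.ndarray:
        p = X.shape[1]
        return theta[0] + X @ theta[1 : p + 1] + (X**2) @ theta[p + 1 :]

    def _mu(self, X: np.ndarray, theta: np.ndarray) -> np.ndarray:
        eta = np.clip(self._eta(X, theta), -500, 500)
        return self.a / (1.0 + np.exp(-eta))

    def fit(self, X, y):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, float)
        if len(X) < 4:
            raise ValueError("need at least four samples")
        if np.any(y < 0) or np.any(y > self.a):
            raise ValueError(f"targets must lie within [0, {self.a}]")
        p = X.shape[1]

        starts = [
            np.zeros(2 * p + 1),
            np.concatenate([[1.0], np.zeros(2 * p)]),
            np.concatenate([[-1.0], np.zeros(2 * p)]),
            np.concatenate([[0.0], np.ones(p), np.zeros(p)]),
            np.concatenate([[0.0], -np.ones(p), np.zeros(p)]),
        ]

        def residuals(theta):
            return self._mu(X, theta) - y

        best = None
        failures = []
        for x0 in starts:
            try:
                res = least_squares(residuals, x0, max_nfev=self.max_nfev)
            except Exception as exc:  # pragma: no cover - scipy internal failure
                failures.append(str(exc))
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError(f"quadratic-logistic fit failed from all starts: {failures}")
        self.intercept_ = float(best.x[0])
        self.coef_ = best.x[1 : p + 1].copy()
        self.quad_coef_ = best.x[p + 1 :].copy()
        self.n_features_in_ = p
        self._theta = best.x
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return self._mu(X, self._theta)


def fit_qda(
    X: np.ndarray,
    y: np.ndarray,
    reg_param: float = 1e-3,
    priors=(0.5, 0.5),
) -> QuadraticDiscriminantAnalysis:
    """Gaussian class-conditional (QDA) fit with a small covariance ridge.

    ``reg_param`` shrinks each class covariance slightly toward a scaled
    identity; discrete features (such as the cluster count) can be constant
    within a class, which would otherwise make the covariance singular.
    Priors default to equal, matching class-equalized training sets; class
    scores for ROC thresholding come from ``predict_proba``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("need at least two samples per class")
    model = QuadraticDiscriminantAnalysis(priors=list(priors), reg_param=reg_param)
    return model.fit(X, y)


def mae(q: np.ndarray, q_hat: np.ndarray) -> float:
    """Mean absolute error between true and estimated scores."""
    q = np.asarray(q, float)
    q_hat = np.asarray(q_hat, float)
    if q.shape != q_hat.shape:
        raise ValueError("length mismatch")
    if q.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(q - q_hat)))


def f1_sesp(se: float, sp: float) -> float:
    """Harmonic mean of sensitivity and specificity (0 when both are 0)."""
    if se + sp == 0:
        return 0.0
    return 2.0 * se * sp / (se + sp)


@dataclasses.dataclass
class ClassificationMetrics:
    ac: float
    se: float
    sp: float
    f1: float
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


def classification_metrics(
    y: np.ndarray, y_hat: np.ndarray, scores: np.ndarray | None = None
) -> ClassificationMetrics:
    """Accuracy, sensitivity, specificity, Se/Sp F1, and ROC/AUC.

    ``scores`` (continuous class-1 scores) drive the ROC threshold sweep;
    when omitted the hard predictions are used. Requires both classes in
    ``y``.
    """
    y = np.asarray(y).astype(int)
    y_hat = np.asarray(y_hat).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    tp = int(np.sum((y == 1) & (y_hat == 1)))
    tn = int(np.sum((y == 0) & (y_hat == 0)))
    fp = int(np.sum((y == 0) & (y_hat == 1)))
    fn = int(np.sum((y == 1) & (y_hat == 0)))
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    ac = (tp + tn) / len(y)
    if scores is None:
        scores = y_hat.astype(float)
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ClassificationMetrics(ac, se, sp, f1_sesp(se, sp), auc, fpr, tpr)


def f_test_vs_baseline(
    residuals_model: np.ndarray, residuals_baseline: np.ndarray, df_model: int
) -> tuple[float, float]:
    """F-test of a fitted model against the constant-mean baseline.

    ``df_model`` counts the model's parameters including its intercept (the
    baseline has one). Returns ``(F, p)`` from the F distribution with
    ``(df_model - 1, n - df_model)`` degrees of freedom.
    """
    r1 = np.asarray(residuals_model, float)
    r0 = np.asarray(residuals_baseline, float)
    n = len(r1)
    df_num = df_model - 1
    df_den = n - df_model
    if df_num <= 0 or df_den <= 0:
        raise ValueError("non-positive degrees of freedom")
    rss1 = float(np.sum(r1**2))
    rss0 = float(np.sum(r0**2))
    if rss1 == 0:
        return np.inf, 0.0
    f = max((rss0 - rss1) / df_num, 0.0) / (rss1 / df_den)
    return f, float(stats.f.sf(f, df_num, df_den))
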
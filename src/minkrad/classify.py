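"""Classifiers and evaluation metrics for the two-class response problem.

Two classifiers are provided, both tuned by leave-one-out cross-validation
(LOOCV) and both exposing the scikit-learn estimator protocol:

* :class:`LOOCVGridRBFSVM` — an RBF-kernel support vector machine whose
  ``(C, gamma)`` pair is chosen by exhaustive grid search maximizing LOOCV
  accuracy.
* :class:`LassoLogisticLOOCV` — L1-penalized logistic regression solved by
  an iteratively reweighted quadratic approximation with coordinate-wise
  soft-thresholding, with the penalty chosen by LOOCV accuracy.

Accuracy, sensitivity and specificity are reported with Wilson score
intervals; ranking performance with the ROC area under the curve.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y
from statsmodels.stats.proportion import proportion_confint

#: Default RBF-SVM search grid (powers of two, LIBSVM practice).
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** k for k in range(-15, 4, 2))

#: Default lasso penalty grid (log-spaced).
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(
    float(x) for x in np.logspace(-3, 1, 17)
)


def wilson_interval(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Has the correct boundary behaviour: the lower bound is exactly 0 when
    ``successes == 0`` and the upper bound exactly 1 when ``successes == n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, {n}], got {successes}")
    lo, hi = proportion_confint(successes, n, alpha=1 - conf, method="wilson")
    # the score interval's bounds are exactly 0 / 1 at the boundary counts
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    return float(lo), float(hi)


def roc_auc(decision_values, labels) -> float:
    """ROC area under the curve of a score for a binary label.

    Equals the Mann–Whitney U statistic normalized by ``n_pos * n_neg``;
    tied scores contribute one half.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("ROC analysis needs both classes present")
    return float(roc_auc_score(labels, np.asarray(decision_values, dtype=float)))


def classification_metrics(y_true, y_pred, decision_values=None,
                           conf: float = 0.95) -> dict:
    """Accuracy, sensitivity, specificity (with Wilson intervals) and AUC.

    Accuracy is ``(TP + TN) / (TP + FP + TN + FN)``; sensitivity is the
    recall of the positive class (label 1), specificity of the negative.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ValueError("empty evaluation set")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = tp + tn + fp + fn
    out = {
        "n": n,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": (tp + tn) / n,
        "accuracy_ci": list(wilson_interval(tp + tn, n, conf)),
    }
    if tp + fn > 0:
        out["sensitivity"] = tp / (tp + fn)
        out["sensitivity_ci"] = list(wilson_interval(tp, tp + fn, conf))
    if tn + fp > 0:
        out["specificity"] = tn / (tn + fp)
        out["specificity_ci"] = list(wilson_interval(tn, tn + fp, conf))
    if decision_values is not None and np.unique(y_true).size == 2:
        out["auc"] = roc_auc(decision_values, y_true)
    return out


def _loocv_indices(n: int):
    for i in range(n):
        idx = np.ones(n, dtype=bool)
        idx[i] = False
        yield i, idx


class LOOCVGridRBFSVM(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with (C, gamma) chosen by LOOCV grid search.

    For every grid pair the LOOCV accuracy is computed; the pair with the
    highest accuracy wins, ties broken by the smallest ``C`` then the
    smallest ``gamma``.  The final model is trained on all rows at the
    chosen pair, and the held-out LOOCV predictions and decision values at
    that pair are retained for ROC analysis and honest reporting.

    Expects features already selected and scaled; labels in {0, 1} with 1
    the positive (progression) class.

    Attributes
    ----------
    C_, gamma_ : float
        Chosen hyperparameters.
    loocv_predictions_, loocv_decision_ : ndarray of shape (n_samples,)
        Held-out label and decision value per sample at (C_, gamma_).
    loocv_accuracy_ : float
    loocv_metrics_ : dict
        Accuracy/sensitivity/specificity with Wilson intervals and AUC of
        the held-out predictions.
    grid_accuracy_ : ndarray of shape (len(C_grid), len(gamma_grid))
        The full LOOCV accuracy surface.
    """

    def __init__(self, C_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                 conf: float = 0.95):
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.conf = conf

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = y.astype(int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("LOOCV SVM needs exactly two classes")
        n = len(y)
        c_grid = np.asarray(self.C_grid, dtype=float)
        g_grid = np.asarray(self.gamma_grid, dtype=float)
        acc = np.zeros((c_grid.size, g_grid.size))
        preds = np.zeros((c_grid.size, g_grid.size, n), dtype=int)
        decs = np.zeros((c_grid.size, g_grid.size, n))
        for ic, C in enumerate(c_grid):
            for ig, gamma in enumerate(g_grid):
                for i, idx in _loocv_indices(n):
                    if np.unique(y[idx]).size < 2:
                        # leave-one-out removed the last member of a class
                        preds[ic, ig, i] = int(np.bincount(y[idx]).argmax())
                        decs[ic, ig, i] = 0.0
                        continue
                    clf = SVC(kernel="rbf", C=C, gamma=gamma)
                    clf.fit(X[idx], y[idx])
                    preds[ic, ig, i] = int(clf.predict(X[i:i + 1])[0])
                    decs[ic, ig, i] = float(clf.decision_function(X[i:i + 1])[0])
                acc[ic, ig] = float(np.mean(preds[ic, ig] == y))
        # Ties: smallest C, then smallest gamma (grids are sorted ascending).
        best = np.unravel_index(
            np.argmax(np.round(acc, 12)), acc.shape
        )
        self.grid_accuracy_ = acc
        self.C_ = float(c_grid[best[0]])
        self.gamma_ = float(g_grid[best[1]])
        self.loocv_predictions_ = preds[best]
        self.loocv_decision_ = decs[best]
        self.loocv_accuracy_ = float(acc[best])
        self.loocv_metrics_ = classification_metrics(
            y, self.loocv_predictions_, self.loocv_decision_, conf=self.conf
        )
        self.model_ = SVC(kernel="rbf", C=self.C_, gamma=self.gamma_).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self.model_.decision_function(np.asarray(X, dtype=float))


def _soft_threshold(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


class LassoConvergenceWarning(UserWarning):
    """The penalized solver hit the iteration cap before the tolerance."""


@njit(cache=True)
def _lasso_irls_kernel(X, y, lam, tol, max_outer, beta, beta0):
    """IRLS outer loop with an exact coordinate-descent inner solve.

    Returns (beta, beta0, n_outer, converged_flag).  Numba-compiled: the
    inner coordinate sweeps on correlated radiomics features may need many
    thousands of passes, which is where nearly all the time goes.
    """
    n, d = X.shape
    cap = 30.0  # |coef| beyond this on standardized data means separability
    outer = 0
    converged = False
    while outer < max_outer:
        outer += 1
        # Newton-type quadratic surrogate at the current estimate
        eta = np.empty(n)
        for i in range(n):
            s = beta0
            for j in range(d):
                s += X[i, j] * beta[j]
            if s > 30.0:
                s = 30.0
            elif s < -30.0:
                s = -30.0
            eta[i] = s
        w = np.empty(n)
        z = np.empty(n)
        sw = 0.0
        for i in range(n):
            p = 1.0 / (1.0 + np.exp(-eta[i]))
            wi = p * (1.0 - p)
            if wi < 1e-5:
                wi = 1e-5
            w[i] = wi
            sw += wi
            z[i] = eta[i] + (y[i] - p) / wi
        dens = np.zeros(d)
        for j in range(d):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            dens[j] = s / n
        r = np.empty(n)
        for i in range(n):
            s = z[i] - beta0
            for j in range(d):
                s -= X[i, j] * beta[j]
            r[i] = s
        # coordinate-wise soft-thresholding until the surrogate is solved
        outer_delta = 0.0
        for sweep in range(100_000):
            sweep_delta = 0.0
            db0 = 0.0
            for i in range(n):
                db0 += w[i] * r[i]
            db0 /= sw
            for i in range(n):
                r[i] -= db0
            beta0 += db0
            if abs(db0) > sweep_delta:
                sweep_delta = abs(db0)
            for j in range(d):
                if dens[j] == 0.0:
                    continue
                num = 0.0
                for i in range(n):
                    num += w[i] * X[i, j] * r[i]
                num = num / n + dens[j] * beta[j]
                if num > lam:
                    nb = (num - lam) / dens[j]
                elif num < -lam:
                    nb = (num + lam) / dens[j]
                else:
                    nb = 0.0
                diff = nb - beta[j]
                if diff != 0.0:
                    for i in range(n):
                        r[i] -= X[i, j] * diff
                    if abs(diff) > sweep_delta:
                        sweep_delta = abs(diff)
                    beta[j] = nb
            if sweep == 0:
                outer_delta = sweep_delta
            if sweep_delta < 0.1 * tol:
                break
        # converged when a fresh reweighting moves no coefficient by >= tol
        if outer_delta < tol:
            converged = True
            break
        stop = abs(beta0) > cap
        for j in range(d):
            if abs(beta[j]) > cap:
                stop = True
        if stop:
            break
    return beta, beta0, outer, converged


def lasso_logistic(X, y, lam: float, tol: float = 1e-6,
                   max_iter: int = 10_000,
                   warm_start: tuple[np.ndarray, float] | None = None,
                   ) -> tuple[np.ndarray, float, int, bool]:
    """L1-penalized logistic regression by IRLS + coordinate descent.

    Minimizes ``-(1/n) loglik(beta0, beta) + lam * ||beta||_1`` (intercept
    unpenalized).  Each outer iteration builds the Newton-type quadratic
    approximation at the current estimate (working response and weights)
    and minimizes it exactly by coordinate-wise soft-thresholding; the fit
    has converged when a reweighting step changes no coefficient by
    ``tol`` or more, up to ``max_iter`` reweightings.

    Returns ``(beta, intercept, n_iter, converged)``.  On separable data
    with ``lam`` near 0 the penalized likelihood has no finite maximizer;
    coefficients are then capped (at 30 on the standardized scale) and
    ``converged`` is False (a warning is emitted).
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if warm_start is not None:
        beta = np.array(warm_start[0], dtype=float)
        beta0 = float(warm_start[1])
    else:
        beta = np.zeros(X.shape[1])
        beta0 = 0.0
    beta, beta0, it, converged = _lasso_irls_kernel(
        X, y, float(lam), float(tol), int(max_iter), beta, beta0
    )
    if not converged:
        warnings.warn(
            f"lasso solver stopped after {it} reweightings without reaching "
            f"tolerance {tol} (lambda={lam}); coefficients capped",
            LassoConvergenceWarning,
        )
    return beta, float(beta0), int(it), bool(converged)


class LassoLogisticLOOCV(ClassifierMixin, BaseEstimator):
    """L1-penalized logistic regression with the penalty chosen by LOOCV.

    The penalty grid is scanned; the value with the highest LOOCV accuracy
    wins, ties broken towards the larger penalty (the sparser model).  The
    final model is fit on all rows at the chosen penalty.

    Attributes
    ----------
    lambda_ : float
        Chosen penalty.
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    loocv_predictions_, loocv_decision_ : ndarray
        Held-out predictions/logits at ``lambda_``.
    loocv_accuracy_ : float
    loocv_metrics_ : dict
    converged_ : bool
    """

    def __init__(self, lambda_grid=DEFAULT_LAMBDA_GRID, tol: float = 1e-6,
                 max_iter: int = 10_000, conf: float = 0.95):
        self.lambda_grid = lambda_grid
        self.tol = tol
        self.max_iter = max_iter
        self.conf = conf

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = y.astype(int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("needs exactly two classes")
        n = len(y)
        grid = np.sort(np.asarray(self.lambda_grid, dtype=float))
        # per fold, fit the whole penalty path descending with warm starts
        preds_by_lam = np.zeros((grid.size, n), dtype=int)
        decs_by_lam = np.zeros((grid.size, n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", LassoConvergenceWarning)
            for i, idx in _loocv_indices(n):
                if np.unique(y[idx]).size < 2:
                    preds_by_lam[:, i] = int(np.bincount(y[idx]).argmax())
                    continue
                warm = None
                for k in range(grid.size - 1, -1, -1):
                    b, b0, _, _ = lasso_logistic(
                        X[idx], y[idx], float(grid[k]), tol=self.tol,
                        max_iter=self.max_iter, warm_start=warm,
                    )
                    warm = (b, b0)
                    decs_by_lam[k, i] = b0 + X[i] @ b
                    preds_by_lam[k, i] = int(decs_by_lam[k, i] >= 0)
        best_lam, best_acc = None, -1.0
        best_preds, best_decs = None, None
        for k, lam in enumerate(grid):
            preds, decs = preds_by_lam[k], decs_by_lam[k]
            acc = float(np.mean(preds == y))
            # ascending scan with >= : ties resolve to the larger (sparser)
            # penalty
            if acc >= best_acc:
                best_lam, best_acc = float(lam), acc
                best_preds, best_decs = preds, decs
        self.lambda_ = best_lam
        self.loocv_predictions_ = best_preds
        self.loocv_decision_ = best_decs
        self.loocv_accuracy_ = best_acc
        self.coef_, self.intercept_, self.n_iter_, self.converged_ = lasso_logistic(
            X, y, self.lambda_, tol=self.tol, max_iter=self.max_iter
        )
        self.loocv_metrics_ = classification_metrics(
            y, self.loocv_predictions_, self.loocv_decision_, conf=self.conf
        )
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)
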
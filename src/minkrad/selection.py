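"""Feature selection: univariate t-tests and random-forest importance.

Both selectors follow the scikit-learn transformer protocol (``fit``,
``transform``, ``get_support``) so they compose with pipelines and model
selection utilities.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y


class TTestSelector(SelectorMixin, BaseEstimator):
    """Keep features whose two-class difference is significant by t-test.

    A two-tailed unpaired Student t-test (equal variances) is run per
    feature; features with ``P < alpha`` are kept.  An optional Holm
    step-down correction is available for the family of tests.

    Parameters
    ----------
    alpha : float, default 0.05
        Per-feature significance threshold.
    holm : bool, default False
        Apply the Holm correction to the family of P values before
        thresholding.

    Attributes
    ----------
    t_, p_ : ndarray of shape (n_features,)
        t statistics and two-tailed P values.
    df_ : int
        Degrees of freedom ``n1 + n2 - 2``.
    neg_log10_p_ : ndarray
        ``-log10(P)`` per feature (the selection surface).
    support_ : bool ndarray
        Mask of the kept features.
    """

    def __init__(self, alpha: float = 0.05, holm: bool = False):
        self.alpha = alpha
        self.holm = holm

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 classes, got {classes.size}")
        a, b = X[y == classes[0]], X[y == classes[1]]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 samples per class for a t-test")
        res = stats.ttest_ind(a, b, axis=0, equal_var=True)
        self.t_ = np.asarray(res.statistic)
        self.p_ = np.asarray(res.pvalue)
        # Constant-in-both-classes features give 0/0 -> NaN; never selected.
        self.p_ = np.where(np.isnan(self.p_), 1.0, self.p_)
        self.t_ = np.where(np.isnan(self.t_), 0.0, self.t_)
        self.df_ = len(a) + len(b) - 2
        with np.errstate(divide="ignore"):
            self.neg_log10_p_ = -np.log10(self.p_)
        if self.holm:
            from statsmodels.stats.multitest import multipletests

            reject, _, _, _ = multipletests(self.p_, alpha=self.alpha,
                                            method="holm")
            self.support_ = reject
        else:
            self.support_ = self.p_ < self.alpha
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class RandomForestImportanceSelector(SelectorMixin, BaseEstimator):
    """Keep features with above-mean random-forest permutation importance.

    Importance is the classic out-of-bag (OOB) permutation measure: for
    every bootstrapped tree, the OOB accuracy drop when one feature column
    is shuffled among the OOB samples, averaged over trees.  Measuring on
    the OOB samples (rather than the training rows, which a deep forest
    classifies perfectly regardless of any single feature) keeps the
    measure informative on small, feature-redundant radiomics tables.
    Features scoring above the mean importance are kept — a parameter-free
    cut-off that is stable at radiomics-scale feature counts.

    Parameters
    ----------
    n_trees : int, default 1000
        Forest size.
    random_state : int
        Mandatory seed; bootstraps, tree randomness and permutations all
        derive from it.

    Attributes
    ----------
    importances_ : ndarray
        Mean OOB permutation importance (accuracy drop) per feature.
    threshold_ : float
        The mean importance used as cut-off.
    support_ : bool ndarray
    """

    def __init__(self, n_trees: int = 1000, random_state: int = 0):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        n, d = X.shape
        rng = np.random.default_rng(self.random_state)
        imp = np.zeros(d)
        used = 0
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree_seed = int(rng.integers(2 ** 31))
            if oob.size == 0:
                continue
            tree = DecisionTreeClassifier(
                max_features="sqrt", random_state=tree_seed
            ).fit(X[boot], y[boot])
            Xoob, yoob = X[oob], y[oob]
            base = np.sum(tree.predict(Xoob) == yoob)
            # one stacked predict per tree: block b holds OOB rows with
            # feature b permuted
            stacked = np.tile(Xoob, (d, 1))
            for j in range(d):
                rows = slice(j * oob.size, (j + 1) * oob.size)
                stacked[rows, j] = rng.permutation(Xoob[:, j])
            correct = (
                tree.predict(stacked) == np.tile(yoob, d)
            ).reshape(d, oob.size).sum(axis=1)
            imp += (base - correct) / oob.size
            used += 1
        self.importances_ = imp / max(used, 1)
        self.threshold_ = float(self.importances_.mean())
        self.support_ = self.importances_ > self.threshold_
        if not self.support_.any():
            # All-noise degenerate case: keep the single top feature so the
            # downstream classifier still has an input; importances_ records
            # the evidence either way.
            self.support_ = self.importances_ == self.importances_.max()
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
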
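"""Cohort-level orchestration: scaling, selection, training, evaluation.

A cohort is a pandas DataFrame with the 38 named feature columns, an index
of tumour ids and a ``label`` column (``progression`` — the positive class
— or ``pseudoprogression``).  Two analysis strategies are provided:

* ``ttest-svm``: univariate t-test selection (P < 0.05) followed by an
  RBF-SVM tuned and evaluated by leave-one-out cross-validation;
* ``rf-lasso``: random-forest permutation-importance selection followed by
  L1-penalized logistic regression with the penalty chosen by LOOCV.

Both strategies z-score each feature on the training cohort and apply the
training statistics unchanged to any test cohort.  The result of a fit is a
:class:`FitResult` that can be serialized to JSON and reloaded to classify
new feature tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .classify import (
    LassoLogisticLOOCV,
    LOOCVGridRBFSVM,
    classification_metrics,
)
from .minkowski import FEATURE_NAMES
from .selection import RandomForestImportanceSelector, TTestSelector

POSITIVE_LABEL = "progression"
NEGATIVE_LABEL = "pseudoprogression"


class FeatureScalingWarning(UserWarning):
    pass


class FeatureScaler(TransformerMixin, BaseEstimator):
    """Per-feature z-scoring that drops zero-variance features with a warning.

    Test data must be transformed with the training statistics, never its
    own; this is what ``transform`` does after ``fit`` on the training
    cohort.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1) if len(X) > 1 else np.zeros(X.shape[1])
        self.kept_ = self.scale_ > 0
        self.dropped_idx_ = np.flatnonzero(~self.kept_)
        if self.dropped_idx_.size:
            warnings.warn(
                f"dropping {self.dropped_idx_.size} zero-variance feature(s) "
                f"at column(s) {self.dropped_idx_.tolist()}",
                FeatureScalingWarning,
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        return (X[:, self.kept_] - self.mean_[self.kept_]) / self.scale_[self.kept_]


def labels_to_binary(labels) -> np.ndarray:
    """Map outcome labels to {0, 1} with progression as the positive class."""
    y = np.asarray(labels)
    out = np.zeros(len(y), dtype=int)
    for i, lab in enumerate(y):
        s = str(lab).strip().lower()
        if s in {POSITIVE_LABEL, "p", "1", "true"}:
            out[i] = 1
        elif s in {NEGATIVE_LABEL, "psp", "0", "false"}:
            out[i] = 0
        else:
            raise ValueError(f"unrecognized outcome label {lab!r}")
    return out


def split_table(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a cohort frame into (X, y, feature_names); validates the table."""
    feats = [c for c in df.columns if c in FEATURE_NAMES]
    if not feats:
        raise ValueError("no recognized feature columns in table")
    if "label" not in df.columns or df["label"].isna().any():
        missing = df.index[df["label"].isna()].tolist() if "label" in df.columns else list(df.index)
        raise ValueError(f"rows without labels: {missing}")
    X = df[feats].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    return X, labels_to_binary(df["label"]), feats


@dataclass
class FitResult:
    """A trained classifier with its provenance and honest LOOCV metrics.

    The SVM variant stores the scaled training matrix alongside
    ``(C, gamma)`` and is refit deterministically on load; the lasso variant
    stores its weights directly.
    """

    method: str                      # "ttest-svm" | "rf-lasso"
    seed: int
    feature_names: list[str]         # full input feature order
    selected: list[str]              # ordered selected feature names
    scaler_mean: list[float]         # stats over the selected features
    scaler_scale: list[float]
    dropped_features: list[str]
    model_params: dict
    loocv_predictions: list[int]
    loocv_decision: list[float]
    loocv_labels: list[int]
    metrics: dict
    selection_detail: dict = field(default_factory=dict)
    train_ids: list[str] = field(default_factory=list)

    # -- prediction ----------------------------------------------------
    def _decision(self, Xs: np.ndarray) -> np.ndarray:
        if self.method == "ttest-svm":
            from sklearn.svm import SVC

            Xtr = np.asarray(self.model_params["train_X"], dtype=float)
            ytr = np.asarray(self.model_params["train_y"], dtype=int)
            clf = SVC(kernel="rbf", C=self.model_params["C"],
                      gamma=self.model_params["gamma"]).fit(Xtr, ytr)
            return clf.decision_function(Xs)
        coef = np.asarray(self.model_params["coef"], dtype=float)
        return self.model_params["intercept"] + Xs @ coef

    def predict_frame(self, df: pd.DataFrame) -> pd.DataFrame:
        """Classify a feature table; returns id, decision value and label."""
        missing = [f for f in self.selected if f not in df.columns]
        if missing:
            raise ValueError(f"feature table is missing selected feature(s): {missing}")
        X = df[self.selected].to_numpy(dtype=float)
        Xs = (X - np.asarray(self.scaler_mean)) / np.asarray(self.scaler_scale)
        dec = self._decision(Xs)
        pred = (dec >= 0).astype(int) if self.method == "rf-lasso" else None
        if pred is None:
            # SVM decision sign follows class order {0,1}: positive -> class 1
            pred = (dec >= 0).astype(int)
        return pd.DataFrame({
            "tumour_id": df.index,
            "decision_value": dec,
            "predicted": np.where(pred == 1, POSITIVE_LABEL, NEGATIVE_LABEL),
        }).set_index("tumour_id")

    def evaluate_frame(self, df: pd.DataFrame, conf: float = 0.95) -> dict:
        """Metrics of this model on a labelled feature table."""
        if len(df) == 0:
            raise ValueError("empty test set")
        preds = self.predict_frame(df)
        y_true = labels_to_binary(df["label"])
        y_pred = labels_to_binary(preds["predicted"])
        dec = preds["decision_value"].to_numpy()
        return classification_metrics(
            y_true, y_pred,
            dec if np.unique(y_true).size == 2 else None,
            conf=conf,
        )

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": "minkrad-fit-result-v1",
            "method": self.method,
            "seed": self.seed,
            "feature_names": self.feature_names,
            "selected": self.selected,
            "scaler_mean": list(map(float, self.scaler_mean)),
            "scaler_scale": list(map(float, self.scaler_scale)),
            "dropped_features": self.dropped_features,
            "model_params": self.model_params,
            "loocv_predictions": list(map(int, self.loocv_predictions)),
            "loocv_decision": list(map(float, self.loocv_decision)),
            "loocv_labels": list(map(int, self.loocv_labels)),
            "metrics": self.metrics,
            "selection_detail": self.selection_detail,
            "train_ids": self.train_ids,
        }
        text = json.dumps(payload, indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FitResult":
        text = str(source)
        if not text.lstrip().startswith("{"):  # a path, not a JSON document
            text = Path(source).read_text()
        d = json.loads(text)
        d.pop("format", None)
        return cls(**d)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def train_model(
    df: pd.DataFrame,
    method: str = "ttest-svm",
    seed: int = 0,
    alpha: float = 0.05,
    holm: bool = False,
    C_grid=None,
    gamma_grid=None,
    lambda_grid=None,
    n_trees: int = 1000,
) -> FitResult:
    """Fit one of the two analysis strategies on a labelled cohort table.

    Selection runs on the raw features; the selected features are z-scored
    (training statistics recorded for later test cohorts) and passed to the
    LOOCV-tuned classifier.  All randomness derives from ``seed``.
    """
    X, y, feats = split_table(df)
    if method == "ttest-svm":
        sel = TTestSelector(alpha=alpha, holm=holm).fit(X, y)
        detail = {
            "t": sel.t_.tolist(),
            "p": sel.p_.tolist(),
            "df": int(sel.df_),
            "neg_log10_p": sel.neg_log10_p_.tolist(),
            "alpha": alpha,
        }
        if not sel.support_.any():
            raise ValueError(
                f"no feature reached P < {alpha}; nothing to train on"
            )
    elif method == "rf-lasso":
        sel = RandomForestImportanceSelector(
            n_trees=n_trees, random_state=seed
        ).fit(X, y)
        detail = {
            "importances": sel.importances_.tolist(),
            "threshold": sel.threshold_,
        }
    else:
        raise ValueError(f"unknown method {method!r}")

    selected = [f for f, keep in zip(feats, sel.support_) if keep]
    Xsel = X[:, sel.support_]
    scaler = FeatureScaler().fit(Xsel)
    kept_names = [f for f, k in zip(selected, scaler.kept_) if k]
    dropped = [f for f, k in zip(selected, scaler.kept_) if not k]
    Xs = scaler.transform(Xsel)

    if method == "ttest-svm":
        kwargs = {}
        if C_grid is not None:
            kwargs["C_grid"] = C_grid
        if gamma_grid is not None:
            kwargs["gamma_grid"] = gamma_grid
        clf = LOOCVGridRBFSVM(**kwargs).fit(Xs, y)
        model_params = {
            "kernel": "rbf",
            "C": clf.C_,
            "gamma": clf.gamma_,
            "train_X": Xs.tolist(),
            "train_y": y.tolist(),
        }
    else:
        kwargs = {}
        if lambda_grid is not None:
            kwargs["lambda_grid"] = lambda_grid
        clf = LassoLogisticLOOCV(**kwargs).fit(Xs, y)
        model_params = {
            "lambda": clf.lambda_,
            "coef": clf.coef_.tolist(),
            "intercept": float(clf.intercept_),
            "converged": bool(clf.converged_),
        }

    return FitResult(
        method=method,
        seed=seed,
        feature_names=feats,
        selected=kept_names,
        scaler_mean=scaler.mean_[scaler.kept_].tolist(),
        scaler_scale=scaler.scale_[scaler.kept_].tolist(),
        dropped_features=dropped,
        model_params=model_params,
        loocv_predictions=clf.loocv_predictions_.tolist(),
        loocv_decision=clf.loocv_decision_.tolist(),
        loocv_labels=y.tolist(),
        metrics=clf.loocv_metrics_,
        selection_detail=detail,
        train_ids=[str(i) for i in df.index],
    )


def load_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort feature CSV (tumour_id index, feature + label columns)."""
    df = pd.read_csv(path)
    if "tumour_id" in df.columns:
        df = df.set_index("tumour_id")
    return df


def save_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=True, index_label="tumour_id")
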
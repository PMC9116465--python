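"""Quality regression: RBF-kernel support-vector regression on CEIQA
feature vectors, with grid-searched hyperparameters selected by inner
cross-validated Spearman correlation, min-max feature scaling fitted on
the training partition only, and versioned model persistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.metrics import make_scorer
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from .exceptions import DataError, FingerprintError, ModelFormatError

__all__ = [
    "GridSearchSpec",
    "CEIQARegressor",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1

# canonical practical-guide RBF-SVR grid, log2 steps of 2
_DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
_DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


def _srocc_score(y_true, y_pred):
    from scipy.stats import spearmanr

    if np.ptp(y_pred) == 0 or np.ptp(y_true) == 0:
        return 0.0
    rho = spearmanr(y_true, y_pred).statistic
    return 0.0 if np.isnan(rho) else float(rho)


@dataclass(frozen=True)
class GridSearchSpec:
    """Hyperparameter search specification for the SVR quality model."""

    c_grid: tuple[float, ...] = _DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = _DEFAULT_GAMMA_GRID
    epsilon: float = 0.1
    cv: int = 5

    def __post_init__(self):
        if not self.c_grid or not self.gamma_grid:
            raise DataError("hyperparameter grids must be non-empty")
        if self.cv < 2:
            raise DataError("inner cross-validation needs k >= 2 folds")


class CEIQARegressor(RegressorMixin, BaseEstimator):
    """RBF-SVR quality model over CEIQA features.

    Fitting scales every feature dimension to [-1, 1] (learned from the
    training rows only), grid-searches (C, gamma) by mean inner-k-fold
    validation SROCC, and refits the winning pipeline on all rows.

    Parameters
    ----------
    c_grid, gamma_grid : iterables of floats
        Candidate regularization constants and RBF kernel widths.
    epsilon : float
        SVR epsilon-tube half-width.
    cv : int
        Inner k-fold count for hyperparameter selection.
    random_state : int or None
        Seeds the inner fold shuffling; fixed seed + fixed data gives
        identical selected hyperparameters and predictions.
    fingerprint : str or None
        Feature-layout fingerprint (from ``ScaleConfig.fingerprint()``);
        stored at fit time and enforced at predict time when features
        carry one.

    Attributes
    ----------
    pipeline_ : fitted sklearn Pipeline (scaler + SVR)
    best_params_ : dict with the selected C and gamma
    best_score_ : mean inner-CV SROCC of the selected parameters
    fingerprint_ : layout fingerprint bound to the model
    n_features_in_ : number of feature dimensions seen at fit
    """

    def __init__(self, c_grid=_DEFAULT_C_GRID, gamma_grid=_DEFAULT_GAMMA_GRID,
                 epsilon=0.1, cv=5, random_state=None, fingerprint=None):
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.epsilon = epsilon
        self.cv = cv
        self.random_state = random_state
        self.fingerprint = fingerprint

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise DataError(f"misaligned features {X.shape} and targets {y.shape}")
        if X.shape[0] < 10:
            raise DataError(f"need at least 10 training rows, got {X.shape[0]}")
        if not np.all(np.isfinite(X)):
            raise DataError("features contain NaN or infinite values")
        if np.ptp(y) == 0:
            raise DataError("constant quality targets: nothing to regress")
        base = Pipeline([
            ("scale", MinMaxScaler(feature_range=(-1, 1), clip=False)),
            ("svr", SVR(kernel="rbf", epsilon=self.epsilon)),
        ])
        folds = KFold(n_splits=min(self.cv, X.shape[0]), shuffle=True,
                      random_state=self.random_state)
        search = GridSearchCV(
            base,
            param_grid={"svr__C": list(self.c_grid),
                        "svr__gamma": list(self.gamma_grid)},
            scoring=make_scorer(_srocc_score),
            cv=folds,
            n_jobs=None,
            refit=True,
        )
        search.fit(X, y)
        self.pipeline_ = search.best_estimator_
        self.best_params_ = {
            "C": search.best_params_["svr__C"],
            "gamma": search.best_params_["svr__gamma"],
        }
        self.best_score_ = float(search.best_score_)
        self.n_features_in_ = X.shape[1]
        self.fingerprint_ = self.fingerprint or f"nfeat:{X.shape[1]}"
        return self

    def predict(self, X, fingerprint: str | None = None) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise DataError(f"expected a 2-D feature matrix, got shape {X.shape}")
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != self.n_features_in_:
            raise FingerprintError(
                f"model was trained on {self.n_features_in_} feature "
                f"dimensions, got {X.shape[1]}"
            )
        if fingerprint is not None and fingerprint != self.fingerprint_:
            raise FingerprintError(
                f"feature layout {fingerprint!r} does not match the model's "
                f"{self.fingerprint_!r}"
            )
        return self.pipeline_.predict(X)


def _split_feature_table(features):
    """Separate metadata columns from feature columns of a table built
    by ``extract_batch``; plain arrays pass through."""
    if isinstance(features, pd.DataFrame):
        import re

        feat_cols = [c for c in features.columns if re.match(r"s\d+_", c)]
        if not feat_cols:
            raise DataError("no feature columns (s*_*) found in the table")
        return features[feat_cols].to_numpy(dtype=np.float64), feat_cols
    return np.asarray(features, dtype=np.float64), None


def train(features, mos, spec: GridSearchSpec | None = None, seed: int = 0,
          fingerprint: str | None = None) -> CEIQARegressor:
    """Fit a quality model from a feature table (or matrix) and MOS labels."""
    spec = spec or GridSearchSpec()
    X, _ = _split_feature_table(features)
    model = CEIQARegressor(
        c_grid=tuple(spec.c_grid), gamma_grid=tuple(spec.gamma_grid),
        epsilon=spec.epsilon, cv=spec.cv, random_state=seed,
        fingerprint=fingerprint,
    )
    return model.fit(X, np.asarray(mos, dtype=np.float64))


def predict(model: CEIQARegressor, features, fingerprint: str | None = None) -> np.ndarray:
    """Quality scores for each row of a feature table or matrix."""
    X, _ = _split_feature_table(features) if np.ndim(features) != 1 else (features, None)
    return model.predict(X, fingerprint=fingerprint)


def save_model(model: CEIQARegressor, path) -> None:
    """Persist a fitted model with an explicit format version."""
    check_is_fitted(model, "pipeline_")
    payload = {
        "format_version": _FORMAT_VERSION,
        "fingerprint": model.fingerprint_,
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path) -> CEIQARegressor:
    """Load a persisted model, refusing unknown or corrupt files."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path} is not a ceiqa model file")
    if payload["format_version"] != _FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {payload['format_version']}"
        )
    model = payload["model"]
    model.fingerprint_ = payload["fingerprint"]
    return model
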
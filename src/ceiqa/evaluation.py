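"""Evaluation protocol for no-reference IQA models.

Implements the standard IQA performance criteria — SROCC (Spearman rank
correlation), PLCC (Pearson correlation after a 5-parameter logistic
remapping) and RMSE — together with repeated random train/test
evaluation (median and standard deviation over K splits) and the
Nadeau–Bengio corrected resampled paired t-test used to decide whether
two pipelines evaluated on the same split sequence differ significantly.

The logistic remapping applied before PLCC/RMSE is

    f(x) = b1 * (1/2 - 1/(1 + exp(b2 * (x - b3)))) + b4 * x + b5,

a monotone sigmoid-plus-affine family that absorbs any order-preserving
miscalibration between predicted scores and the subjective MOS scale;
identity and affine relations are inside the family, so perfectly
calibrated predictions fit with zero residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import model as model_mod
from .exceptions import DataError, ParameterError

__all__ = [
    "LogisticFit",
    "EvalSummary",
    "srocc",
    "logistic_fit",
    "plcc_rmse",
    "split_indices",
    "repeated_split_eval",
    "corrected_t_statistic",
    "corrected_resampled_ttest",
    "significance_matrix",
    "ladder_monotonicity",
]


def srocc(pred, mos) -> float:
    """Spearman rank-order correlation with midrank tie handling."""
    pred = np.asarray(pred, dtype=np.float64)
    mos = np.asarray(mos, dtype=np.float64)
    if pred.shape != mos.shape or pred.size < 3:
        raise DataError("need two aligned score vectors of length >= 3")
    if np.ptp(pred) == 0 or np.ptp(mos) == 0:
        raise DataError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(pred, mos).statistic)


@dataclass(frozen=True)
class LogisticFit:
    """Fitted 5-parameter logistic mapping from predicted score to MOS."""

    beta: tuple[float, float, float, float, float]
    converged: bool

    def __call__(self, x):
        return _logistic5(np.asarray(x, dtype=np.float64), *self.beta)


def _logistic5(x, b1, b2, b3, b4, b5):
    # clip the exponent to keep the sigmoid finite under extreme b2
    z = np.clip(b2 * (x - b3), -500, 500)
    return b1 * (0.5 - 1.0 / (1.0 + np.exp(z))) + b4 * x + b5


def logistic_fit(pred, mos) -> LogisticFit:
    """Least-squares fit of the 5-parameter logistic family.

    Initialization: b1 = MOS range with the sign of the raw correlation,
    b2 = 1/std(pred), b3 = mean(pred), and (b4, b5) from a preliminary
    linear fit.  On non-convergence the identity mapping is returned
    with ``converged=False`` (a warning is emitted).
    """
    pred = np.asarray(pred, dtype=np.float64)
    mos = np.asarray(mos, dtype=np.float64)
    if pred.shape != mos.shape or pred.size < 5:
        raise DataError("need two aligned score vectors of length >= 5")
    if np.ptp(pred) == 0:
        raise DataError("cannot fit a mapping from constant predictions")
    corr = np.corrcoef(pred, mos)[0, 1]
    sign = 1.0 if (np.isnan(corr) or corr >= 0) else -1.0
    slope, intercept = np.polyfit(pred, mos, 1)
    p0 = [
        sign * float(np.ptp(mos)),
        1.0 / max(float(np.std(pred)), 1e-12),
        float(np.mean(pred)),
        float(slope),
        float(intercept),
    ]
    best, best_sse = None, np.inf
    for method, kwargs in (
        ("lm", {"maxfev": 20000}),
        ("trf", {"max_nfev": 20000}),
        ("dogbox", {"max_nfev": 20000}),
    ):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                beta, _ = optimize.curve_fit(
                    _logistic5, pred, mos, p0=p0, method=method,
                    ftol=1e-8, xtol=1e-8, **kwargs,
                )
            fitted = _logistic5(pred, *beta)
            if not np.all(np.isfinite(fitted)):
                continue
            sse = float(((fitted - mos) ** 2).sum())
            if sse < best_sse:
                best, best_sse = beta, sse
        except (RuntimeError, ValueError):
            continue
    if best is None:
        warnings.warn("logistic fit did not converge; using identity mapping",
                      stacklevel=2)
        return LogisticFit(beta=(0.0, 1.0, 0.0, 1.0, 0.0), converged=False)
    return LogisticFit(beta=tuple(float(b) for b in best), converged=True)


def plcc_rmse(pred, mos) -> tuple[float, float]:
    """Pearson correlation and RMSE between logistic-remapped
    predictions and MOS."""
    fit = logistic_fit(pred, mos)
    mapped = fit(np.asarray(pred, dtype=np.float64))
    mos = np.asarray(mos, dtype=np.float64)
    if np.ptp(mapped) == 0 or np.ptp(mos) == 0:
        raise DataError("correlation undefined for constant vectors")
    plcc = float(np.corrcoef(mapped, mos)[0, 1])
    rmse = float(np.sqrt(np.mean((mapped - mos) ** 2)))
    return plcc, rmse


def split_indices(n: int, n_repeats: int, train_frac: float, seed: int):
    """Deterministic sequence of (train_idx, test_idx) pairs.

    Training size is round(train_frac * n); the remainder is the test
    partition.  The sequence depends only on (n, n_repeats, train_frac,
    seed), so competing pipelines can replay identical splits.
    """
    if not 0 < train_frac < 1:
        raise ParameterError(f"train_frac must be in (0, 1), got {train_frac}")
    n_train = int(round(train_frac * n))
    if n_train < 1 or n_train >= n:
        raise DataError(f"{n} samples leave no valid {train_frac:.0%} split")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return out


@dataclass(frozen=True)
class EvalSummary:
    """Per-repeat criteria with median/STD reporting."""

    srocc: np.ndarray
    plcc: np.ndarray
    rmse: np.ndarray
    n_repeats: int
    train_frac: float
    seed: int
    n_train: int
    n_test: int

    @property
    def median_srocc(self) -> float:
        return float(np.median(self.srocc))

    @property
    def median_plcc(self) -> float:
        return float(np.median(self.plcc))

    @property
    def median_rmse(self) -> float:
        return float(np.median(self.rmse))

    @property
    def std_srocc(self) -> float:
        return float(np.std(self.srocc, ddof=1)) if self.n_repeats > 1 else 0.0

    @property
    def std_plcc(self) -> float:
        return float(np.std(self.plcc, ddof=1)) if self.n_repeats > 1 else 0.0

    @property
    def std_rmse(self) -> float:
        return float(np.std(self.rmse, ddof=1)) if self.n_repeats > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "repeat": np.arange(self.n_repeats),
            "srocc": self.srocc, "plcc": self.plcc, "rmse": self.rmse,
        })


def repeated_split_eval(
    features,
    mos,
    n_repeats: int = 1000,
    train_frac: float = 0.8,
    seed: int = 0,
    model_spec: model_mod.GridSearchSpec | None = None,
) -> EvalSummary:
    """Repeated random train/test evaluation of the SVR quality model.

    For each repeat a fresh split is drawn from the seeded stream, a
    model is grid-search trained on the training partition (feature
    scaling included, so no information leaks from the test rows), and
    SROCC / PLCC / RMSE are computed on the held-out partition.
    """
    if n_repeats < 1:
        raise ParameterError("need at least one repeat")
    X, _ = model_mod._split_feature_table(features)
    y = np.asarray(mos, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise DataError("features and MOS are misaligned")
    splits = split_indices(X.shape[0], n_repeats, train_frac, seed)
    sr, pl, rm = [], [], []
    for rep, (tr, te) in enumerate(splits):
        m = model_mod.train(X[tr], y[tr], spec=model_spec, seed=seed + rep)
        pred = m.predict(X[te])
        sr.append(srocc(pred, y[te]))
        p, r = plcc_rmse(pred, y[te])
        pl.append(p)
        rm.append(r)
    return EvalSummary(
        srocc=np.asarray(sr), plcc=np.asarray(pl), rmse=np.asarray(rm),
        n_repeats=n_repeats, train_frac=train_frac, seed=seed,
        n_train=len(splits[0][0]), n_test=len(splits[0][1]),
    )


def corrected_t_statistic(diffs, n_train: int, n_test: int) -> float:
    """Nadeau–Bengio corrected resampled t statistic.

    t = mean(d) / sqrt( var(d) * (1/K + n_test/n_train) ) with unbiased
    variance over the K paired per-repeat differences; the n_test/n_train
    term inflates the denominator to compensate for the overlap between
    resampled training sets.
    """
    d = np.asarray(diffs, dtype=np.float64)
    if d.size < 2:
        raise DataError("need at least two paired repeats")
    if n_train <= 0 or n_test <= 0:
        raise ParameterError("partition sizes must be positive")
    var = float(np.var(d, ddof=1))
    if var == 0:
        return 0.0 if float(np.mean(d)) == 0 else np.inf * np.sign(np.mean(d))
    k = d.size
    return float(np.mean(d) / np.sqrt(var * (1.0 / k + n_test / n_train)))


def corrected_resampled_ttest(
    scores_a, scores_b, n_train: int, n_test: int, alpha: float = 0.05
) -> int:
    """Decide whether method a is significantly better (+1), worse (-1)
    or similar (0) to method b over paired per-repeat scores from
    identical split sequences, at confidence 1 - alpha (two-sided,
    K - 1 degrees of freedom)."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise DataError("paired score vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        return 0
    t = corrected_t_statistic(d, n_train, n_test)
    crit = stats.t.ppf(1.0 - alpha / 2.0, df=d.size - 1)
    if abs(t) <= crit:
        return 0
    return 1 if t > 0 else -1


def significance_matrix(
    per_method_scores: dict, n_train: int, n_test: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise corrected resampled t-tests between methods evaluated on
    the same split sequence; antisymmetric with zero diagonal, entries
    in {1, -1, 0} (row method better / worse / similar than column)."""
    names = list(per_method_scores)
    lengths = {len(np.asarray(v)) for v in per_method_scores.values()}
    if len(lengths) > 1:
        raise DataError("per-method score vectors have mismatched lengths")
    mat = np.zeros((len(names), len(names)), dtype=int)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                d = corrected_resampled_ttest(
                    per_method_scores[a], per_method_scores[b],
                    n_train, n_test, alpha,
                )
                mat[i, j] = d
                mat[j, i] = -d
    return pd.DataFrame(mat, index=names, columns=names)


def ladder_monotonicity(pred, ladder_ids, severities) -> float:
    """Fraction of severity ladders whose predicted quality scores are
    strictly decreasing in distortion severity.

    A ladder is one phantom/distortion-kind group observed at several
    severities; a trained quality model that has captured the perceptual
    degradation should rank every ladder from clean to most distorted.
    """
    pred = np.asarray(pred, dtype=np.float64)
    ladder_ids = np.asarray(ladder_ids)
    severities = np.asarray(severities, dtype=np.float64)
    if not (pred.shape == ladder_ids.shape == severities.shape):
        raise DataError("pred, ladder_ids and severities must align")
    ok = total = 0
    for lad in np.unique(ladder_ids):
        sel = ladder_ids == lad
        if sel.sum() < 2:
            continue
        order = np.argsort(severities[sel], kind="stable")
        p = pred[sel][order]
        total += 1
        if np.all(np.diff(p) < 0):
            ok += 1
    if total == 0:
        raise DataError("no ladder has more than one severity")
    return ok / total
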
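"""Multi-miRNA logistic signature: fit, ROC, calibration.

The signature is an ordinary binomial GLM: stage II/III membership is
regressed on the normalized expression of the signature miRNAs.  The
fit is maximum likelihood by iteratively reweighted least squares, with
predictors z-standardized internally for numerical stability (the
standardization parameters are stored so coefficients are available on
both scales).

Discrimination is summarized by the empirical ROC curve — thresholding
at every distinct score — whose area equals the Mann-Whitney statistic
U / (n_pos * n_neg) with ties counted one half; the confidence interval
is DeLong's.  Calibration is summarized by the Brier score, the
calibration slope (coefficient of a logistic refit of outcomes on the
logit of predicted probability) and the calibration-in-the-large
intercept (refit with the slope fixed at 1).

Evaluation is in-sample by default; ``evaluate_signature`` offers an
optional stratified cross-validated mode for sensitivity analyses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .datatypes import (
    CalibrationResult,
    ExpressionMatrix,
    MirstageError,
    ROCResult,
    SignatureModel,
    ValidationError,
)

logger = logging.getLogger(__name__)

_MAX_ITER = 100
_TOL = 1e-8


def _irls(
    design: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
) -> tuple[np.ndarray, bool, int]:
    """Binomial-GLM IRLS on a design matrix that already includes any intercept."""
    n, p = design.shape
    beta = np.zeros(p)
    off = np.zeros(n) if offset is None else offset
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta + off
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = (eta - off) + (y - mu) / w
        wx = design * w[:, np.newaxis]
        try:
            beta_new = np.linalg.solve(design.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(design.T @ wx, wx.T @ z, rcond=None)
        delta = np.max(np.abs(beta_new - beta)) if p else 0.0
        beta = beta_new
        if delta < tol:
            converged = True
            break
    return beta, converged, it


def fit_logistic(
    X: ExpressionMatrix | pd.DataFrame | np.ndarray,
    y,
    feature_order: list[str] | None = None,
) -> SignatureModel:
    """Fit the logistic signature by maximum likelihood (IRLS).

    ``X`` is features x samples (an ExpressionMatrix restricted to the
    signature miRNAs, or an equivalent array); ``y`` is the binary
    stage label per sample (1 = stage II/III).  Predictors are
    z-standardized internally.  Convergence requires the largest
    coefficient change to fall below 1e-8 within 100 iterations;
    perfectly separated data are returned with ``converged=False`` and
    a separation warning rather than raising.
    """
    if isinstance(X, ExpressionMatrix):
        frame = X.values
    elif isinstance(X, pd.DataFrame):
        frame = X
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("X must be a 2-D features x samples array")
        names = feature_order or [f"f{i}" for i in range(arr.shape[0])]
        frame = pd.DataFrame(arr, index=names)
    if feature_order is not None:
        missing = [f for f in feature_order if f not in frame.index]
        if missing:
            raise KeyError(f"features absent from X: {missing[:5]}")
        frame = frame.loc[feature_order]

    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != frame.shape[1]:
        raise ValidationError("y must be one binary label per sample")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("y must contain both classes")
    if counts.min() < 2:
        raise ValidationError("each class needs at least 2 samples")

    mat = frame.to_numpy(dtype=float).T  # samples x features
    means = mat.mean(axis=0)
    scales = mat.std(axis=0, ddof=0)
    scales = np.where(scales > 0, scales, 1.0)
    std = (mat - means) / scales
    design = np.column_stack([np.ones(len(y)), std])

    beta, converged, n_iter = _irls(design, y)
    eta = design @ beta
    separated = False
    if not converged and np.max(np.abs(eta)) > 30.0:
        separated = True
        logger.warning(
            "fit_logistic: apparent perfect separation; coefficients are "
            "unstable and the convergence flag is False"
        )
    return SignatureModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        feature_order=list(frame.index),
        feature_means=means,
        feature_scales=scales,
        converged=converged,
        n_iterations=n_iter,
        separation_warning=separated,
    )


def predict_prob(model: SignatureModel, X: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Predicted stage II/III probabilities, using the stored standardization."""
    frame = X.values if isinstance(X, ExpressionMatrix) else X
    missing = [f for f in model.feature_order if f not in frame.index]
    if missing:
        raise KeyError(f"features absent from X: {missing[:5]}")
    mat = frame.loc[model.feature_order].to_numpy(dtype=float).T
    std = (mat - model.feature_means) / model.feature_scales
    eta = model.intercept + std @ model.coefficients
    return pd.Series(expit(eta), index=frame.columns, name="prob_stage_II_III")


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (tz[:m] - tx) / n  # placement of each positive among negatives
    v01 = 1.0 - (tz[m:] - ty) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_empirical(scores, labels, ci_level: float = 0.95) -> ROCResult:
    """Empirical ROC curve with Mann-Whitney AUC and DeLong CI.

    The curve is traced by thresholding at every distinct score value,
    so tied scores move diagonally and the trapezoidal area equals the
    tie-corrected Mann-Whitney AUC exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length vectors")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to draw a ROC curve")

    thresholds = np.unique(scores)[::-1]
    tp = np.array([(scores[labels == 1] >= t).sum() for t in thresholds], dtype=float)
    fp = np.array([(scores[labels == 0] >= t).sum() for t in thresholds], dtype=float)
    curve = np.column_stack(
        [np.concatenate([[0.0], fp / n_neg]), np.concatenate([[0.0], tp / n_pos])]
    )
    if curve[-1, 0] != 1.0 or curve[-1, 1] != 1.0:
        curve = np.vstack([curve, [1.0, 1.0]])

    auc = _mann_whitney_auc(scores, labels)
    var = _delong_variance(scores, labels)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = zcrit * np.sqrt(max(var, 0.0))
    ci_low = float(np.clip(auc - half, 0.0, 1.0))
    ci_high = float(np.clip(auc + half, 0.0, 1.0))
    return ROCResult(
        auc=auc, ci_low=ci_low, ci_high=ci_high, curve=curve, n_pos=n_pos, n_neg=n_neg
    )


def calibration_assess(probs, labels, n_bins: int = 10) -> CalibrationResult:
    """Brier score, calibration slope/intercept and a binned reliability curve.

    Probabilities of exactly 0 or 1 are clipped to [1e-12, 1 - 1e-12]
    (with a logged notice) before taking logits.  The slope is the
    coefficient of a logistic refit of outcomes on logit(prob); the
    intercept is from the refit with the slope fixed at 1 (offset fit),
    the usual calibration-in-the-large convention.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.shape != labels.shape:
        raise ValidationError("probs and labels must have equal length")
    if np.any((probs < 0) | (probs > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    if np.any((probs <= 0) | (probs >= 1)):
        logger.info("calibration_assess: clipping boundary probabilities")
        probs = np.clip(probs, 1e-12, 1.0 - 1e-12)

    brier = float(np.mean((probs - labels) ** 2))
    lp = logit(probs)
    beta_slope, _, _ = _irls(np.column_stack([np.ones_like(lp), lp]), labels)
    slope = float(beta_slope[1])
    beta_int, _, _ = _irls(np.ones((len(lp), 1)), labels, offset=lp)
    intercept = float(beta_int[0])

    order = np.argsort(probs, kind="mergesort")
    bins = np.array_split(order, min(n_bins, len(probs)))
    curve = np.array(
        [[probs[b].mean(), labels[b].mean()] for b in bins if len(b) > 0]
    )
    return CalibrationResult(intercept=intercept, slope=slope, brier=brier, curve=curve)


def evaluate_signature(
    expr: ExpressionMatrix,
    y,
    signature_ids: list[str],
    cv_folds: int | None = None,
    seed: int = 0,
) -> tuple[SignatureModel, ROCResult, CalibrationResult, pd.Series]:
    """Fit the signature and assess discrimination and calibration.

    By default the model is fitted and evaluated on the same samples
    (apparent performance).  With ``cv_folds`` set, probabilities are
    instead produced out-of-fold by stratified cross-validation; the
    returned model is still the full-data fit.
    """
    avail = [f for f in signature_ids if f in expr.values.index]
    missing = [f for f in signature_ids if f not in expr.values.index]
    if missing:
        logger.warning(
            "evaluate_signature: %d signature miRNAs absent from the matrix", len(missing)
        )
    if not avail:
        raise MirstageError("no signature feature present in the expression matrix")
    sub = expr.values.loc[avail]
    y = np.asarray(y, dtype=int)
    model = fit_logistic(sub, y)
    if cv_folds is None:
        probs = predict_prob(model, sub)
    else:
        probs = pd.Series(index=sub.columns, dtype=float)
        rng = np.random.default_rng(seed)
        folds = np.empty(len(y), dtype=int)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % cv_folds
        for k in range(cv_folds):
            train, test = folds != k, folds == k
            m_k = fit_logistic(sub.loc[:, sub.columns[train]], y[train])
            probs.iloc[np.flatnonzero(test)] = predict_prob(
                m_k, sub.loc[:, sub.columns[test]]
            ).to_numpy()
    roc = roc_empirical(probs.to_numpy(), y)
    cal = calibration_assess(np.clip(probs.to_numpy(), 1e-12, 1 - 1e-12), y)
    return model, roc, cal, probs
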
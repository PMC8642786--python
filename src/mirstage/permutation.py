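"""Relearned-classifier permutation null for the signature AUC.

An in-sample AUC from a refitted multi-feature classifier is optimistic
even under the null, so the observed AUC is referred to a null
distribution built the same way: for each of B draws the stage labels
are shuffled uniformly, the logistic coefficients are relearned from
scratch on the shuffled labels, and the in-sample empirical AUC against
those shuffled labels is recorded.  The empirical p-value uses the
add-one convention (1 + #{null >= observed}) / (B + 1), so it is never
exactly zero at finite B.

Permutations are drawn independently (not guaranteed distinct; with
cohort-scale n collisions are negligible).  Because predictor
standardization depends only on the expression matrix, each refit
reuses the standardized design; permuted fits that fail to converge
(label shuffles can separate) keep their final-iteration AUC and are
counted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classifier import _irls, _mann_whitney_auc
from .datatypes import ExpressionMatrix, PermutationResult, ValidationError

logger = logging.getLogger(__name__)


def empirical_p(null_values, observed: float) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (B + 1)."""
    null = np.asarray(list(null_values), dtype=float)
    if null.size == 0:
        raise ValidationError("empirical_p needs a non-empty null sample")
    return float((1 + int((null >= observed).sum())) / (null.size + 1))


def permutation_null(
    X: ExpressionMatrix | pd.DataFrame | np.ndarray,
    y,
    B: int,
    seed: int,
) -> PermutationResult:
    """Permutation null of the in-sample AUC with relearned coefficients.

    ``X`` is features x samples; ``y`` the binary stage labels
    (1 = stage II/III).  Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValidationError("B must be at least 1")
    if isinstance(X, ExpressionMatrix):
        mat = X.values.to_numpy(dtype=float)
    elif isinstance(X, pd.DataFrame):
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("y must contain both classes")
    if mat.shape[1] != len(y):
        raise ValidationError("X and y disagree on the number of samples")

    samples = mat.T
    means = samples.mean(axis=0)
    scales = samples.std(axis=0, ddof=0)
    scales = np.where(scales > 0, scales, 1.0)
    design = np.column_stack([np.ones(len(y)), (samples - means) / scales])

    def fit_auc(labels: np.ndarray) -> tuple[float, bool]:
        beta, converged, _ = _irls(design, labels)
        eta = design @ beta
        return _mann_whitney_auc(eta, labels.astype(int)), converged

    observed_auc, _ = fit_auc(y)
    rng = np.random.default_rng(seed)
    null_aucs = np.empty(B)
    n_nonconv = 0
    for b in range(B):
        perm = rng.permutation(y)
        auc_b, conv = fit_auc(perm)
        null_aucs[b] = auc_b
        if not conv:
            n_nonconv += 1
    if n_nonconv:
        logger.info(
            "permutation_null: %d of %d permuted refits did not converge "
            "(final-iteration AUC kept)",
            n_nonconv,
            B,
        )
    return PermutationResult(
        null_aucs=null_aucs,
        B=B,
        observed_auc=observed_auc,
        p_empirical=empirical_p(null_aucs, observed_auc),
        seed=seed,
        n_nonconverged=n_nonconv,
    )
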
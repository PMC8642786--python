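"""Two-group negative-binomial Wald test with Benjamini-Hochberg FDR.

Each miRNA's counts are modelled as negative binomial with mean
``mu_gj = s_j * m_g(j)`` (size factor times a stage-group mean) and
variance ``mu + alpha * mu^2``.  The dispersion ``alpha`` is estimated
per feature by the method of moments on depth-corrected counts, with a
small floor for under-dispersed features; group means are then fitted
by maximum likelihood at that fixed dispersion (a one-dimensional
Newton solve per group, since the two-group log-link model is
orthogonal in the group log-means).  The Wald statistic is the log
fold change divided by its standard error from the Fisher information,
referred to a standard normal.

The discovery filter keeps features with a BH-adjusted q-value below
``fdr_max`` and an absolute log2 fold change above ``log2(min_fold)``
(both strict), with positive log2 fold change meaning overexpression in
stage II/III.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    STAGE_EARLY,
    STAGE_LATE,
    CountMatrix,
    DETable,
    SampleAnnotation,
    SizeFactors,
    ValidationError,
)

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


def estimate_dispersion(counts_for_feature, sf: SizeFactors | np.ndarray) -> float:
    """Moment estimator of the NB dispersion for one feature.

    On depth-corrected counts ``z = y / s`` the estimator is
    ``(var(z) - mean(z)) / mean(z)^2`` floored at 1e-8, so Poisson-like
    or constant features land on the floor.  Requires at least 4
    samples.
    """
    y = np.asarray(counts_for_feature, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise ValidationError("dispersion estimation needs >= 4 samples")
    s = sf.factors.to_numpy() if isinstance(sf, SizeFactors) else np.asarray(sf, float)
    if len(s) != len(y):
        raise ValidationError("size factor length must match sample count")
    z = y / s
    m = z.mean()
    if m <= 0:
        return DISPERSION_FLOOR
    alpha = (z.var(ddof=1) - m) / m**2
    return float(max(alpha, DISPERSION_FLOOR))


def _moment_dispersions(mat: np.ndarray, s: np.ndarray) -> np.ndarray:
    z = mat / s[np.newaxis, :]
    m = z.mean(axis=1)
    v = z.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def _fit_group_means(
    mat: np.ndarray, s: np.ndarray, alpha: np.ndarray, max_iter: int = 50
) -> np.ndarray:
    """ML estimate of the depth-corrected group mean, per feature.

    Solves, per feature, the NB score equation
    ``sum_j (y_j - s_j m) / (1 + alpha s_j m) = 0`` by Newton iteration
    on beta = log(m).  The score is strictly decreasing in beta so the
    root is unique.  Features with all-zero counts get mean 0.
    """
    z_mean = (mat / s[np.newaxis, :]).mean(axis=1)
    beta = np.log(np.maximum(z_mean, 1e-300))
    active = z_mean > 0
    for _ in range(max_iter):
        if not active.any():
            break
        m = np.exp(beta[active])[:, np.newaxis]
        mu = m * s[np.newaxis, :]
        a = alpha[active][:, np.newaxis]
        denom = 1.0 + a * mu
        score = ((mat[active] - mu) / denom).sum(axis=1)
        dscore = -(mu * (1.0 + a * mat[active]) / denom**2).sum(axis=1)
        step = np.clip(score / dscore, -5.0, 5.0)
        beta_active = beta[active] - step
        done = np.abs(step) < 1e-12
        beta[active] = beta_active
        still = np.zeros_like(active)
        still[np.flatnonzero(active)[~done]] = True
        active = still
    out = np.exp(beta)
    out[z_mean == 0] = 0.0
    return out


def _group_information(m: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fisher information for the group log-mean: sum_j mu_j / (1 + alpha mu_j)."""
    mu = m[:, np.newaxis] * s[np.newaxis, :]
    return (mu / (1.0 + alpha[:, np.newaxis] * mu)).sum(axis=1)


def nb_wald_test(
    counts: CountMatrix,
    labels: SampleAnnotation,
    sf: SizeFactors,
    cohort_tag: str = "",
) -> DETable:
    """Per-feature NB Wald test of stage II/III vs stage I.

    Features with zero counts in every sample are excluded (with a
    logged notice).  Features with all-zero counts in exactly one stage
    group are kept: their log2 fold change and Wald statistic are
    computed after adding 0.5 to both depth-corrected group means (and
    evaluating the information at those shifted means), and the record
    is flagged ``zero_group``.
    """
    sample_ids = counts.sample_ids
    stages = labels.stages(sample_ids)
    if stages.isna().any():
        missing = list(stages.index[stages.isna()])[:5]
        raise ValidationError(f"samples missing from annotation: {missing}")
    groups = {lvl: (stages == lvl).to_numpy() for lvl in (STAGE_EARLY, STAGE_LATE)}
    for lvl, mask in groups.items():
        if mask.sum() < 2:
            raise ValidationError(f"stage group {lvl!r} has fewer than 2 samples")

    filtered, dropped = counts.drop_all_zero_features()
    if dropped:
        logger.info("nb_wald_test: excluded %d all-zero features", len(dropped))
    mat = filtered.values.to_numpy(dtype=float)
    s = sf.reindex(sample_ids)

    alpha = _moment_dispersions(mat, s)
    m_early = _fit_group_means(mat[:, groups[STAGE_EARLY]], s[groups[STAGE_EARLY]], alpha)
    m_late = _fit_group_means(mat[:, groups[STAGE_LATE]], s[groups[STAGE_LATE]], alpha)

    zero_group = (m_early == 0) | (m_late == 0)
    # Shifted means keep the fold change (and, for flagged features, the
    # Wald statistic) finite when one stage group is all zeros.
    me = np.where(zero_group, m_early + 0.5, m_early)
    ml = np.where(zero_group, m_late + 0.5, m_late)

    log2fc = np.log2(ml / me)
    info_early = _group_information(me, s[groups[STAGE_EARLY]], alpha)
    info_late = _group_information(ml, s[groups[STAGE_LATE]], alpha)
    se_ln = np.sqrt(1.0 / info_early + 1.0 / info_late)
    wald = np.log(ml / me) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(wald))
    q = np.asarray(bh_adjust(list(p)))
    mean_expr = (mat / s[np.newaxis, :]).mean(axis=1)

    frame = pd.DataFrame(
        {
            "log2fc": log2fc,
            "wald_stat": wald,
            "p_value": p,
            "q_value": q,
            "mean_expression": mean_expr,
            "zero_group": zero_group,
        },
        index=filtered.values.index,
    )
    return DETable(frame, cohort_tag=cohort_tag)


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the
    input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("bh_adjust needs a non-empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def filter_discovery(
    de: DETable, fdr_max: float = 0.05, min_fold: float = 1.5
) -> DETable:
    """Discovery-cohort filter: q < fdr_max and |log2fc| > log2(min_fold).

    Both inequalities are strict.  Either direction of change passes;
    the cross-cohort step later records which direction each hit has.
    """
    f = de.frame
    keep = (f["q_value"] < fdr_max) & (f["log2fc"].abs() > np.log2(min_fold))
    return DETable(f.loc[keep].copy(), cohort_tag=de.cohort_tag)
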
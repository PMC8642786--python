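"""Depth normalization and log transform of raw miRNA counts.

Sequencing depth varies by orders of magnitude between libraries, so raw
counts are first divided by a per-sample *size factor* estimated with
the median-of-ratios convention of the DESeq family: each sample's
factor is the median, over features detected in every sample, of the
ratio of its count to the feature's geometric mean across samples.
Factors are rescaled to geometric mean 1 so the overall count scale is
preserved.

Depth-corrected counts are then passed through a shifted-log transform,
``log2(count / s_j + pseudocount)``, which tempers the mean-variance
relationship of counts enough for the downstream logistic signature,
and is irrelevant to the Spearman screen (rank-invariant to any
monotone transform).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ExpressionMatrix, SizeFactors, ValidationError

logger = logging.getLogger(__name__)


def estimate_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only features with strictly positive counts in every sample enter
    the median (the geometric mean of a feature with any zero is zero
    and its ratios are undefined).

    Raises
    ------
    ValidationError
        If no feature is positive in all samples; callers should
        prefilter to a detected-everywhere feature subset first.
    """
    mat = counts.values.to_numpy(dtype=float)
    all_positive = np.all(mat > 0, axis=1)
    if not all_positive.any():
        raise ValidationError(
            "no feature has positive counts in every sample; "
            "prefilter low-coverage features before estimating size factors"
        )
    sub = mat[all_positive]
    geo_mean = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    raw = np.median(sub / geo_mean, axis=0)
    sf = raw / np.exp(np.mean(np.log(raw)))  # geometric mean 1
    return SizeFactors(pd.Series(sf, index=counts.values.columns))


def normalize_counts(
    counts: CountMatrix, sf: SizeFactors, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Shifted-log transform of depth-corrected counts.

    value_gj = log2(count_gj / s_j + pseudocount).  The pseudocount is
    recorded in the matrix's ``transform_tag``.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    s = sf.reindex(counts.sample_ids)  # KeyError on missing sample
    corrected = counts.values.to_numpy(dtype=float) / s[np.newaxis, :]
    values = pd.DataFrame(
        np.log2(corrected + pseudocount),
        index=counts.values.index,
        columns=counts.values.columns,
    )
    return ExpressionMatrix(values, transform_tag=f"log2(count/sf + {pseudocount:g})")


def prepare_counts(counts: CountMatrix) -> tuple[CountMatrix, SizeFactors]:
    """Drop all-zero features (with a logged notice) and estimate size factors."""
    filtered, dropped = counts.drop_all_zero_features()
    if dropped:
        logger.info("dropped %d features with zero counts in every sample", len(dropped))
    return filtered, estimate_size_factors(filtered)
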
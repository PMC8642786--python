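"""Target-map-constrained miRNA-mRNA anti-correlation screening.

miRNAs repress their targets post-transcriptionally, so a functional
miRNA-mRNA interaction should show up as an inverse association between
the miRNA's and the gene's expression across samples.  The screen is
constrained to experimentally supported edges from a curated target
map: candidate pairs are the map edges whose miRNA belongs to the
validated signature; each pair is scored by Spearman correlation over
the samples shared by the two matrices; Benjamini-Hochberg adjustment
is applied across all candidate pairs of one cohort's screen; and a
pair is significant when rho < 0 and q < 0.1 (both strict, defaults).
Pairs significant and negative in both cohorts form the concordant set.

Spearman p-values use the large-sample t approximation on n - 2
degrees of freedom; below 10 samples an exact permutation p-value is
used instead.  A flag allows unsigned screening for sensitivity
analyses.
"""

from __future__ import annotations

import logging
from itertools import permutations as _iter_permutations

import numpy as np

from .datatypes import (
    ExpressionMatrix,
    PairRecord,
    TargetMap,
    ValidatedSignature,
    ValidationError,
)
from .diff_expr import bh_adjust

logger = logging.getLogger(__name__)


def candidate_pairs(
    signature: ValidatedSignature | list[str], targets: TargetMap
) -> list[tuple[str, str]]:
    """Target-map edges whose miRNA belongs to the signature.

    Preserves the map's edge order; signature miRNAs with no edge in
    the map contribute nothing.
    """
    ids = set(signature.mirna_ids if isinstance(signature, ValidatedSignature) else signature)
    return [(m, g) for m, g in targets.edges if m in ids]


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho (small n only)."""
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    perms = np.array(list(_iter_permutations(range(n))))
    rhos = (ry_c[perms] @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_rho(x, y, method: str = "auto") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks; rho is the Pearson correlation of the
    rank vectors.  ``method`` is ``"auto"`` (exact permutation below 10
    samples, t approximation otherwise), ``"t"`` or ``"exact"``.
    """
    from scipy.stats import rankdata, t as t_dist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValidationError("Spearman correlation needs at least 4 samples")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("Spearman correlation undefined for a constant vector")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "auto":
        method = "exact" if n < 10 else "t"
    if method == "exact":
        p = _exact_permutation_p(rx, ry, rho)
    elif method == "t":
        rho_c = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
        tstat = rho_c * np.sqrt((n - 2) / (1.0 - rho_c**2))
        p = float(2.0 * t_dist.sf(abs(tstat), df=n - 2))
    else:
        raise ValidationError(f"unknown method {method!r}")
    return rho, min(p, 1.0)


def screen_pairs(
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    rho_max: float = 0.0,
    fdr_max: float = 0.1,
    cohort_tag: str = "",
    signed: bool = True,
) -> list[PairRecord]:
    """Score candidate pairs and keep the significant inverse ones.

    Correlations run over the samples shared by the two matrices (at
    least 4 required).  BH adjustment spans every candidate pair tested
    in this call.  Kept records satisfy rho < rho_max and q < fdr_max
    (strict); with ``signed=False`` the rho condition is waived.
    Pairs referencing a feature absent from either matrix are dropped
    with a logged notice.
    """
    shared = [s for s in mirna_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    if len(shared) < 4:
        raise ValidationError("screens need at least 4 shared samples")
    mi = mirna_expr.values[shared]
    mr = mrna_expr.values[shared]

    tested: list[tuple[str, str, float, float]] = []
    n_dropped = 0
    for mirna_id, gene_id in pairs:
        if mirna_id not in mi.index or gene_id not in mr.index:
            n_dropped += 1
            continue
        rho, p = spearman_rho(mi.loc[mirna_id].to_numpy(), mr.loc[gene_id].to_numpy())
        tested.append((mirna_id, gene_id, rho, p))
    if n_dropped:
        logger.info("screen_pairs: dropped %d pairs with absent features", n_dropped)
    if not tested:
        return []

    qs = bh_adjust([p for *_, p in tested])
    records = []
    for (mirna_id, gene_id, rho, p), q in zip(tested, qs):
        if q < fdr_max and (not signed or rho < rho_max):
            records.append(
                PairRecord(
                    mirna_id=mirna_id,
                    gene_id=gene_id,
                    rho=rho,
                    p_value=p,
                    q_value=q,
                    cohort_tag=cohort_tag,
                    n_samples=len(shared),
                )
            )
    return records


def concordant_pairs(
    screen_a: list[PairRecord], screen_b: list[PairRecord]
) -> list[tuple[str, str]]:
    """Pairs significant with negative rho in both cohorts.

    Sorted by the worse of the two q-values, ascending, so the most
    consistently supported interactions come first.
    """
    by_id_a = {r.pair_id: r for r in screen_a}
    by_id_b = {r.pair_id: r for r in screen_b}
    common = [
        pid
        for pid in by_id_a
        if pid in by_id_b and by_id_a[pid].rho < 0 and by_id_b[pid].rho < 0
    ]
    common.sort(key=lambda pid: (max(by_id_a[pid].q_value, by_id_b[pid].q_value), pid))
    return common
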
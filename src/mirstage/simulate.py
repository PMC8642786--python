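"""Synthetic two-cohort miRNA/mRNA data with a planted truth.

The generator emulates the structure the analysis assumes: two cohorts
of rectal-cancer-scale size (127 samples, roughly one quarter to one
third stage I), ~1426 miRNA features with negative-binomial counts over
log-normally spread library depths, a planted subset of miRNAs whose
stage II/III group mean is multiplied by a configured fold change, and
a continuous mRNA matrix in which planted target genes decrease
linearly in their regulating miRNA's log abundance.

Two random streams keep twin cohorts comparable: the *structural*
stream, seeded by ``config.seed`` alone, draws everything the cohorts
must share (baseline means, which miRNAs are planted, which pairs are
planted); the *sampling* stream, seeded by ``config.seed`` together
with the cohort label, draws the per-cohort noise.  Calling
``simulate_cohort`` twice with the same config and label is
bitwise-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    STAGE_EARLY,
    STAGE_LATE,
    ConfigurationError,
    CountMatrix,
    ExpressionMatrix,
    SampleAnnotation,
    TargetMap,
)

#: Fold changes (stage II/III over stage I) spanning the range reported
#: for validated stage-associated miRNAs in rectal cancer (~1.6 to 4.6).
DEFAULT_PLANTED_FOLD_CHANGES = (
    1.81, 1.66, 2.36, 2.53, 2.77, 4.59, 1.91, 1.84, 2.84, 2.27,
    1.91, 1.68, 1.76, 1.65, 3.12, 2.43, 1.58, 1.83, 1.65,
)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the study conditions the pipeline is meant for:
    127 samples per cohort with ~32% stage-I prevalence, 1426 miRNAs,
    19 planted miRNAs overexpressed in stage II/III, and 3 planted
    inverse miRNA-mRNA pairs.
    """

    seed: int
    n_samples_per_cohort: int = 127
    prevalence_stage1: float = 41 / 127
    n_mirna: int = 1426
    n_mrna: int = 2000
    n_planted_mirna: int = 19
    planted_fold_changes: tuple[float, ...] = DEFAULT_PLANTED_FOLD_CHANGES
    nb_dispersion: float = 0.2
    baseline_mean_log_range: tuple[float, float] = (1.6, 6.2)  # natural log of mean counts
    n_planted_pairs: int = 3
    pair_effect: float = -1.0  # slope of target mRNA on miRNA log2 abundance
    mrna_noise_sd: float = 1.0
    library_size_spread: float = 0.25  # log-normal sigma of per-sample depth

    def __post_init__(self) -> None:
        if self.n_samples_per_cohort <= 0 or self.n_mirna <= 0 or self.n_mrna <= 0:
            raise ConfigurationError("dimensions must be positive")
        if not 0.0 < self.prevalence_stage1 < 1.0:
            raise ConfigurationError("prevalence_stage1 must lie in (0, 1)")
        if not 0 <= self.n_planted_mirna <= self.n_mirna:
            raise ConfigurationError("n_planted_mirna must lie in [0, n_mirna]")
        # The default fold-change list may be longer than a reduced
        # n_planted_mirna; truncation keeps the two consistent.
        self.planted_fold_changes = tuple(self.planted_fold_changes)[: self.n_planted_mirna]
        if len(self.planted_fold_changes) != self.n_planted_mirna:
            raise ConfigurationError(
                "planted_fold_changes must have length n_planted_mirna"
            )
        if any(fc <= 0 for fc in self.planted_fold_changes):
            raise ConfigurationError("fold changes must be positive")
        if self.n_planted_pairs < 0 or self.n_planted_pairs > self.n_mrna:
            raise ConfigurationError("n_planted_pairs out of range")
        if self.n_planted_pairs > 0 and self.pair_effect >= 0:
            raise ConfigurationError("pair_effect must be negative (inverse pairs)")
        if self.nb_dispersion <= 0 or self.library_size_spread < 0:
            raise ConfigurationError("nb_dispersion must be > 0 and spread >= 0")
        n1 = round(self.prevalence_stage1 * self.n_samples_per_cohort)
        if n1 < 2 or self.n_samples_per_cohort - n1 < 2:
            raise ConfigurationError(
                "prevalence yields a stage group with fewer than 2 samples"
            )


@dataclass
class TruthSet:
    """The planted structure of a simulated cohort pair.

    ``planted_mirna_log2fc`` maps each planted miRNA id to its true
    log2 fold change (stage II/III over I); ``planted_pairs`` lists the
    (miRNA, mRNA) interactions wired into the mRNA generator.  The full
    feature universes are carried along so decoy target edges can be
    drawn from non-planted combinations.
    """

    planted_mirna_log2fc: dict[str, float]
    planted_pairs: list[tuple[str, str]]
    mirna_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        planted = set(self.planted_mirna_log2fc)
        for m, g in self.planted_pairs:
            if m not in planted:
                raise ConfigurationError(
                    f"planted pair references non-planted miRNA {m!r}"
                )

    @property
    def planted_mirna_ids(self) -> set[str]:
        return set(self.planted_mirna_log2fc)


def _cohort_rng(seed: int, cohort_label: str) -> np.random.Generator:
    tag = zlib.crc32(cohort_label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def _structure(config: SimulationConfig):
    """Cohort-shared structure drawn from the seed alone."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed]))
    mirna_ids = [f"miR-sim-{i + 1:04d}" for i in range(config.n_mirna)]
    gene_ids = [f"GENE{i + 1:04d}" for i in range(config.n_mrna)]
    lo, hi = config.baseline_mean_log_range
    base_log_mean = rng.uniform(lo, hi, size=config.n_mirna)
    planted_idx = rng.choice(config.n_mirna, size=config.n_planted_mirna, replace=False)
    log2fc = np.zeros(config.n_mirna)
    log2fc[planted_idx] = np.log2(np.asarray(config.planted_fold_changes))
    pair_mirna_idx = (
        rng.choice(planted_idx, size=config.n_planted_pairs, replace=False)
        if config.n_planted_pairs
        else np.array([], dtype=int)
    )
    pair_gene_idx = (
        rng.choice(config.n_mrna, size=config.n_planted_pairs, replace=False)
        if config.n_planted_pairs
        else np.array([], dtype=int)
    )
    mrna_base = rng.uniform(4.0, 12.0, size=config.n_mrna)
    return mirna_ids, gene_ids, base_log_mean, planted_idx, log2fc, pair_mirna_idx, pair_gene_idx, mrna_base


def simulate_cohort(
    config: SimulationConfig, cohort_label: str
) -> tuple[CountMatrix, ExpressionMatrix, SampleAnnotation, TruthSet]:
    """Generate one cohort (counts, mRNA, labels) plus its planted truth.

    Counts are negative binomial with mean ``depth_j * m_i * fc_i^[late]``
    and variance ``mu + alpha mu^2``; planted fold changes act
    multiplicatively in the stage II/III group.  Planted target genes
    follow ``base - |pair_effect| * log2(count/depth + 1) + noise``;
    all other genes are Gaussian around their baseline.  Two calls with
    identical config and label return identical objects.
    """
    (
        mirna_ids,
        gene_ids,
        base_log_mean,
        planted_idx,
        log2fc,
        pair_mirna_idx,
        pair_gene_idx,
        mrna_base,
    ) = _structure(config)
    rng = _cohort_rng(config.seed, cohort_label)

    n = config.n_samples_per_cohort
    n1 = round(config.prevalence_stage1 * n)
    stages = np.array([STAGE_EARLY] * n1 + [STAGE_LATE] * (n - n1))
    rng.shuffle(stages)
    sample_ids = [f"{cohort_label}-s{j + 1:03d}" for j in range(n)]

    depth = np.exp(rng.normal(0.0, config.library_size_spread, size=n))
    late = (stages == STAGE_LATE).astype(float)
    mu = (
        np.exp(base_log_mean)[:, np.newaxis]
        * np.power(2.0, np.outer(log2fc, late))
        * depth[np.newaxis, :]
    )
    size = 1.0 / config.nb_dispersion  # NB "number of failures" parameter
    counts = rng.negative_binomial(size, size / (size + mu))

    mrna = mrna_base[:, np.newaxis] + rng.normal(
        0.0, config.mrna_noise_sd, size=(config.n_mrna, n)
    )
    mirna_log = np.log2(counts / depth[np.newaxis, :] + 1.0)
    for mi, gi in zip(pair_mirna_idx, pair_gene_idx):
        z = mirna_log[mi]
        mrna[gi] = (
            mrna_base[gi]
            + config.pair_effect * (z - z.mean())
            + rng.normal(0.0, config.mrna_noise_sd, size=n)
        )

    count_matrix = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=mirna_ids, columns=sample_ids)
    )
    mrna_matrix = ExpressionMatrix(
        pd.DataFrame(mrna, index=gene_ids, columns=sample_ids),
        transform_tag="synthetic_lognormal_mrna",
    )
    annotation = SampleAnnotation(
        pd.DataFrame(
            {"cohort": cohort_label, "stage": stages},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = TruthSet(
        planted_mirna_log2fc={
            mirna_ids[i]: float(log2fc[i]) for i in sorted(planted_idx)
        },
        planted_pairs=[
            (mirna_ids[mi], gene_ids[gi]) for mi, gi in zip(pair_mirna_idx, pair_gene_idx)
        ],
        mirna_ids=mirna_ids,
        gene_ids=gene_ids,
    )
    return count_matrix, mrna_matrix, annotation, truth


def simulate_target_map(
    truth: TruthSet, n_decoy_edges: int, seed: int
) -> TargetMap:
    """Toy curated target map: every planted pair plus random decoys.

    Decoy edges are non-planted (miRNA, gene) combinations.  When the
    truth contains planted miRNAs, decoy miRNAs are drawn from the
    planted set — the stringent case, where decoys compete inside the
    screen — otherwise from all miRNAs.  Requesting more decoys than
    there are available combinations raises.
    """
    if n_decoy_edges < 0:
        raise ConfigurationError("n_decoy_edges must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A26]))
    planted = set(truth.planted_pairs)
    mirna_pool = sorted(truth.planted_mirna_ids) or list(truth.mirna_ids)
    gene_pool = list(truth.gene_ids)
    if not mirna_pool or not gene_pool:
        if n_decoy_edges > 0:
            raise ConfigurationError("no feature universe available for decoys")
        return TargetMap(list(truth.planted_pairs), provenance="synthetic")
    n_combos = len(mirna_pool) * len(gene_pool) - len(planted)
    if n_decoy_edges > n_combos:
        raise ConfigurationError(
            f"requested {n_decoy_edges} decoys but only {n_combos} "
            "non-planted combinations exist"
        )
    decoys: list[tuple[str, str]] = []
    chosen = set(planted)
    while len(decoys) < n_decoy_edges:
        m = mirna_pool[rng.integers(len(mirna_pool))]
        g = gene_pool[rng.integers(len(gene_pool))]
        if (m, g) not in chosen:
            chosen.add((m, g))
            decoys.append((m, g))
    return TargetMap(list(truth.planted_pairs) + decoys, provenance="synthetic")
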
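"""Typed containers shared across the pipeline stages.

Expression matrices are thin wrappers around pandas DataFrames laid out
features x samples; the wrappers enforce the integrity rules the
downstream statistics assume (unique identifiers, non-negative integer
counts, finite expression values).  Result objects are plain dataclasses.

Stage labels are serialized as ``"I"`` (early) and ``"II_III"`` (locally
advanced); the locally advanced group is the positive class everywhere,
so positive log2 fold changes mean *higher in stage II/III*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGE_EARLY = "I"
STAGE_LATE = "II_III"
VALID_STAGES = (STAGE_EARLY, STAGE_LATE)


class MirstageError(Exception):
    """Base class for all package errors."""


class ValidationError(MirstageError, ValueError):
    """An input object violates its structural contract."""


class ConfigurationError(MirstageError, ValueError):
    """A configuration value is out of its admissible range."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class CountMatrix:
    """Raw miRNA counts, features x samples.

    ``values`` must hold non-negative integers; feature ids (index) and
    sample ids (columns) must be unique.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise ValidationError("CountMatrix.values must be a DataFrame")
        _check_unique(v.index, "feature ids")
        _check_unique(v.columns, "sample ids")
        arr = v.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise ValidationError("counts must be finite integers")
            self.values = v.astype(np.int64)
            arr = self.values.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def drop_all_zero_features(self) -> tuple["CountMatrix", list[str]]:
        """Remove features with zero counts in every sample.

        Returns the filtered matrix and the list of dropped feature ids.
        """
        keep = self.values.sum(axis=1) > 0
        dropped = list(self.values.index[~keep])
        return CountMatrix(self.values.loc[keep]), dropped


@dataclass
class ExpressionMatrix:
    """Continuous expression values, features x samples.

    ``transform_tag`` records how the values were produced (e.g. the
    pseudocount of a shifted-log transform, or ``"external"`` for a
    pre-normalized matrix supplied by the user).
    """

    values: pd.DataFrame
    transform_tag: str = "external"

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise ValidationError("ExpressionMatrix.values must be a DataFrame")
        _check_unique(v.index, "feature ids")
        _check_unique(v.columns, "sample ids")
        arr = v.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        self.values = v.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SizeFactors:
    """Per-sample depth-normalization scalars.

    All factors are positive and their geometric mean is 1, so the
    normalization rescales depth without changing the overall count
    scale.
    """

    factors: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.factors, dtype=float)
        _check_unique(s.index, "sample ids")
        if (s <= 0).any() or not np.all(np.isfinite(s)):
            raise ValidationError("size factors must be positive and finite")
        gm = float(np.exp(np.mean(np.log(s.to_numpy()))))
        if abs(gm - 1.0) > 1e-9:
            raise ValidationError(
                f"size factors must have geometric mean 1 (got {gm:.6g})"
            )
        self.factors = s

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])

    def reindex(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.factors.index]
        if missing:
            raise KeyError(f"no size factor for samples: {missing[:5]}")
        return self.factors.reindex(sample_ids).to_numpy()


@dataclass
class SampleAnnotation:
    """Sample metadata: cohort of origin and binary stage label."""

    frame: pd.DataFrame  # index: sample_id; columns: cohort, stage

    def __post_init__(self) -> None:
        f = self.frame
        if not {"cohort", "stage"}.issubset(f.columns):
            raise ValidationError("annotation needs 'cohort' and 'stage' columns")
        _check_unique(f.index, "sample ids")
        bad = sorted(set(f["stage"]) - set(VALID_STAGES))
        if bad:
            raise ValidationError(
                f"unknown stage labels {bad}; allowed values are {list(VALID_STAGES)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def stages(self, sample_ids=None) -> pd.Series:
        s = self.frame["stage"]
        return s if sample_ids is None else s.reindex(sample_ids)

    def binary_labels(self, sample_ids=None) -> np.ndarray:
        """1 for stage II/III (positive class), 0 for stage I."""
        return (self.stages(sample_ids) == STAGE_LATE).to_numpy(dtype=int)

    def group_sizes(self) -> dict[str, int]:
        return self.frame["stage"].value_counts().to_dict()


@dataclass
class DETable:
    """Per-feature differential-expression results for one cohort.

    Columns of ``frame`` (indexed by feature id): ``log2fc`` (stage
    II/III over stage I), ``wald_stat``, ``p_value``, ``q_value``
    (Benjamini-Hochberg over the features in this table),
    ``mean_expression`` and a ``zero_group`` flag marking features where
    one stage group had no counts at all (their fold change uses a +0.5
    mean shift to stay finite).
    """

    frame: pd.DataFrame
    cohort_tag: str = ""

    REQUIRED = ("log2fc", "wald_stat", "p_value", "q_value", "mean_expression")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"DETable missing columns: {missing}")
        _check_unique(self.frame.index, "feature ids")
        if "zero_group" not in self.frame.columns:
            self.frame = self.frame.assign(zero_group=False)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TargetMap:
    """Directed miRNA -> target-gene edges (mature miRNA ids only)."""

    edges: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        edges = [(str(m), str(g)) for m, g in self.edges]
        if len(set(edges)) != len(edges):
            raise ValidationError("target map contains duplicate edges")
        self.edges = edges

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return tuple(edge) in set(self.edges)

    @property
    def mirna_ids(self) -> set[str]:
        return {m for m, _ in self.edges}

    def targets_of(self, mirna_id: str) -> list[str]:
        return [g for m, g in self.edges if m == mirna_id]


@dataclass
class NameMap:
    """Precursor -> mature miRNA name mapping with case-insensitive lookup.

    A precursor hairpin (e.g. ``mir-31``) yields up to two mature arms
    (``miR-31-5p`` and ``miR-31-3p``); datasets quantified at the
    precursor level must be expanded to mature names before joining with
    mature-level tables or target databases.  Every mature id belongs to
    exactly one precursor.
    """

    precursor_to_mature: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        lowered: dict[str, tuple[str, ...]] = {}
        for prec, arms in self.precursor_to_mature.items():
            arms = tuple(arms)
            for arm in arms:
                key = arm.lower()
                if key in seen and seen[key] != prec:
                    raise ValidationError(
                        f"mature id {arm!r} maps to both {seen[key]!r} and {prec!r}"
                    )
                seen[key] = prec
            lowered[prec.lower()] = arms
        self._lower = lowered
        self._mature_ids = set(seen)

    @classmethod
    def identity(cls) -> "NameMap":
        return cls({})

    def lookup(self, name: str) -> tuple[str, ...] | None:
        """Mature arms for ``name`` if it is a known precursor, else None."""
        return self._lower.get(name.lower())

    def is_mature(self, name: str) -> bool:
        return name.lower() in self._mature_ids


@dataclass
class ValidatedSignature:
    """Discovery hits confirmed in the validation cohort.

    ``frame`` is ordered by discovery q-value (ascending) and indexed by
    mature miRNA id, with the discovery statistics (fold change, q) and
    validation statistics (fold change, nominal p) side by side.
    ``direction`` is +1 for miRNAs higher in stage II/III, -1 for higher
    in stage I.
    """

    frame: pd.DataFrame

    COLUMNS = (
        "discovery_log2fc",
        "discovery_fold_change",
        "discovery_q",
        "validation_log2fc",
        "validation_fold_change",
        "validation_p",
        "direction",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"ValidatedSignature missing columns: {missing}")
        _check_unique(self.frame.index, "signature miRNA ids")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_up_late(self) -> int:
        return int((self.frame["direction"] > 0).sum())

    @property
    def n_up_early(self) -> int:
        return int((self.frame["direction"] < 0).sum())


@dataclass
class SignatureModel:
    """Fitted logistic signature over a named miRNA set.

    Coefficients are stored on the internal z-score scale
    (``coefficients``) together with the standardization parameters, and
    exposed on the original expression scale via ``coefficients_raw`` /
    ``intercept_raw``.
    """

    intercept: float
    coefficients: np.ndarray
    feature_order: list[str]
    feature_means: np.ndarray
    feature_scales: np.ndarray
    converged: bool
    n_iterations: int
    separation_warning: bool = False

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.feature_order),):
            raise ValidationError("coefficient count must match feature_order")
        if self.converged and not (
            np.isfinite(self.intercept) and np.all(np.isfinite(self.coefficients))
        ):
            raise ValidationError("converged model must have finite coefficients")

    @property
    def coefficients_raw(self) -> np.ndarray:
        return self.coefficients / self.feature_scales

    @property
    def intercept_raw(self) -> float:
        return float(
            self.intercept - np.sum(self.coefficients * self.feature_means / self.feature_scales)
        )


@dataclass
class ROCResult:
    """Empirical ROC curve with Mann-Whitney AUC and DeLong CI."""

    auc: float
    ci_low: float
    ci_high: float
    curve: np.ndarray  # (k, 2) array of (fpr, tpr), from (0,0) to (1,1)
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError("AUC must lie in [0, 1]")
        if not (self.ci_low <= self.auc + 1e-12 and self.auc - 1e-12 <= self.ci_high):
            raise ValidationError("CI must bracket the AUC")
        fpr, tpr = self.curve[:, 0], self.curve[:, 1]
        if np.any(np.diff(fpr) < -1e-12) or np.any(np.diff(tpr) < -1e-12):
            raise ValidationError("ROC curve coordinates must be non-decreasing")


@dataclass
class CalibrationResult:
    """Calibration of predicted probabilities against observed outcomes."""

    intercept: float
    slope: float
    brier: float
    curve: np.ndarray  # (n_bins, 2): (mean predicted, observed event rate)

    def __post_init__(self) -> None:
        if not (0.0 <= self.brier <= 1.0):
            raise ValidationError("Brier score must lie in [0, 1]")
        self.curve = np.asarray(self.curve, dtype=float)


@dataclass
class PermutationResult:
    """Relearned-classifier permutation null for the in-sample AUC."""

    null_aucs: np.ndarray
    B: int
    observed_auc: float
    p_empirical: float
    seed: int
    n_nonconverged: int = 0

    def __post_init__(self) -> None:
        self.null_aucs = np.asarray(self.null_aucs, dtype=float)
        if len(self.null_aucs) != self.B:
            raise ValidationError("null_aucs must have length B")
        if self.null_aucs.size and (
            self.null_aucs.min() < 0 or self.null_aucs.max() > 1
        ):
            raise ValidationError("null AUC values must lie in [0, 1]")
        if not (0.0 < self.p_empirical <= 1.0):
            raise ValidationError("empirical p must lie in (0, 1]")


@dataclass
class PairRecord:
    """One miRNA-mRNA candidate pair scored by Spearman correlation."""

    mirna_id: str
    gene_id: str
    rho: float
    p_value: float
    q_value: float
    cohort_tag: str
    n_samples: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValidationError("Spearman rho must lie in [-1, 1]")

    @property
    def pair_id(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


def pair_records_to_frame(records: list[PairRecord]) -> pd.DataFrame:
    """Tabular view of a pair screen, one row per candidate pair."""
    return pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "gene_id": r.gene_id,
                "rho": r.rho,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "cohort_tag": r.cohort_tag,
                "n_samples": r.n_samples,
            }
            for r in records
        ]
    )
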
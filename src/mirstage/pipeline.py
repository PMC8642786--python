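"""End-to-end orchestration of the two-cohort analysis.

The pipeline runs: depth normalization -> discovery-cohort NB Wald DE
-> FDR + fold-change filter -> validation-cohort DE (precursor names
mapped to mature arms) -> direction-consistent validation -> logistic
signature fit, empirical ROC, calibration and relearned-classifier
permutation null per cohort -> target-map-constrained anti-correlation
screen per cohort -> cross-cohort concordant pairs.  Every stage's
output is written as TSV/JSON next to a single ``summary.json``, and a
fixed seed reproduces the run bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io
from .classifier import evaluate_signature
from .cross_cohort import filter_validation, map_precursor_to_mature
from .datatypes import (
    ConfigurationError,
    MirstageError,
    NameMap,
    pair_records_to_frame,
)
from .diff_expr import filter_discovery, nb_wald_test
from .integration import candidate_pairs, concordant_pairs, screen_pairs
from .permutation import permutation_null
from .preprocess import normalize_counts, prepare_counts

logger = logging.getLogger(__name__)


@dataclass
class CohortPaths:
    """Input files of one cohort."""

    counts: str
    mrna: str
    annotation: str


@dataclass
class PipelineConfig:
    """All inputs and tuning constants of one pipeline run.

    The thresholds default to the analysis conventions the pipeline
    encodes: discovery FDR < 0.05 with fold change > 1.5, validation at
    nominal two-sided p < 0.05 in the same direction, pair screening at
    Spearman rho < 0 with FDR < 0.1, and B = 10000 label permutations
    for the AUC null.
    """

    discovery: CohortPaths
    validation: CohortPaths
    target_map: str
    output_dir: str
    name_map: str | None = None
    fdr_discovery: float = 0.05
    min_fold: float = 1.5
    alpha_validation: float = 0.05
    rho_max: float = 0.0
    fdr_pairs: float = 0.1
    pseudocount: float = 1.0
    B: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.discovery, dict):
            self.discovery = CohortPaths(**self.discovery)
        if isinstance(self.validation, dict):
            self.validation = CohortPaths(**self.validation)
        for name in ("fdr_discovery", "alpha_validation", "fdr_pairs"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1]")
        if self.min_fold < 1.0:
            raise ConfigurationError("min_fold must be >= 1")
        if self.B < 1:
            raise ConfigurationError("B must be >= 1")

    @classmethod
    def from_json(cls, path, **overrides) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


def _guard(stage: str, fn, *args, **kwargs):
    """Run one pipeline stage, attributing any failure to its name."""
    try:
        return fn(*args, **kwargs)
    except MirstageError as exc:
        raise MirstageError(f"stage {stage!r} failed: {exc}") from exc


def _evaluate_cohort(expr, annotation, signature_ids, B, seed, tag):
    y = annotation.binary_labels(expr.sample_ids)
    model, roc, cal, probs = evaluate_signature(expr, y, signature_ids)
    sub = expr.values.loc[[f for f in signature_ids if f in expr.values.index]]
    perm = permutation_null(sub, y, B=B, seed=seed)
    logger.info(
        "%s: AUC %.3f (%.3f-%.3f), permutation p %.4g (B=%d)",
        tag, roc.auc, roc.ci_low, roc.ci_high, perm.p_empirical, perm.B,
    )
    return {
        "model": model,
        "roc": roc,
        "calibration": cal,
        "probs": probs,
        "permutation": perm,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole analysis and write its artifacts.

    Returns the summary dictionary that is also written to
    ``<output_dir>/summary.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "thresholds: discovery FDR < %g, fold > %g; validation p < %g; "
        "pairs rho < %g, FDR < %g; B = %d; seed = %d",
        config.fdr_discovery, config.min_fold, config.alpha_validation,
        config.rho_max, config.fdr_pairs, config.B, config.seed,
    )

    # --- load ---------------------------------------------------------
    disc_counts = _guard("load", io.read_count_matrix, config.discovery.counts)
    disc_mrna = _guard("load", io.read_expression_matrix, config.discovery.mrna)
    disc_ann = _guard("load", io.read_annotation, config.discovery.annotation)
    val_counts = _guard("load", io.read_count_matrix, config.validation.counts)
    val_mrna = _guard("load", io.read_expression_matrix, config.validation.mrna)
    val_ann = _guard("load", io.read_annotation, config.validation.annotation)
    targets = _guard("load", io.read_target_map, config.target_map)
    name_map = (
        _guard("load", io.read_name_map, config.name_map)
        if config.name_map
        else NameMap.identity()
    )

    # --- normalize ----------------------------------------------------
    disc_counts, disc_sf = _guard("normalize", prepare_counts, disc_counts)
    val_counts, val_sf = _guard("normalize", prepare_counts, val_counts)
    disc_expr = normalize_counts(disc_counts, disc_sf, config.pseudocount)
    val_expr = normalize_counts(val_counts, val_sf, config.pseudocount)

    # --- differential expression + cross-cohort validation ------------
    de_disc = _guard(
        "de_discovery", nb_wald_test, disc_counts, disc_ann, disc_sf, cohort_tag="discovery"
    )
    io.write_de_table(de_disc, out / "de_discovery.tsv")
    hits = filter_discovery(de_disc, config.fdr_discovery, config.min_fold)
    de_val = _guard(
        "de_validation", nb_wald_test, val_counts, val_ann, val_sf, cohort_tag="validation"
    )
    de_val = map_precursor_to_mature(de_val, name_map)
    io.write_de_table(de_val, out / "de_validation.tsv")
    signature = filter_validation(hits, de_val, config.alpha_validation)
    io.write_signature(signature, out / "signature.tsv")

    summary: dict = {
        "seed": config.seed,
        "B": config.B,
        "thresholds": {
            "fdr_discovery": config.fdr_discovery,
            "min_fold": config.min_fold,
            "alpha_validation": config.alpha_validation,
            "rho_max": config.rho_max,
            "fdr_pairs": config.fdr_pairs,
        },
        "n_features_discovery": len(de_disc),
        "n_discovery_hits": len(hits),
        "signature": signature.mirna_ids,
        "n_signature_up_late": signature.n_up_late,
        "n_signature_up_early": signature.n_up_early,
    }

    if len(signature) == 0:
        logger.info("empty validated signature; downstream stages skipped")
        summary.update({"cohorts": {}, "concordant_pairs": []})
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8"
        )
        return summary

    # --- signature evaluation + permutation null ----------------------
    sig_ids = signature.mirna_ids
    cohorts = {}
    for tag, expr, ann in (
        ("discovery", disc_expr, disc_ann),
        ("validation", val_expr, val_ann),
    ):
        res = _evaluate_cohort(expr, ann, sig_ids, config.B, config.seed, tag)
        np.savetxt(out / f"null_auc_{tag}.tsv", res["permutation"].null_aucs)
        cohorts[tag] = {
            "auc": res["roc"].auc,
            "auc_ci": [res["roc"].ci_low, res["roc"].ci_high],
            "p_permutation": res["permutation"].p_empirical,
            "observed_auc_refit": res["permutation"].observed_auc,
            "brier": res["calibration"].brier,
            "calibration_intercept": res["calibration"].intercept,
            "calibration_slope": res["calibration"].slope,
            "n_pos": res["roc"].n_pos,
            "n_neg": res["roc"].n_neg,
        }
    summary["cohorts"] = cohorts

    # --- miRNA-mRNA integration ---------------------------------------
    pairs = candidate_pairs(signature, targets)
    screens = {}
    for tag, mirna_expr, mrna_expr in (
        ("discovery", disc_expr, disc_mrna),
        ("validation", val_expr, val_mrna),
    ):
        screen = screen_pairs(
            mirna_expr, mrna_expr, pairs,
            rho_max=config.rho_max, fdr_max=config.fdr_pairs, cohort_tag=tag,
        )
        pair_records_to_frame(screen).to_csv(
            out / f"pairs_{tag}.tsv", sep="\t", index=False
        )
        screens[tag] = screen
    concordant = concordant_pairs(screens["discovery"], screens["validation"])
    summary["n_candidate_pairs"] = len(pairs)
    summary["n_pairs_discovery"] = len(screens["discovery"])
    summary["n_pairs_validation"] = len(screens["validation"])
    summary["concordant_pairs"] = [list(p) for p in concordant]

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8"
    )
    return summary


def simulate_twin_cohort_inputs(
    config, out_dir, n_decoy_edges: int = 30
) -> PipelineConfig:
    """Write a complete synthetic two-cohort input set and its config.

    Generates twin cohorts sharing planted structure (``config`` is a
    :class:`~mirstage.simulate.SimulationConfig`), a toy target map and
    the truth JSON, and returns a ready-to-run :class:`PipelineConfig`.
    """
    from .simulate import simulate_cohort, simulate_target_map

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    truth = None
    for tag in ("discovery", "validation"):
        counts, mrna, ann, truth = simulate_cohort(config, tag)
        io.write_matrix(counts, out / f"{tag}_mirna_counts.tsv")
        io.write_matrix(mrna, out / f"{tag}_mrna.tsv")
        io.write_annotation(ann, out / f"{tag}_annotation.tsv")
        paths[tag] = CohortPaths(
            counts=str(out / f"{tag}_mirna_counts.tsv"),
            mrna=str(out / f"{tag}_mrna.tsv"),
            annotation=str(out / f"{tag}_annotation.tsv"),
        )
    targets = simulate_target_map(truth, n_decoy_edges=n_decoy_edges, seed=config.seed)
    io.write_target_map(targets, out / "target_map.tsv")
    io.write_truth(truth, out / "truth.json")
    pipeline_config = PipelineConfig(
        discovery=paths["discovery"],
        validation=paths["validation"],
        target_map=str(out / "target_map.tsv"),
        output_dir=str(out / "results"),
        seed=config.seed,
    )
    (out / "config.json").write_text(
        json.dumps(asdict(pipeline_config), indent=1), encoding="utf-8"
    )
    return pipeline_config
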
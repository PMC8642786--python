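"""Readers and writers for the pipeline's plain-text formats.

All tabular files are UTF-8 TSV without quoting:

* count / expression matrices: header ``feature_id<TAB>sample...``,
  one feature per row;
* sample annotation: columns ``sample_id``, ``cohort``, ``stage`` with
  stage in {I, II_III};
* target map: columns ``mirna_id``, ``gene_id`` (a minimal
  miRTarBase-like dialect; ``read_mirtarbase_export`` ingests the real
  export's ``miRNA`` / ``Target Gene`` columns);
* name map: columns ``precursor_id``, ``mature_id`` (one arm per row).

Readers validate as they parse and report offending line/column so a
malformed cell is locatable in the source file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    VALID_STAGES,
    CountMatrix,
    DETable,
    ExpressionMatrix,
    NameMap,
    SampleAnnotation,
    TargetMap,
    ValidatedSignature,
    ValidationError,
)
from .simulate import TruthSet


class ParseError(ValidationError):
    """A file failed to parse; the message names the line and column."""


def _read_matrix_rows(path: Path) -> tuple[list[str], list[str], list[list[str]]]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        if len(cols) < 2:
            raise ParseError(f"{path}: line 1: expected tab-separated header")
        sample_ids = cols[1:]
        feature_ids: list[str] = []
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(cols)} fields, got {len(parts)}"
                )
            feature_ids.append(parts[0])
            rows.append(parts[1:])
    return sample_ids, feature_ids, rows


def read_count_matrix(path) -> CountMatrix:
    """Read a raw count matrix, rejecting non-integer cells."""
    path = Path(path)
    sample_ids, feature_ids, rows = _read_matrix_rows(path)
    values = np.empty((len(rows), len(sample_ids)), dtype=np.int64)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                values[i, j] = int(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {i + 2}, column {j + 2}: "
                    f"expected an integer count, got {cell!r}"
                ) from None
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ParseError(f"{path}: line {i + 2}, column {j + 2}: negative count")
    return CountMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids))


def read_expression_matrix(path, transform_tag: str = "external") -> ExpressionMatrix:
    """Read a continuous expression matrix (floats, finite)."""
    path = Path(path)
    sample_ids, feature_ids, rows = _read_matrix_rows(path)
    values = np.empty((len(rows), len(sample_ids)), dtype=float)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {i + 2}, column {j + 2}: "
                    f"expected a number, got {cell!r}"
                ) from None
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(f"{path}: line {i + 2}, column {j + 2}: non-finite value")
    return ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids),
        transform_tag=transform_tag,
    )


def write_matrix(matrix: CountMatrix | ExpressionMatrix, path) -> None:
    frame = matrix.values.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


def read_annotation(path) -> SampleAnnotation:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "cohort", "stage"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad = frame.index[~frame["stage"].isin(VALID_STAGES)]
    if len(bad):
        lineno = int(bad[0]) + 2
        raise ParseError(
            f"{path}: line {lineno}: stage {frame.loc[bad[0], 'stage']!r} "
            f"not allowed; valid values are {list(VALID_STAGES)}"
        )
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    return SampleAnnotation(frame.set_index("sample_id"))


def write_annotation(annotation: SampleAnnotation, path) -> None:
    frame = annotation.frame.copy()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def read_target_map(path) -> TargetMap:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mirna_id", "gene_id"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    edges = list(dict.fromkeys(zip(frame["mirna_id"], frame["gene_id"])))
    if len(edges) < len(frame):
        # duplicates in user files are tolerated on read, deduplicated
        pass
    return TargetMap(edges, provenance=str(path.name))


def read_mirtarbase_export(path) -> TargetMap:
    """Ingest a miRTarBase-style export via its miRNA / Target Gene columns."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().strip(): c for c in frame.columns}
    mir_col = cols.get("mirna")
    gene_col = cols.get("target gene")
    if mir_col is None or gene_col is None:
        raise ParseError(f"{path}: expected 'miRNA' and 'Target Gene' columns")
    edges = list(dict.fromkeys(zip(frame[mir_col], frame[gene_col])))
    return TargetMap(edges, provenance=str(path.name))


def write_target_map(targets: TargetMap, path) -> None:
    pd.DataFrame(targets.edges, columns=["mirna_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_name_map(path) -> NameMap:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("precursor_id", "mature_id"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    mapping: dict[str, list[str]] = {}
    for prec, mature in zip(frame["precursor_id"], frame["mature_id"]):
        mapping.setdefault(prec, []).append(mature)
    return NameMap({k: tuple(v) for k, v in mapping.items()})


def write_name_map(name_map: NameMap, path) -> None:
    rows = [
        (prec, mature)
        for prec, arms in name_map.precursor_to_mature.items()
        for mature in arms
    ]
    pd.DataFrame(rows, columns=["precursor_id", "mature_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_de_table(de: DETable, path) -> None:
    frame = de.frame.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


def read_de_table(path, cohort_tag: str = "") -> DETable:
    frame = pd.read_csv(path, sep="\t", index_col="feature_id")
    return DETable(frame, cohort_tag=cohort_tag)


def write_signature(signature: ValidatedSignature, path) -> None:
    frame = signature.frame.copy()
    frame.index.name = "mirna_id"
    frame.to_csv(path, sep="\t")


def write_truth(truth: TruthSet, path) -> None:
    payload = {
        "planted_mirna_log2fc": truth.planted_mirna_log2fc,
        "planted_pairs": [list(p) for p in truth.planted_pairs],
        "mirna_ids": truth.mirna_ids,
        "gene_ids": truth.gene_ids,
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_truth(path) -> TruthSet:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return TruthSet(
        planted_mirna_log2fc=payload["planted_mirna_log2fc"],
        planted_pairs=[tuple(p) for p in payload["planted_pairs"]],
        mirna_ids=payload.get("mirna_ids", []),
        gene_ids=payload.get("gene_ids", []),
    )
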
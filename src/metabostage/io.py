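"""Readers and writers for feature tables, metadata and result artifacts.

Tabular artifacts (feature matrices, metadata, association tables,
selection frequencies) travel as UTF-8 CSV/TSV with a mandatory header;
models and reports travel as JSON.  Everything written here can be read
back losslessly at double precision.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, SampleMetadata
from .errors import FormatError

RESERVED_COLUMNS = ("injection_order", "batch", "is_qc")

_SEP = {"csv": ",", "tsv": "\t"}


def _delimiter(path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    try:
        return _SEP[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")


def _check_header(path, sep: str) -> list[str]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if not header:
        raise FormatError(f"{path}: empty file or missing header row")
    seen, dups = set(), []
    for name in header:
        if name in seen:
            dups.append(name)
        seen.add(name)
    if dups:
        raise FormatError(f"{path}: duplicated column name(s) {dups}")
    return header


def read_feature_table(
    path, dialect: str | None = None, *, is_scaled: bool = False
) -> FeatureMatrix:
    """Read an injections × features abundance table.

    Expected layout: first column = sample id, then the reserved columns
    ``injection_order``, ``batch``, ``is_qc``, then one column per
    feature.  Zero encodes a missing abundance.  Pass ``is_scaled=True``
    when reading back a pareto-scaled table (values may be negative).
    """
    sep = _delimiter(path, dialect)
    header = _check_header(path, sep)
    for col in ("injection_order", "is_qc"):
        if col not in header:
            raise FormatError(f"{path}: required column '{col}' missing")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index.name = None
    order = df.pop("injection_order")
    qc = df.pop("is_qc")
    if qc.dtype == object:
        qc = qc.map(
            {"True": True, "False": False, "true": True, "false": False}
        )
        if qc.isna().any():
            raise FormatError(f"{path}: is_qc must be boolean")
    qc = qc.astype(bool)
    batch = df.pop("batch") if "batch" in df.columns else pd.Series("B1", index=df.index)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric abundance value ({exc})")
    return FeatureMatrix(
        df, order.to_numpy(), batch.to_numpy(), qc.to_numpy(),
        is_scaled=is_scaled,
    )


def write_feature_table(fm: FeatureMatrix, path, dialect: str | None = None) -> None:
    sep = _delimiter(path, dialect)
    out = fm.values.copy()
    out.insert(0, "injection_order", fm.injection_order)
    out.insert(1, "batch", fm.batch_id)
    out.insert(2, "is_qc", fm.is_qc)
    out.to_csv(path, sep=sep, index=True, index_label="sample_id")


def read_sample_metadata(path, dialect: str | None = None) -> SampleMetadata:
    sep = _delimiter(path, dialect)
    _check_header(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index.name = None
    return SampleMetadata(df)


def write_sample_metadata(md: SampleMetadata, path, dialect: str | None = None) -> None:
    sep = _delimiter(path, dialect)
    md.table.to_csv(path, sep=sep, index=True, index_label="sample_id")


# ----------------------------------------------------------------------
# result artifacts


def write_results(obj, path) -> None:
    """Serialize a result object; CSV for tables, JSON for models/reports.

    Dispatches on the object's own serialization hooks: anything with a
    ``to_json_dict`` becomes JSON, anything with a ``to_frame`` (or any
    plain DataFrame) becomes CSV.
    """
    path = Path(path)
    if hasattr(obj, "to_json_dict"):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj.to_json_dict(), fh, indent=2)
    elif hasattr(obj, "to_frame"):
        obj.to_frame().to_csv(path, index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=True)
    else:
        raise FormatError(
            f"cannot serialize object of type {type(obj).__name__}"
        )


def read_selection_result(path):
    from .selection import SelectionResult

    return SelectionResult.from_frame(pd.read_csv(path))


def read_diagnostic_model(path):
    from .selection import DiagnosticModel

    with open(path, "r", encoding="utf-8") as fh:
        return DiagnosticModel.from_json_dict(json.load(fh))


def read_evaluation_report(path):
    from .evaluation import EvaluationReport

    with open(path, "r", encoding="utf-8") as fh:
        return EvaluationReport.from_json_dict(json.load(fh))
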
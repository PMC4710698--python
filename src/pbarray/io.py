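"""Readers and writers for the pipeline's tab-separated interchange formats.

Formats (all TSV with a header row, LF or CRLF accepted):

* expression matrix — first column ``probe_id``, one column per sample;
* sample sheet — ``sample_id, species, tissue, treatment, replicate``;
* annotation — ``probe_id, gene_id, classes`` (classes ``;``-separated);
* qRT-PCR pairs — ``gene_id, tissue, fc_array, fc_qpcr``;
* DE / candidate / enrichment / concordance tables as written by their stages.

Fold changes and intensities serialize with 6 significant digits, p and q
values in scientific notation; round-tripping a table reproduces it to
that precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SAMPLE_SHEET_COLUMNS
from .errors import DataError

_FLOAT_FMT = "%.6g"
_PQ_COLUMNS = {"p", "q", "p_value"}


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except ValueError as e:
        raise DataError(f"{path}: parse error: {e}") from e


def read_matrix(matrix_path, samples_path) -> ExpressionMatrix:
    """Load an expression matrix and its sample sheet, validating the pairing."""
    values = _read_tsv(matrix_path)
    if values.columns[0] != "probe_id":
        raise DataError(f"{matrix_path}: first column must be probe_id, got {values.columns[0]!r}")
    dup = values["probe_id"][values["probe_id"].duplicated()]
    if len(dup):
        first = dup.iloc[0]
        line = int(dup.index[0]) + 2  # header is line 1
        raise DataError(f"{matrix_path}:{line}: duplicate probe_id {first!r}")
    values = values.set_index("probe_id")
    bad = values.columns[~values.apply(lambda c: np.issubdtype(c.dtype, np.number))]
    if len(bad):
        col = bad[0]
        nonnum = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
        line = int(nonnum.index.get_indexer([nonnum.index[0]])[0]) if len(nonnum) else 0
        raise DataError(f"{matrix_path}: non-numeric cell in column {col!r}")
    samples = _read_tsv(samples_path)
    if "sample_id" not in samples.columns:
        raise DataError(f"{samples_path}: missing sample_id column")
    samples = samples.set_index("sample_id")
    missing = [c for c in values.columns if c not in samples.index]
    if missing:
        raise DataError(f"{samples_path}: matrix columns missing from sample sheet: {missing}")
    return ExpressionMatrix(values.astype(float), samples)


def write_matrix(m: ExpressionMatrix, matrix_path, samples_path) -> None:
    out = m.values.copy()
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT)
    sheet = m.samples.reset_index()
    first = sheet.columns[0]
    if first != "sample_id":
        sheet = sheet.rename(columns={first: "sample_id"})
    sheet.to_csv(samples_path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = _read_tsv(path, dtype=str).fillna("")
    for col in ("probe_id", "gene_id"):
        if col not in ann.columns:
            raise DataError(f"{path}: missing column {col!r}")
    if "classes" not in ann.columns:
        ann["classes"] = ""
    dup = ann["probe_id"][ann["probe_id"].duplicated()]
    if len(dup):
        raise DataError(f"{path}: duplicate probe_id {dup.iloc[0]!r}")
    return ann[["probe_id", "gene_id", "classes"]]


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any stage table; p/q-like columns in scientific notation, rest %.6g."""
    out = df.copy()
    for col in out.columns:
        if col in _PQ_COLUMNS:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6e}")
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def read_qpcr(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("gene_id", "fc_array", "fc_qpcr"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
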
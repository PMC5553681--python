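"""Readers and writers for the tabular formats the pipeline touches.

All on-disk formats are plain text: a long-format probe TSV (the internal
dialect), an Agilent Feature Extraction-like TSV dialect, GEO series-matrix
style processed tables, sample-sheet CSVs, qPCR plate CSVs (with an explicit
``Undetected`` sentinel, never numeric 0), and the filter-trace TSV report.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "PROBE_COLUMNS",
    "read_probe_table",
    "write_probe_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_qpcr_plate",
    "write_qpcr_plate",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_filter_trace",
    "read_filter_trace",
]

PROBE_COLUMNS = ["array_id", "probe_id", "sequence_id", "mirna_name",
                 "control_type", "rna_class", "raw_signal"]
CONTROL_TYPES = {"experimental", "negative", "other_control"}
RNA_CLASSES = {"miRNA", "tRNA", "rRNA", "unknown"}
SHEET_COLUMNS = ["array_id", "donor_id", "passage_label", "tech_rep_index",
                 "cohort"]
QPCR_COLUMNS = ["sample_id", "cohort", "passage_label", "target_id",
                "is_reference", "control_role", "well_rep_index", "cq"]
UNDETECTED = "Undetected"

#: mapping from AFE-style column names to the internal schema; configurable
#: because deposited files vary in their exact header set
AFE_DIALECT = {
    "FeatureNum": "probe_id",
    "ProbeName": "probe_id",
    "SystematicName": "sequence_id",
    "GeneName": "mirna_name",
    "ControlType": "control_type",
    "gTotalGeneSignal": "raw_signal",
    "gTotalProbeSignal": "raw_signal",
}
#: AFE ControlType codes: 0 experimental, -1 negative, 1 positive/other
AFE_CONTROL_CODES = {0: "experimental", -1: "negative", 1: "other_control"}


class FormatError(ValueError):
    """A file does not have the expected columns or layout."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {c!r}")


def validate_probe_table(df: pd.DataFrame, path="<memory>") -> pd.DataFrame:
    _require_columns(df, PROBE_COLUMNS, path)
    bad = df.index[~(df["raw_signal"] > 0)]
    if len(bad):
        raise ValidationError(
            f"{path}: non-positive raw_signal at row {int(bad[0])}"
        )
    unknown = set(df["control_type"]) - CONTROL_TYPES
    if unknown:
        warnings.warn(
            f"unknown control types {sorted(unknown)} mapped to 'other_control'"
        )
        df = df.copy()
        df.loc[df["control_type"].isin(unknown), "control_type"] = "other_control"
    dup = df.duplicated(subset=["array_id", "probe_id"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (array_id, probe_id) at row {int(df.index[dup][0])}"
        )
    arrays_without_neg = set(df["array_id"]) - set(
        df.loc[df["control_type"] == "negative", "array_id"]
    )
    if arrays_without_neg:
        warnings.warn(
            f"arrays without negative controls: {sorted(arrays_without_neg)}"
        )
    return df


def read_probe_table(path, dialect: str = "internal_long",
                     dialect_map: dict | None = None) -> pd.DataFrame:
    """Read a probe-level table in one of the supported dialects.

    ``internal_long`` is the package's own long TSV; ``afe_like`` is a
    per-array Feature Extraction-style TSV (``array_id`` taken from the file
    stem unless a column provides it); ``geo_series_matrix`` is a processed
    sequence-by-sample table with a ``!``-prefixed metadata preamble, read as
    one probe row per (sequence, sample).
    """
    path = Path(path)
    if dialect == "internal_long":
        # keep empty annotation fields as "" rather than NaN
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
        _require_columns(df, PROBE_COLUMNS, path)
        df["raw_signal"] = pd.to_numeric(df["raw_signal"], errors="raise")
        return validate_probe_table(df, path)
    if dialect == "afe_like":
        mapping = dict(AFE_DIALECT)
        if dialect_map:
            mapping.update(dialect_map)
        raw = pd.read_csv(path, sep="\t", comment="#")
        cols = {}
        for src, dst in mapping.items():
            if src in raw.columns and dst not in cols:
                cols[dst] = raw[src]
        for required in ("probe_id", "sequence_id", "control_type", "raw_signal"):
            if required not in cols:
                raise FormatError(f"{path}: missing mandatory column {required!r}")
        df = pd.DataFrame(cols)
        df["control_type"] = (
            df["control_type"].map(AFE_CONTROL_CODES).fillna("other_control")
        )
        if "array_id" not in df.columns:
            df["array_id"] = path.stem
        if "mirna_name" not in df.columns:
            df["mirna_name"] = df["sequence_id"]
        df["rna_class"] = "unknown"
        return validate_probe_table(df[PROBE_COLUMNS], path)
    if dialect == "geo_series_matrix":
        wide = read_geo_series_matrix(path)
        long = wide.stack().rename("raw_signal").reset_index()
        long.columns = ["sequence_id", "array_id", "raw_signal"]
        long["probe_id"] = long["sequence_id"]
        long["mirna_name"] = long["sequence_id"]
        long["control_type"] = "experimental"
        long["rna_class"] = "unknown"
        return validate_probe_table(long[PROBE_COLUMNS], path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_probe_table(df: pd.DataFrame, path) -> None:
    validate_probe_table(df, path)
    df.to_csv(path, sep="\t", index=False)


def read_geo_series_matrix(path) -> pd.DataFrame:
    """Read a GEO series-matrix style file into a sequence x sample frame.

    Tolerates the ``!``-prefixed metadata preamble and the
    ``series_matrix_table_begin/end`` sentinels; the table must be keyed by
    an ``ID_REF`` column.
    """
    lines = []
    with open(path) as fh:
        in_table = False
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                break
            if stripped.startswith("!"):
                continue
            if in_table or not lines:
                # files without sentinels: first non-! line is the header
                if stripped:
                    lines.append(line)
                    in_table = True
    if not lines:
        raise FormatError(f"{path}: no data table found")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines)), sep="\t")
    df.columns = [c.strip('"') for c in df.columns]
    if "ID_REF" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column 'ID_REF'")
    if df["ID_REF"].dtype == object:
        df["ID_REF"] = df["ID_REF"].str.strip('"')
    return df.set_index("ID_REF")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SHEET_COLUMNS, path)
    dup = df.duplicated(subset=["donor_id", "passage_label", "tech_rep_index"])
    if dup.any():
        raise ValidationError(f"{path}: duplicate (donor, passage, tech rep) entry")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df[SHEET_COLUMNS].to_csv(path, index=False)


def check_sheet_matches_probes(sheet: pd.DataFrame, probes: pd.DataFrame) -> None:
    a, b = set(sheet["array_id"]), set(probes["array_id"])
    if a != b:
        raise ValidationError(
            f"sample sheet arrays do not match probe table arrays: "
            f"only-in-sheet={sorted(a - b)}, only-in-probes={sorted(b - a)}"
        )


def read_qpcr_plate(path, references=None) -> pd.DataFrame:
    """Read a qPCR plate CSV; ``Undetected`` wells become NaN Cq.

    If ``references`` is given, every sample must carry every reference
    target at least once.
    """
    df = pd.read_csv(path)
    _require_columns(df, QPCR_COLUMNS, path)
    cq = df["cq"].replace(UNDETECTED, np.nan)
    df["cq"] = pd.to_numeric(cq, errors="raise")
    bad = df.index[(df["cq"] <= 0) | (df["cq"] > 45)]
    if len(bad):
        raise ValidationError(f"{path}: cq out of (0, 45] at row {int(bad[0])}")
    if references is not None:
        present = df.groupby("sample_id")["target_id"].agg(set)
        for sample, targets in present.items():
            missing = set(references) - targets
            if missing:
                raise ValidationError(
                    f"{path}: sample {sample!r} missing reference target(s) "
                    f"{sorted(missing)}"
                )
    return df


def write_qpcr_plate(df: pd.DataFrame, path) -> None:
    out = df[QPCR_COLUMNS].copy()
    out["cq"] = out["cq"].astype(object).where(out["cq"].notna(), UNDETECTED)
    out.to_csv(path, index=False)


def read_expression_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sequence_id"
    return df


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sequence_id")


def write_filter_trace(trace: pd.DataFrame, path) -> None:
    """Write the per-sequence filter trace as TSV, one row per sequence."""
    trace.to_csv(path, sep="\t", index_label="sequence_id")


def read_filter_trace(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sequence_id")
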
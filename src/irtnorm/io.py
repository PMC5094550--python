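"""Tab-separated table schemas and JSON model (de)serialization.

All tables are TSV with a header row and '.' as the decimal radix; extra
columns are preserved on read and appended after the schema columns on
write.  Models serialize to a small JSON document that round-trips exactly
for finite doubles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .regression import SegmentedTheilSenRegressor
from .windowing import ExtractionWindowEstimator

__all__ = [
    "SchemaError",
    "TableSchema",
    "ANCHOR_TABLE",
    "REPLICATE_REPORT",
    "CALIBRATION_TABLE",
    "WINDOW_OBSERVATIONS",
    "RUN_EXPORT",
    "PSM_TABLE",
    "FRAGMENT_TABLE",
    "OPENSWATH_LIBRARY",
    "read_table",
    "write_table",
    "save_model",
    "load_model",
]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    """Required columns of a TSV table and their types ('str'|'float'|'int'|'bool')."""

    name: str
    columns: tuple[tuple[str, str], ...]

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.columns)


ANCHOR_TABLE = TableSchema("anchors", (
    ("precursor_id", "str"), ("x", "float"), ("y", "float"),
))
REPLICATE_REPORT = TableSchema("replicates", (
    ("run_id", "str"), ("precursor_id", "str"), ("modified_sequence", "str"),
    ("charge", "int"), ("rt_apex_min", "float"),
))
CALIBRATION_TABLE = TableSchema("calibration", (
    ("precursor_id", "str"), ("irt", "float"), ("rt_mean_min", "float"),
    ("rt_sd_min", "float"),
))
WINDOW_OBSERVATIONS = TableSchema("window_observations", (
    ("precursor_id", "str"), ("irt", "float"), ("rt_measured_min", "float"),
    ("rt_predicted_min", "float"), ("peak_width_min", "float"),
))
RUN_EXPORT = TableSchema("run", (
    ("precursor_id", "str"), ("true_irt", "float"), ("rt_apex_min", "float"),
    ("peak_width_min", "float"), ("is_outlier", "bool"),
))
PSM_TABLE = TableSchema("psms", (
    ("run_id", "str"), ("precursor_id", "str"), ("modified_sequence", "str"),
    ("sequence", "str"), ("charge", "int"), ("rt_apex_min", "float"),
    ("score", "float"),
))
FRAGMENT_TABLE = TableSchema("fragments", (
    ("run_id", "str"), ("precursor_id", "str"), ("series", "str"),
    ("ordinal", "int"), ("fragment_charge", "int"), ("mz", "float"),
    ("intensity", "float"),
))
OPENSWATH_LIBRARY = TableSchema("openswath_library", (
    ("PrecursorMz", "float"), ("ProductMz", "float"),
    ("LibraryIntensity", "float"), ("NormalizedRetentionTime", "float"),
    ("PeptideSequence", "str"), ("ModifiedPeptideSequence", "str"),
    ("PrecursorCharge", "int"), ("FragmentType", "str"),
    ("FragmentSeriesNumber", "int"), ("FragmentCharge", "int"),
    ("ProteinId", "str"),
))

_CONVERTERS = {
    "str": lambda s: s.astype(str),
    "float": lambda s: s.astype(float),
    "int": lambda s: s.astype(int),
    "bool": lambda s: s.map({"True": True, "False": False, "true": True,
                             "false": False, "1": True, "0": False}),
}


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read a TSV table, validating and typing the schema's columns.

    Extra columns are preserved as strings.  Raises :class:`SchemaError`
    naming the first missing column, or the offending row for a value that
    cannot be parsed (including ','-radix decimals).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in schema.column_names:
        if col not in df.columns:
            raise SchemaError(
                f"{schema.name} table {path}: missing required column {col!r}"
            )
    for col, kind in schema.columns:
        try:
            df[col] = _CONVERTERS[kind](df[col])
        except (ValueError, TypeError):
            bad = _first_bad_row(df[col], kind)
            value = df[col].iloc[bad]
            hint = (" (',' decimal radix is not accepted; use '.')"
                    if kind == "float" and "," in str(value) else "")
            raise SchemaError(
                f"{schema.name} table {path}: column {col!r} row {bad + 2}: "
                f"cannot parse {value!r} as {kind}{hint}"
            ) from None
        if kind == "bool" and df[col].isna().any():
            bad = int(df[col].isna().idxmax())
            raise SchemaError(
                f"{schema.name} table {path}: column {col!r} row {bad + 2}: "
                f"not a boolean"
            )
    return df


def _first_bad_row(series: pd.Series, kind: str) -> int:
    for i, v in enumerate(series):
        try:
            _CONVERTERS[kind](pd.Series([v]))
        except (ValueError, TypeError):
            return i
    return 0


def write_table(df: pd.DataFrame, path, schema: TableSchema) -> None:
    """Write a TSV table with the schema's columns first, then extras.

    Floats use ``repr`` precision so that a write/read round-trip is
    lossless for finite doubles.
    """
    missing = set(schema.column_names) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{schema.name} table for {path}: missing columns {sorted(missing)}"
        )
    extras = [c for c in df.columns if c not in schema.column_names]
    ordered = df[list(schema.column_names) + extras]
    ordered.to_csv(path, sep="\t", index=False, float_format=None)


def save_model(model, path) -> None:
    """Serialize a fitted regression or window model to JSON."""
    if isinstance(model, ExtractionWindowEstimator):
        doc = {"kind": "window", **model.to_dict()}
    elif isinstance(model, SegmentedTheilSenRegressor):
        doc = {"kind": "segmented", **model.to_dict()}
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path):
    """Load a model written by :func:`save_model`."""
    doc = json.loads(Path(path).read_text())
    kind = doc.get("kind")
    if kind == "window":
        return ExtractionWindowEstimator.from_dict(doc)
    if kind == "segmented":
        return SegmentedTheilSenRegressor.from_dict(doc)
    raise ValueError(f"unknown model kind {kind!r} in {path}")
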
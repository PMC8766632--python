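"""Delimited-table input and the categorical indicator/complement encoding.

Each subcategory ``s`` of a categorical column yields TWO binary columns —
the indicator ``chi(x = s)`` and its complement ``chi(x != s)`` — so both
polarities of a rule ("margin is circumscribed" / "margin is not
circumscribed") are available to the L1 selection; continuous columns are
min-max rescaled to [0, 1]. Rows containing the missing-value sentinel are
dropped (and the drop count logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import LabeledDataset, ValidationError

__all__ = [
    "ColumnSpec",
    "EncodingSchema",
    "read_table",
    "read_raw",
    "encode_categorical",
    "write_table",
    "read_encoded",
    "BIRADS_SCHEMA",
]

logger = logging.getLogger(__name__)


@dataclass
class ColumnSpec:
    """Role and encoding details for one raw column."""

    role: str  # categorical | continuous | label | group | drop
    categories: list[str] = field(default_factory=list)  # ordered subcategory values
    names: dict = field(default_factory=dict)  # value -> readable name (optional)

    def __post_init__(self) -> None:
        if self.role not in ("categorical", "continuous", "label", "group", "drop"):
            raise ValidationError(f"unknown column role {self.role!r}")
        if self.role in ("categorical", "label"):
            if not self.categories:
                raise ValidationError(f"{self.role} column needs an ordered category list")
            if len(set(self.categories)) != len(self.categories):
                raise ValidationError("duplicate subcategory values")


@dataclass
class EncodingSchema:
    columns: dict[str, ColumnSpec]
    missing: str = "?"

    def __post_init__(self) -> None:
        labels = [c for c, s in self.columns.items() if s.role == "label"]
        if len(labels) != 1:
            raise ValidationError("schema must declare exactly one label column")

    @property
    def label_column(self) -> str:
        return next(c for c, s in self.columns.items() if s.role == "label")

    @property
    def group_column(self) -> str | None:
        return next((c for c, s in self.columns.items() if s.role == "group"), None)


#: UCI mammographic-mass layout: BI-RADS assessment dropped, age continuous,
#: shape (4) / margin (5) / density (4) categorical, severity is the label.
BIRADS_SCHEMA = EncodingSchema(
    columns={
        "birads": ColumnSpec("drop"),
        "age": ColumnSpec("continuous"),
        "shape": ColumnSpec(
            "categorical",
            ["1", "2", "3", "4"],
            {"1": "round", "2": "oval", "3": "lobular", "4": "irregular"},
        ),
        "margin": ColumnSpec(
            "categorical",
            ["1", "2", "3", "4", "5"],
            {
                "1": "circumscribed",
                "2": "microlobulated",
                "3": "obscured",
                "4": "ill_defined",
                "5": "spiculated",
            },
        ),
        "density": ColumnSpec(
            "categorical",
            ["1", "2", "3", "4"],
            {"1": "high", "2": "iso", "3": "low", "4": "fat_containing"},
        ),
        "severity": ColumnSpec("label", ["0", "1"], {"0": "benign", "1": "malignant"}),
    },
    missing="?",
)


def read_raw(path, schema: EncodingSchema) -> pd.DataFrame:
    """Read the delimited file as strings, drop rows with missing values."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing_cols = [c for c in schema.columns if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"input lacks schema columns: {missing_cols}")
    used = [c for c, s in schema.columns.items() if s.role != "drop"]
    df = df[used]
    mask = df.isna().any(axis=1) | (df == schema.missing).any(axis=1)
    if mask.any():
        logger.info("dropped %d rows with missing values", int(mask.sum()))
    df = df[~mask].reset_index(drop=True)
    if df.empty:
        raise ValidationError("no complete rows remain after dropping missing values")
    return df


def encode_categorical(raw: pd.DataFrame, schema: EncodingSchema) -> LabeledDataset:
    """Expand categoricals into indicator/complement pairs, rescale continuous
    columns to [0, 1], and code labels/groups per the schema order."""
    feature_cols: list[np.ndarray] = []
    feature_names: list[str] = []
    for col, spec in schema.columns.items():
        if spec.role == "categorical":
            values = raw[col].astype(str)
            unknown = set(values) - set(spec.categories)
            if unknown:
                raise ValidationError(f"column {col!r}: values outside schema: {sorted(unknown)}")
            for cat in spec.categories:
                name = spec.names.get(cat, cat)
                ind = (values == cat).to_numpy(dtype=float)
                feature_cols.extend([ind, 1.0 - ind])
                feature_names.extend([f"{col}_is_{name}", f"{col}_not_{name}"])
        elif spec.role == "continuous":
            x = pd.to_numeric(raw[col], errors="raise").to_numpy(dtype=float)
            lo, hi = x.min(), x.max()
            feature_cols.append((x - lo) / (hi - lo) if hi > lo else np.zeros_like(x))
            feature_names.append(col)

    label_spec = schema.columns[schema.label_column]
    labels_raw = raw[schema.label_column].astype(str)
    unknown = set(labels_raw) - set(label_spec.categories)
    if unknown:
        bad = raw.index[labels_raw.isin(unknown)][0]
        raise ValidationError(
            f"unknown label value {labels_raw[bad]!r} in row {bad} of column "
            f"{schema.label_column!r}"
        )
    code_of = {v: k + 1 for k, v in enumerate(label_spec.categories)}
    labels = labels_raw.map(code_of).to_numpy(dtype=int)
    label_names = [label_spec.names.get(v, v) for v in label_spec.categories]

    gcol = schema.group_column
    if gcol is None:
        groups = np.ones(len(raw), dtype=int)
    else:
        gvals = raw[gcol].astype(str)
        gcats = schema.columns[gcol].categories or sorted(gvals.unique())
        gmap = {v: k + 1 for k, v in enumerate(gcats)}
        if not set(gvals).issubset(gmap):
            raise ValidationError(f"unknown group values: {sorted(set(gvals) - set(gmap))}")
        groups = gvals.map(gmap).to_numpy(dtype=int)

    return LabeledDataset(
        np.column_stack(feature_cols), labels, groups, feature_names, label_names
    )


def read_table(path, schema: EncodingSchema) -> LabeledDataset:
    """Read, drop-missing, encode: the full path from a raw delimited file to
    a model-ready dataset."""
    return encode_categorical(read_raw(path, schema), schema)


def write_table(dataset: LabeledDataset, path) -> None:
    """Write an encoded dataset as CSV: feature columns, then ``label`` (the
    label name) and ``group`` (the integer code)."""
    df = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    df["label"] = [dataset.label_names[c - 1] for c in dataset.observed_labels]
    df["group"] = dataset.groups
    df.to_csv(path, index=False)


def read_encoded(path, label_names: list[str] | None = None) -> LabeledDataset:
    """Inverse of :func:`write_table`. Label codes follow ``label_names`` when
    given, else the sorted distinct label values."""
    df = pd.read_csv(path)
    if "label" not in df.columns or "group" not in df.columns:
        raise ValidationError("encoded table needs 'label' and 'group' columns")
    names = label_names or sorted(df["label"].astype(str).unique())
    code_of = {v: k + 1 for k, v in enumerate(names)}
    labels = df["label"].astype(str).map(code_of)
    if labels.isna().any():
        raise ValidationError("label values outside the provided label_names")
    feats = df.drop(columns=["label", "group"])
    return LabeledDataset(
        feats.to_numpy(dtype=float),
        labels.to_numpy(dtype=int),
        df["group"].to_numpy(dtype=int),
        list(feats.columns),
        list(names),
    )
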
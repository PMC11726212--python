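"""Cohort data model and CSV round-tripping.

A cohort is a patients × features matrix in clinical units with an explicit
missingness mask.  Files are plain UTF-8 CSV with a mandatory header, a
``patient_id`` first column, and empty cells denoting missing values; label
files carry the three subtype severities (``lv``, ``pca``, ``fv``), each in
[0, 1], keyed by patient id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import FeatureSchema

ID_COLUMN = "patient_id"
SUBTYPES = ("lv", "pca", "fv")


class CohortFormatError(ValueError):
    """Raised for malformed cohort or label files."""


@dataclass(frozen=True)
class SubtypeSeverities:
    """Per-patient target: one severity in [0, 1] per subtype.

    ``lv``  — Logopenic Variant (language impairment),
    ``pca`` — Posterior Cortical Atrophy (visual processing),
    ``fv``  — Frontal Variant (behaviour/executive function).
    """

    lv: float
    pca: float
    fv: float

    def __post_init__(self) -> None:
        for name in SUBTYPES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"severity {name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.lv, self.pca, self.fv], dtype=float)


@dataclass
class CohortTable:
    """Patients × features values (clinical units) plus missingness mask.

    ``values`` holds NaN at masked positions; column order always equals the
    schema's feature order.
    """

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if len(self.patient_ids) != n:
            raise ValueError("patient_ids length does not match values rows")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match values columns")
        if self.missing_mask.shape != (n, p):
            raise ValueError("missing_mask shape does not match values")
        if len(set(self.patient_ids)) != n:
            raise ValueError("patient identifiers must be unique")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "CohortTable":
        return CohortTable(
            list(self.patient_ids),
            list(self.feature_names),
            self.values.copy(),
            self.missing_mask.copy(),
        )

    def subset(self, rows: Sequence[int]) -> "CohortTable":
        idx = np.asarray(rows, dtype=int)
        return CohortTable(
            [self.patient_ids[i] for i in idx],
            list(self.feature_names),
            self.values[idx].copy(),
            self.missing_mask[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, ID_COLUMN, self.patient_ids)
        return df


def read_cohort(csv_path: str | Path, schema: FeatureSchema) -> CohortTable:
    """Read a cohort CSV, reordering columns to schema order.

    Header names must match the schema's feature names (order-insensitive);
    empty cells are flagged missing.  A non-numeric cell raises a parse error
    naming the offending row and column.
    """
    path = Path(csv_path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if ID_COLUMN not in raw.columns:
        raise CohortFormatError(f"{path}: missing required column {ID_COLUMN!r}")
    missing_cols = [n for n in schema.names if n not in raw.columns]
    if missing_cols:
        raise CohortFormatError(f"{path}: missing required column(s) {missing_cols}")

    ids = raw[ID_COLUMN].astype(str).tolist()
    n = len(ids)
    values = np.empty((n, len(schema)), dtype=float)
    mask = np.zeros((n, len(schema)), dtype=bool)
    for j, name in enumerate(schema.names):
        col = raw[name].to_numpy(dtype=object)
        for i, cell in enumerate(col):
            text = str(cell).strip()
            if text == "":
                values[i, j] = np.nan
                mask[i, j] = True
                continue
            try:
                values[i, j] = float(text)
            except ValueError as exc:
                raise CohortFormatError(
                    f"{path}: non-numeric value {text!r} at row {i + 1}, "
                    f"column {name!r}"
                ) from exc
    return CohortTable(ids, list(schema.names), values, mask)


def write_cohort(table: CohortTable, csv_path: str | Path) -> Path:
    """Write a cohort CSV; masked cells become empty strings.

    ``read_cohort(write_cohort(t))`` reproduces values, mask and ids exactly
    for finite inputs (floats are serialized with round-trip precision).
    """
    path = Path(csv_path)
    rows = []
    for i, pid in enumerate(table.patient_ids):
        row = [pid]
        for j in range(len(table.feature_names)):
            row.append(
                "" if table.missing_mask[i, j] else repr(float(table.values[i, j]))
            )
        rows.append(row)
    header = [ID_COLUMN, *table.feature_names]
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")
    return path


def read_labels(csv_path: str | Path) -> pd.DataFrame:
    """Read a label CSV with columns patient_id, lv, pca, fv (severities in [0,1])."""
    path = Path(csv_path)
    df = pd.read_csv(path)
    required = [ID_COLUMN, *SUBTYPES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")
    df = df[required].copy()
    df[ID_COLUMN] = df[ID_COLUMN].astype(str)
    vals = df[list(SUBTYPES)].to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals < 0).any() or (vals > 1).any():
        raise CohortFormatError(f"{path}: severities must be finite and in [0, 1]")
    return df


def write_labels(labels: pd.DataFrame, csv_path: str | Path) -> Path:
    path = Path(csv_path)
    labels[[ID_COLUMN, *SUBTYPES]].to_csv(path, index=False)
    return path


def align_labels(table: CohortTable, labels: pd.DataFrame) -> np.ndarray:
    """Return the (n, 3) severity matrix aligned to the table's patient order."""
    by_id = labels.set_index(ID_COLUMN)
    try:
        aligned = by_id.loc[table.patient_ids, list(SUBTYPES)]
    except KeyError as exc:
        raise CohortFormatError(f"label file lacks patient id(s): {exc}") from exc
    return aligned.to_numpy(dtype=float)
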
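"""Descriptor tables: the tabular contract shared by every stage of the pipeline.

A :class:`DescriptorTable` holds one row per chemical and one column per
numeric molecular descriptor (e.g. precomputed PaDEL 1D/2D descriptors),
plus an optional experimental clearance index (CI) target.  CI is the
permeability of a chemical across the ex vivo perfused placenta relative to
antipyrine, a dimensionless nonnegative ratio.  ``ci_min`` and
``ci_variation`` carry the lower bound of the reported CI within
experimental variation, used for variation-aware external evaluation.

Feature order is significant: it is the file column order and it is the
tie-break order used by sequential forward selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable",
    "TableSchema",
    "PredictionRecord",
    "read_table",
    "write_predictions",
    "read_predictions",
]


@dataclass
class TableSchema:
    """Column mapping used by :func:`read_table`.

    ``normalized`` declares whether the feature values in the file are
    already z-score normalized (supplementary exports often are); the loader
    cannot infer this, so the user states it and downstream code can check
    :attr:`DescriptorTable.normalized`.
    """

    id_column: str = "chemical_id"
    ci_column: str | None = "CI"
    ci_min_column: str | None = None
    ci_variation_column: str | None = None
    name_column: str | None = None
    smiles_column: str | None = None
    exclude: tuple[str, ...] = ()
    normalized: bool = False


@dataclass
class DescriptorTable:
    chemical_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # (n_chemicals, n_features), finite floats
    ci: np.ndarray | None = None
    ci_min: np.ndarray | None = None
    ci_variation: np.ndarray | None = None
    names: list[str] | None = None
    smiles: list[str] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.chemical_ids):
            raise ValueError(
                f"values has {n} rows but {len(self.chemical_ids)} chemical ids"
            )
        if p != len(self.feature_names):
            raise ValueError(
                f"values has {p} columns but {len(self.feature_names)} feature names"
            )
        if len(self.chemical_ids) == 0:
            raise ValueError("table must contain at least one chemical")
        dup = _duplicates(self.chemical_ids)
        if dup:
            raise ValueError(f"duplicate chemical ids: {sorted(dup)}")
        dup = _duplicates(self.feature_names)
        if dup:
            raise ValueError(f"duplicate feature names: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite descriptor value at row "
                f"{self.chemical_ids[bad[0]]!r}, column {self.feature_names[bad[1]]!r}"
            )
        for attr in ("ci", "ci_min", "ci_variation"):
            v = getattr(self, attr)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{attr} must have one value per chemical")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{attr} contains missing or non-finite values")
            if np.any(v < 0):
                raise ValueError(f"{attr} must be nonnegative (CI is a ratio)")
            setattr(self, attr, v)

    @property
    def n_chemicals(self) -> int:
        return len(self.chemical_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def feature_index(self, names: Sequence[str]) -> np.ndarray:
        pos = {f: i for i, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in pos]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return np.array([pos[f] for f in names], dtype=int)

    def select_features(self, names: Sequence[str]) -> "DescriptorTable":
        """A copy restricted to the given features, in the given order."""
        idx = self.feature_index(names)
        return replace(self, feature_names=list(names), values=self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "chemical_id", self.chemical_ids)
        if self.ci is not None:
            df["CI"] = self.ci
        if self.ci_min is not None:
            df["CI_min"] = self.ci_min
        if self.ci_variation is not None:
            df["CI_variation"] = self.ci_variation
        return df


@dataclass
class PredictionRecord:
    chemical_id: str
    predicted_ci: float
    in_ad: bool | str = "unassessed"  # True/False once AD was applied
    matched_rules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.in_ad is True and self.matched_rules:
            raise ValueError("a chemical matching an exclusion rule cannot be in-AD")
        if self.in_ad is False and not self.matched_rules:
            raise ValueError("out-of-AD requires at least one matched rule")


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_table(path: str | Path, schema: TableSchema | None = None) -> DescriptorTable:
    """Read a descriptor CSV into a :class:`DescriptorTable`.

    The file must be UTF-8 CSV with a header row and "." decimal separator.
    Every column not named in the schema (id/name/smiles/targets/excluded)
    is treated as a numeric feature; file column order becomes feature
    order.  Missing values are rejected, never imputed.
    """
    schema = schema or TableSchema()
    path = Path(path)
    df = pd.read_csv(path)
    if schema.id_column not in df.columns:
        raise ValueError(f"id column {schema.id_column!r} not found in {path}")
    ids = df[schema.id_column].astype(str).tolist()
    dup = _duplicates(ids)
    if dup:
        raise ValueError(f"duplicate chemical ids in {path}: {sorted(dup)}")

    special = {schema.id_column, *schema.exclude}
    for col in (schema.name_column, schema.smiles_column):
        if col is not None:
            special.add(col)

    def _target(col: str | None) -> np.ndarray | None:
        if col is None:
            return None
        if col not in df.columns:
            raise ValueError(f"declared target column {col!r} not found in {path}")
        special.add(col)
        raw = pd.to_numeric(df[col], errors="coerce")
        if raw.isna().any():
            rows = [ids[i] for i in np.flatnonzero(raw.isna().to_numpy())]
            raise ValueError(
                f"missing or non-numeric values in target column {col!r} "
                f"for chemicals {rows} (imputation is not supported)"
            )
        return raw.to_numpy(dtype=float)

    # the default CI column is optional (prediction-only tables have none)
    ci = None
    if schema.ci_column is not None and schema.ci_column in df.columns:
        ci = _target(schema.ci_column)
    ci_min = _target(schema.ci_min_column)
    ci_var = _target(schema.ci_variation_column)

    feature_cols = [c for c in df.columns if c not in special]
    values = np.empty((len(ids), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(num.isna().to_numpy())
        if bad.size:
            raise ValueError(
                f"non-numeric or missing value in feature column {col!r}, "
                f"row for chemical {ids[bad[0]]!r}"
            )
        values[:, j] = num.to_numpy(dtype=float)

    names = df[schema.name_column].astype(str).tolist() if schema.name_column else None
    smiles = df[schema.smiles_column].astype(str).tolist() if schema.smiles_column else None
    return DescriptorTable(
        chemical_ids=ids,
        feature_names=feature_cols,
        values=values,
        ci=ci,
        ci_min=ci_min,
        ci_variation=ci_var,
        names=names,
        smiles=smiles,
        normalized=schema.normalized,
    )


_PRECISION = 10  # decimal places kept by write_predictions


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    """Write prediction records as CSV (in_ad "unassessed" serialized as NA)."""
    if not records:
        raise ValueError("no prediction records to write")
    rows = []
    for r in records:
        in_ad = "NA" if r.in_ad == "unassessed" else str(bool(r.in_ad))
        rows.append(
            {
                "chemical_id": r.chemical_id,
                "predicted_ci": round(float(r.predicted_ci), _PRECISION),
                "in_ad": in_ad,
                "matched_rules": ";".join(r.matched_rules),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        raw = str(row["in_ad"])
        in_ad: bool | str = "unassessed" if raw == "NA" else raw == "True"
        matched = [m for m in str(row["matched_rules"]).split(";") if m]
        out.append(
            PredictionRecord(
                chemical_id=str(row["chemical_id"]),
                predicted_ci=float(row["predicted_ci"]),
                in_ad=in_ad,
                matched_rules=matched,
            )
        )
    return out
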
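"""Cohort table I/O, the natural-log transform, and tertile utilities."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyInputError,
    InsufficientDataError,
    SchemaError,
    StateError,
)
from .graph_model import BlockOrdering, VariableSpec


@dataclass
class CohortTable:
    """One row per participant, one numeric column per declared variable.

    ``log_applied`` records whether the natural-log transform has been taken;
    it toggles exactly once, via :func:`log_transform`.
    """

    data: pd.DataFrame
    meta: dict[str, VariableSpec]
    log_applied: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def missing_counts(self) -> dict[str, int]:
        return {c: int(self.data[c].isna().sum()) for c in self.data.columns}

    def copy(self) -> "CohortTable":
        return replace(self, data=self.data.copy(), warnings=list(self.warnings))


def read_cohort(path, ordering: BlockOrdering) -> CohortTable:
    """Read a CSV cohort file against a declared block ordering.

    Non-numeric cells become missing; undeclared columns are dropped with a
    warning record; a declared column that is absent raises SchemaError.
    """
    raw = pd.read_csv(path)
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    declared = ordering.names()
    missing_cols = [c for c in declared if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing declared column(s) {missing_cols}")
    warns = []
    extra = [c for c in raw.columns if c not in declared]
    for c in extra:
        warns.append(f"ignored undeclared column {c!r}")
    data = pd.DataFrame(
        {c: pd.to_numeric(raw[c], errors="coerce") for c in declared},
        index=range(len(raw)),
    ).astype(float)
    return CohortTable(data=data, meta=ordering.variables, warnings=warns)


def from_dataframe(df: pd.DataFrame, ordering: BlockOrdering,
                   log_applied: bool = False) -> CohortTable:
    """Wrap an in-memory DataFrame (already numeric) as a CohortTable."""
    declared = ordering.names()
    missing_cols = [c for c in declared if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing declared column(s) {missing_cols}")
    return CohortTable(
        data=df[declared].astype(float).reset_index(drop=True),
        meta=ordering.variables,
        log_applied=log_applied,
    )


def log_transform(t: CohortTable) -> CohortTable:
    """Natural-log transform of every variable flagged for it.

    Raises DomainError (naming row and column) if a flagged variable has a
    non-positive value, and StateError if applied twice.
    """
    if t.log_applied:
        raise StateError("log transform already applied")
    data = t.data.copy()
    for name, spec in t.meta.items():
        col = data[name]
        if spec.positive_required:
            bad = col[col.notna() & (col <= 0)]
            if len(bad):
                row = int(bad.index[0])
                raise DomainError(
                    f"non-positive value {bad.iloc[0]!r} in column {name!r} "
                    f"(row {row}) cannot be log-transformed"
                )
        if spec.log_transform:
            data[name] = np.log(col)
    return replace(t, data=data, log_applied=True, warnings=list(t.warnings))


def complete_cases(t: CohortTable, variables) -> CohortTable:
    """Rows with no missing value among ``variables`` (order preserved)."""
    variables = list(variables)
    unknown = [v for v in variables if v not in t.data.columns]
    if unknown:
        raise SchemaError(f"unknown variable(s) {unknown}")
    if not variables:
        return t.copy()
    keep = t.data[variables].notna().all(axis=1)
    return replace(t, data=t.data.loc[keep].copy(), warnings=list(t.warnings))


def descriptives(t: CohortTable) -> pd.DataFrame:
    """Mean, SD, min, max per variable on the original scale.

    Missing values are excluded variable by variable.  If the table has been
    log-transformed, flagged variables are exponentiated back first.
    """
    data = t.data.copy()
    if t.log_applied:
        for name, spec in t.meta.items():
            if spec.log_transform:
                data[name] = np.exp(data[name])
    rows = []
    for c in data.columns:
        v = data[c].dropna()
        rows.append(
            {
                "variable": c,
                "n": len(v),
                "mean": v.mean() if len(v) else np.nan,
                "sd": v.std(ddof=1) if len(v) > 1 else (0.0 if len(v) else np.nan),
                "min": v.min() if len(v) else np.nan,
                "max": v.max() if len(v) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def tertile_split(values) -> tuple[pd.Series, tuple[float, float]]:
    """Split a vector at its empirical 1/3 and 2/3 quantiles.

    Boundaries use linear interpolation.  Values <= lower boundary are
    'low', <= upper are 'mid', else 'high'; ties go to the lower group;
    missing stays missing.  Needs at least 3 non-missing values.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    obs = v.dropna()
    if len(obs) < 3:
        raise InsufficientDataError(
            f"tertile split needs >= 3 non-missing values, got {len(obs)}"
        )
    lo, hi = np.quantile(obs, [1 / 3, 2 / 3])
    if lo == hi:
        warnings.warn("degenerate tertile boundaries (ties dominate)",
                      stacklevel=2)
    labels = pd.Series(pd.NA, index=v.index, dtype="object")
    labels[v.notna() & (v <= lo)] = "low"
    labels[v.notna() & (v > lo) & (v <= hi)] = "mid"
    labels[v.notna() & (v > hi)] = "high"
    return labels, (float(lo), float(hi))


def geometric_mean(values) -> float:
    """exp(mean of natural logs); requires strictly positive values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise InsufficientDataError("geometric mean of an empty vector")
    if np.any(v <= 0):
        raise DomainError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(v))))


@dataclass
class TertileGrid:
    """3x3 grid of outcome geometric means over two factors' tertiles.

    Rows index the first factor's tertiles (low, mid, high), columns the
    second's.  Empty cells hold NaN and are listed in ``empty_cells``.
    """

    outcome: str
    factor_rows: str
    factor_cols: str
    row_boundaries: tuple[float, float]
    col_boundaries: tuple[float, float]
    cells: np.ndarray  # 3x3 geometric means
    counts: np.ndarray  # 3x3 cell sizes

    LEVELS = ("low", "mid", "high")

    @property
    def empty_cells(self) -> list[tuple[str, str]]:
        out = []
        for i, r in enumerate(self.LEVELS):
            for j, c in enumerate(self.LEVELS):
                if self.counts[i, j] == 0:
                    out.append((r, c))
        return out

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "factor_rows": self.factor_rows,
            "factor_cols": self.factor_cols,
            "row_boundaries": list(self.row_boundaries),
            "col_boundaries": list(self.col_boundaries),
            "levels": list(self.LEVELS),
            "cells": [[None if np.isnan(x) else float(x) for x in row]
                      for row in self.cells],
            "counts": self.counts.astype(int).tolist(),
            "quantile_convention": "linear interpolation; ties to lower group",
        }
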
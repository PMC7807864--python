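"""Schema validation of the delimited tables exchanged between stages."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .qualitylab.io import sniff_delimiter

SCHEMAS = ("observations", "covariates", "predictor", "clean", "results")


@dataclass
class Violation:
    row: int | None  # None for file/column level problems
    column: str
    rule: str

    def __str__(self) -> str:
        where = f"row {self.row}, " if self.row is not None else ""
        return f"{where}column {self.column}: {self.rule}"


def _require_columns(df: pd.DataFrame, columns) -> list[Violation]:
    return [
        Violation(None, c, "required column is missing")
        for c in columns
        if c not in df.columns
    ]


def _numeric(df, column) -> pd.Series:
    return pd.to_numeric(df[column], errors="coerce")


def validate_table(
    path: str | Path,
    schema: str,
    n_pcs: int | None = None,
    threshold: float | None = None,
) -> list[Violation]:
    """Validate a file against one of the known schemas.

    Returns the list of violations (empty for a clean table).  For the
    ``covariates`` schema, ``n_pcs`` demands columns pc1..pc<n>; for
    ``results``, ``threshold`` enables the significant/p cross-field check.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sniff_delimiter(path), dtype=str, keep_default_na=False)
    v: list[Violation] = []

    def numeric_rule(column: str, rule, description: str, allow_empty=False):
        if column not in df.columns:
            return
        x = _numeric(df, column)
        for row in np.flatnonzero(~rule(x)):
            if allow_empty and df[column].iloc[row] == "":
                continue
            v.append(Violation(int(row), column, description))

    if schema == "observations":
        v += _require_columns(df, ["patient_id", "lab_id", "value", "unit", "age"])
        numeric_rule("age", lambda x: x.notna() & (x >= 0), "age must be a number >= 0")
        for col in ("patient_id", "lab_id"):
            if col in df.columns:
                for row in np.flatnonzero(df[col].str.len() == 0):
                    v.append(Violation(int(row), col, "identifier must be non-empty"))

    elif schema == "covariates":
        v += _require_columns(df, ["patient_id", "sex", "median_age"])
        if n_pcs is not None:
            v += _require_columns(df, [f"pc{i}" for i in range(1, n_pcs + 1)])
        numeric_rule("median_age", lambda x: x.notna() & (x >= 0),
                     "median_age must be a number >= 0")

    elif schema == "predictor":
        v += _require_columns(df, ["patient_id", "value"])
        numeric_rule("value", lambda x: x.notna(), "value must be numeric")

    elif schema == "clean":
        v += _require_columns(df, ["patient_id", "lab_id", "median_value",
                                   "age_at_median", "n_obs", "int_value"])
        numeric_rule("n_obs", lambda x: x.notna() & (x >= 1), "n_obs must be >= 1")
        if {"patient_id", "lab_id"} <= set(df.columns):
            dupes = df.duplicated(["patient_id", "lab_id"])
            for row in np.flatnonzero(dupes):
                v.append(Violation(int(row), "patient_id",
                                   "at most one record per (patient, lab)"))

    elif schema == "results":
        v += _require_columns(df, ["lab_id", "n", "beta", "se", "ci_low", "ci_high",
                                   "p_value", "direction", "significant",
                                   "skipped_reason"])
        if {"beta", "ci_low", "ci_high"} <= set(df.columns):
            beta, lo, hi = _numeric(df, "beta"), _numeric(df, "ci_low"), _numeric(df, "ci_high")
            bad = beta.notna() & ~((lo <= beta) & (beta <= hi))
            for row in np.flatnonzero(bad):
                v.append(Violation(int(row), "beta", "ci_low <= beta <= ci_high"))
        if {"beta", "direction"} <= set(df.columns):
            beta = _numeric(df, "beta")
            want = np.where(beta > 0, "up", "down")
            bad = beta.notna() & (df["direction"].to_numpy() != want)
            for row in np.flatnonzero(bad):
                v.append(Violation(int(row), "direction", "direction must match sign of beta"))
        if threshold is not None and {"p_value", "significant"} <= set(df.columns):
            p = _numeric(df, "p_value")
            sig = df["significant"].str.casefold() == "true"
            bad = p.notna() & (sig != (p < threshold))
            for row in np.flatnonzero(bad):
                v.append(Violation(int(row), "significant",
                                   f"significant must equal (p_value < {threshold})"))

    return v
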
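"""Reading and writing the delimited-text tables used across the pipeline.

Observation files are read with raw ``value`` and ``unit`` strings preserved
byte-for-byte; only ``age`` is parsed.  Tab is the canonical output dialect;
comma or tab are accepted on input (sniffed from the header line).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

OBSERVATION_FIELDS = ("patient_id", "lab_id", "value", "unit", "age")
CLEAN_TABLE_COLUMNS = (
    "patient_id",
    "lab_id",
    "median_value",
    "age_at_median",
    "n_obs",
    "int_value",
)


def sniff_delimiter(path: str | Path) -> str:
    with open(path, encoding="utf-8", newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_lab_observations(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a long-format observation file into the canonical frame.

    ``column_map`` maps canonical field names (patient_id, lab_id, value,
    unit, age) to the file's column names; omitted fields default to their
    canonical names.  Raw value and unit text is preserved exactly; rows
    with a malformed shape are skipped with a tallied, logged count
    (available as ``df.attrs["n_skipped_rows"]``).

    Raises a configuration error for missing columns and a validation error
    (naming the row) for negative or unparseable ages.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sep or sniff_delimiter(path)
    column_map = {**{f: f for f in OBSERVATION_FIELDS}, **(column_map or {})}

    skipped = 0

    def _bad_line(line):  # pragma: no cover - exercised via malformed fixtures
        nonlocal skipped
        skipped += 1
        return None

    df = pd.read_csv(
        path,
        sep=sep,
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines=_bad_line,
        encoding="utf-8",
    )
    missing = [col for col in column_map.values() if col not in df.columns]
    if missing:
        raise KeyError(f"observation file {path} is missing column(s): {missing}")
    df = df.rename(columns={v: k for k, v in column_map.items()})
    df = df[list(OBSERVATION_FIELDS)]

    age = pd.to_numeric(df["age"], errors="coerce")
    bad_age = age.isna() | (age < 0)
    if bad_age.any():
        row = int(bad_age.idxmax())
        raise ValueError(
            f"invalid age {df['age'].iloc[row]!r} at data row {row} of {path}"
        )
    df["age"] = age.astype(float)

    empty_id = (df["patient_id"].str.len() == 0) | (df["lab_id"].str.len() == 0)
    if empty_id.any():
        row = int(empty_id.idxmax())
        raise ValueError(f"empty patient_id/lab_id at data row {row} of {path}")

    if skipped:
        log.warning("skipped %d unreadable row(s) in %s", skipped, path)
    df.attrs["n_skipped_rows"] = skipped
    return df


def write_clean_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=list(CLEAN_TABLE_COLUMNS))


def read_clean_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "lab_id": str})
    missing = [c for c in CLEAN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"clean table {path} is missing column(s): {missing}")
    return df


def read_keyed_column(path: str | Path, column: str = "value") -> pd.Series:
    """Read a (patient_id, <column>) file into a patient-indexed Series."""
    sep = sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    if column not in df.columns:
        raise KeyError(f"{path} is missing column {column!r}")
    return df.set_index("patient_id")[column]


def read_covariates(path: str | Path) -> pd.DataFrame:
    sep = sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise KeyError(f"covariate file {path} is missing column 'patient_id'")
    return df
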
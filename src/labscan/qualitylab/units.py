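"""Strict numeric parsing of raw lab value strings and unit canonicalization."""

from __future__ import annotations

import re
from collections.abc import Mapping

import numpy as np
import pandas as pd

# Plain decimal / scientific notation only.  Thousands separators,
# underscores, comparator prefixes ("<5") and free text all fail.
_NUMERIC_RE = re.compile(r"^[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?$")
# Tokens that parse as floats but are never valid measurements.
_NONFINITE_RE = re.compile(r"^[+-]?(?:inf(?:inity)?|nan)$", re.IGNORECASE)


def parse_numeric(text: str) -> float | None:
    """Parse ``text`` as a finite number, or return ``None``.

    "inf", "nan" and overflowing exponents are parseable but non-finite
    and therefore rejected, as are comparator-prefixed values ("<5").
    """
    s = text.strip()
    if not _NUMERIC_RE.match(s):
        return None
    value = float(s)
    return value if np.isfinite(value) else None


def numeric_values(values: pd.Series) -> pd.Series:
    """Vectorized :func:`parse_numeric`: float Series, NaN where not numeric."""
    s = values.astype(str).str.strip()
    ok = s.str.match(_NUMERIC_RE)
    out = pd.to_numeric(s.where(ok, other=np.nan), errors="coerce")
    out[~np.isfinite(out)] = np.nan
    return out


def normalize_unit_text(unit: str) -> str:
    return unit.strip().casefold()


class UnitSynonymTable:
    """Mapping from raw unit text to a canonical unit.

    Keys and values are case-folded and whitespace-stripped on
    construction; canonical units always map to themselves.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        table: dict[str, str] = {}
        for raw, canonical in (mapping or {}).items():
            key = normalize_unit_text(raw)
            value = normalize_unit_text(canonical)
            if key in table and table[key] != value:
                raise ValueError(
                    f"unit {key!r} maps to both {table[key]!r} and {value!r}"
                )
            table[key] = value
        for canonical in list(table.values()):
            existing = table.setdefault(canonical, canonical)
            if existing != canonical:
                raise ValueError(
                    f"canonical unit {canonical!r} must map to itself, "
                    f"not {existing!r}"
                )
        self._table = table

    def canonical(self, unit: str) -> str:
        key = normalize_unit_text(unit)
        return self._table.get(key, key)

    def as_dict(self) -> dict[str, str]:
        return dict(self._table)

    def __len__(self) -> int:
        return len(self._table)

    def __eq__(self, other) -> bool:
        return isinstance(other, UnitSynonymTable) and self._table == other._table


def canonicalize_units(
    observations: pd.DataFrame, synonyms: UnitSynonymTable | None = None
) -> pd.DataFrame:
    """Return a copy of ``observations`` with the ``unit`` column canonicalized.

    Unmapped units are not an error; they pass through case-folded and
    stripped, forming their own canonical unit.
    """
    synonyms = synonyms or UnitSynonymTable()
    out = observations.copy()
    units = out["unit"].astype(str).str.strip().str.casefold()
    table = synonyms.as_dict()
    if table:
        units = units.map(lambda u: table.get(u, u))
    out["unit"] = units
    return out
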
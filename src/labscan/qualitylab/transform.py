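"""Rank-based inverse normal quantile transformation."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata


def inverse_normal_transform(values, offset: float = 0.375) -> np.ndarray:
    """Map values to standard-normal quantiles by rank.

    Ties receive their average rank, so tied inputs map to identical
    outputs.  With rank r_i out of n, the transformed value is
    ``ndtri((r_i - offset) / (n - 2*offset + 1))``; the default offset 3/8
    is Blom's.  Rank order is preserved exactly.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if len(arr) == 0:
        raise ValueError("expected at least one value")
    bad = np.flatnonzero(~np.isfinite(arr))
    if len(bad):
        raise ValueError(f"non-finite value at index {bad[0]}")
    ranks = rankdata(arr, method="average")
    n = len(arr)
    return ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))


def add_int_column(
    summaries: pd.DataFrame, offset: float = 0.375, column: str = "int_value"
) -> pd.DataFrame:
    """Apply the transformation per lab to ``median_value``; returns a copy."""
    out = summaries.copy()
    out[column] = np.nan
    for _, idx in out.groupby("lab_id", sort=False).indices.items():
        out.iloc[idx, out.columns.get_loc(column)] = inverse_normal_transform(
            out["median_value"].to_numpy()[idx], offset=offset
        )
    return out
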
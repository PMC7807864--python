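"""Predictor vectors and standardization to mean 0 / SD 1."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def standardize_predictor(values) -> np.ndarray | pd.Series:
    """Scale a continuous vector to mean zero and sample SD one.

    Purely affine, hence rank-preserving.  Raises on a zero-variance input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("expected a 1-D vector with n >= 2")
    sd = float(np.std(arr, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance predictor")
    out = (arr - float(np.mean(arr))) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


@dataclass
class PredictorVector:
    """A per-patient predictor: a continuous score or a 0/1 flag."""

    values: pd.Series  # indexed by patient_id
    kind: str = "continuous"  # "continuous" | "binary"
    standardized: bool = False

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "binary":
            levels = set(pd.unique(self.values.dropna()))
            if not levels <= {0, 1}:
                raise ValueError("binary predictor must take values in {0, 1}")

    @classmethod
    def from_series(cls, values: pd.Series) -> "PredictorVector":
        """Infer kind: values confined to {0, 1} are binary, else continuous."""
        levels = set(pd.unique(values.dropna()))
        kind = "binary" if levels <= {0, 1} and len(levels) <= 2 else "continuous"
        return cls(values=values.astype(float), kind=kind)

    def prepared(self) -> "PredictorVector":
        """Standardize continuous predictors; binary flags pass through as-is."""
        if self.kind == "binary" or self.standardized:
            return self
        return PredictorVector(
            values=standardize_predictor(self.values), kind=self.kind, standardized=True
        )
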
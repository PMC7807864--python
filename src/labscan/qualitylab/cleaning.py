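"""Observation-level filters: numeric/unit stage, single-pass SD filter,
pre-event truncation and patient exclusion."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..config import QCConfig
from .units import numeric_values

log = logging.getLogger(__name__)


@dataclass
class CleaningResult:
    """Cleaned observations of one lab plus a per-stage removal ledger."""

    lab_id: str
    data: pd.DataFrame  # columns of the input plus float column "value_num"
    n_input: int
    removed_non_numeric: int  # stage 1: non-numeric and non-finite values
    removed_non_modal_unit: int  # stage 1: numeric but not in the modal unit
    removed_outlier: int  # stage 2: beyond k SD of the stage-1 survivors
    n_output: int
    mean: float
    sd: float
    empty_after_cleaning: bool

    def counts(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_non_numeric": self.removed_non_numeric,
            "removed_non_modal_unit": self.removed_non_modal_unit,
            "removed_outlier": self.removed_outlier,
            "n_output": self.n_output,
        }


def clean_observations(
    observations: pd.DataFrame,
    config: QCConfig | None = None,
    modal_unit: str | None = None,
) -> CleaningResult:
    """Clean the observations of a single kept lab.

    Stage 1 removes non-numeric / non-finite values and, when
    ``config.keep_modal_unit_only``, observations not in the modal unit.
    Stage 2 computes the mean and sample SD of the stage-1 survivors in a
    single pass and removes values more than ``outlier_sd_multiplier``
    standard deviations from that mean.  The filter is deliberately NOT
    iterated.
    """
    config = config or QCConfig()
    lab_ids = observations["lab_id"].unique()
    if len(lab_ids) > 1:
        raise ValueError("clean_observations expects observations of a single lab")
    lab_id = str(lab_ids[0]) if len(lab_ids) else ""

    values = numeric_values(observations["value"])
    numeric_mask = values.notna().to_numpy()
    n_input = len(observations)
    removed_non_numeric = int(n_input - numeric_mask.sum())

    keep = numeric_mask.copy()
    removed_non_modal = 0
    if config.keep_modal_unit_only and numeric_mask.any():
        units = observations["unit"].to_numpy()
        if modal_unit is None:
            counts = pd.Series(units[numeric_mask]).value_counts()
            top = counts[counts == counts.max()]
            modal_unit = sorted(top.index)[0]
        unit_ok = units == modal_unit
        removed_non_modal = int((numeric_mask & ~unit_ok).sum())
        keep &= unit_ok

    stage1 = observations.loc[keep].copy()
    stage1["value_num"] = values[keep]

    if len(stage1) == 0:
        log.warning("lab %s is empty after stage-1 cleaning; excluded downstream", lab_id)
        return CleaningResult(
            lab_id=lab_id,
            data=stage1,
            n_input=n_input,
            removed_non_numeric=removed_non_numeric,
            removed_non_modal_unit=removed_non_modal,
            removed_outlier=0,
            n_output=0,
            mean=float("nan"),
            sd=float("nan"),
            empty_after_cleaning=True,
        )

    x = stage1["value_num"].to_numpy()
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")
    if np.isfinite(sd):
        inliers = np.abs(x - mean) <= config.outlier_sd_multiplier * sd
    else:
        inliers = np.ones(len(x), dtype=bool)
    removed_outlier = int((~inliers).sum())
    cleaned = stage1.loc[inliers]

    return CleaningResult(
        lab_id=lab_id,
        data=cleaned,
        n_input=n_input,
        removed_non_numeric=removed_non_numeric,
        removed_non_modal_unit=removed_non_modal,
        removed_outlier=removed_outlier,
        n_output=len(cleaned),
        mean=mean,
        sd=sd,
        empty_after_cleaning=len(cleaned) == 0,
    )


def filter_pre_event(
    observations: pd.DataFrame,
    event_ages: pd.Series,
    config: QCConfig | None = None,
) -> pd.DataFrame:
    """Drop observations at or after each patient's first event age.

    ``event_ages`` maps patient_id to the age (years) of the first event
    (e.g., first medication mention).  Patients absent from the series keep
    all observations.  Same-day draws (age == event age) are removed iff
    ``config.same_day_event_excluded``.
    """
    config = config or QCConfig()
    if event_ages.empty:
        return observations.copy()
    if (event_ages.dropna() < 0).any():
        raise ValueError("event ages must be non-negative")
    cutoff = observations["patient_id"].map(event_ages)
    age = observations["age"]
    if config.same_day_event_excluded:
        keep = cutoff.isna() | (age < cutoff)
    else:
        keep = cutoff.isna() | (age <= cutoff)
    removed = int((~keep).sum())
    out = observations.loc[keep].copy()
    out.attrs["n_removed_post_event"] = removed
    log.info("pre-event filter removed %d observations", removed)
    return out


def exclude_patients(
    table: pd.DataFrame, excluded_ids
) -> tuple[pd.DataFrame, int]:
    """Remove every record whose patient_id is in ``excluded_ids``.

    Returns the filtered table and the number of records removed.
    """
    excluded = set(excluded_ids)
    if not excluded:
        return table.copy(), 0
    keep = ~table["patient_id"].isin(excluded)
    n_removed = int((~keep).sum())
    out = table.loc[keep].copy()
    if len(out) == 0 and len(table) > 0:
        log.warning("patient exclusion removed every record")
    return out, n_removed
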
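"""Per-patient median summaries, stratification, and stratum statistics."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..config import StratumSpec

log = logging.getLogger(__name__)


def compute_patient_medians(cleaned: pd.DataFrame) -> pd.DataFrame:
    """Collapse cleaned observations to one record per (patient, lab).

    Observations are ordered by (value, age-at-draw, input order).  For an
    odd count the median is the middle order statistic and the age is that
    observation's age; for an even count the median is the mean of the two
    middle order statistics and the age is the midpoint of those two
    observations' ages.

    ``cleaned`` must carry a float ``value_num`` column (as produced by
    :func:`labscan.qualitylab.clean_observations`).

    Returns columns: patient_id, lab_id, median_value, age_at_median, n_obs.
    """
    if len(cleaned) == 0:
        return pd.DataFrame(
            columns=["patient_id", "lab_id", "median_value", "age_at_median", "n_obs"]
        )
    s = cleaned.reset_index(drop=True).sort_values(
        ["lab_id", "patient_id", "value_num", "age"], kind="stable"
    )
    lab = s["lab_id"].to_numpy()
    pat = s["patient_id"].to_numpy()
    val = s["value_num"].to_numpy(dtype=float)
    age = s["age"].to_numpy(dtype=float)

    new_group = np.ones(len(s), dtype=bool)
    new_group[1:] = (lab[1:] != lab[:-1]) | (pat[1:] != pat[:-1])
    starts = np.flatnonzero(new_group)
    sizes = np.diff(np.append(starts, len(s)))
    lo = starts + (sizes - 1) // 2
    hi = starts + sizes // 2

    return pd.DataFrame(
        {
            "patient_id": pat[starts],
            "lab_id": lab[starts],
            "median_value": (val[lo] + val[hi]) / 2.0,
            "age_at_median": (age[lo] + age[hi]) / 2.0,
            "n_obs": sizes,
        }
    )


def stratify(
    observations: pd.DataFrame,
    demographics: pd.DataFrame,
    spec: StratumSpec,
) -> dict[tuple[str, str, str], pd.DataFrame]:
    """Split observations into one subset per (sex, age group, race) cell.

    Pooled levels (``spec.pooled_label``) are included for every factor, so
    the number of subsets is (|sex|+1) x (|age groups|+1) x (|race|+1).
    Age-group membership is decided per observation from ``age`` against
    half-open [lo, hi) intervals.  Observations whose age falls outside all
    non-pooled groups appear only in pooled-age cells (counted and logged).

    ``demographics`` must have columns patient_id, sex, race.
    """
    spec.validate()
    demo = demographics.set_index("patient_id")
    missing = set(observations["patient_id"]) - set(demo.index)
    if missing:
        raise ValueError(
            f"{len(missing)} patient(s) lack demographics, e.g. {sorted(missing)[:3]}"
        )
    sex = observations["patient_id"].map(demo["sex"]).to_numpy()
    race = observations["patient_id"].map(demo["race"]).to_numpy()
    age = observations["age"].to_numpy(dtype=float)

    pooled = spec.pooled_label
    age_masks: dict[str, np.ndarray] = {pooled: np.ones(len(observations), dtype=bool)}
    assigned = np.zeros(len(observations), dtype=bool)
    for label, lo, hi in spec.age_groups:
        mask = (age >= lo) & (age < hi)
        age_masks[label] = mask
        assigned |= mask
    n_unassigned = int((~assigned).sum())
    if n_unassigned:
        log.warning(
            "%d observation(s) fall outside all non-pooled age groups; "
            "they appear only in pooled-age subsets",
            n_unassigned,
        )

    sex_masks = {pooled: np.ones(len(observations), dtype=bool)}
    for level in spec.sex_levels:
        sex_masks[level] = sex == level
    race_masks = {pooled: np.ones(len(observations), dtype=bool)}
    for level in spec.race_levels:
        race_masks[level] = race == level

    subsets: dict[tuple[str, str, str], pd.DataFrame] = {}
    for s_level, s_mask in sex_masks.items():
        for a_level, a_mask in age_masks.items():
            for r_level, r_mask in race_masks.items():
                subsets[(s_level, a_level, r_level)] = observations.loc[
                    s_mask & a_mask & r_mask
                ]
    return subsets


def summarize_stratum(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-lab descriptive statistics of the median lab value in one stratum.

    ``summaries`` holds per-patient records (as from
    :func:`compute_patient_medians`).  Returns one row per lab with
    n_patients, mean, sd (sample), min, quartiles, max.  An empty input
    yields an empty frame; single-record labs have an undefined (NaN) sd.
    """
    cols = ["lab_id", "n_patients", "mean", "sd", "min", "q25", "median", "q75", "max"]
    if len(summaries) == 0:
        return pd.DataFrame(columns=cols)
    g = summaries.groupby("lab_id", sort=True)["median_value"]
    out = pd.DataFrame(
        {
            "n_patients": g.size(),
            "mean": g.mean(),
            "sd": g.std(ddof=1),
            "min": g.min(),
            "q25": g.quantile(0.25),
            "median": g.quantile(0.50),
            "q75": g.quantile(0.75),
            "max": g.max(),
        }
    ).reset_index()
    return out[cols]
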
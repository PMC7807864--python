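"""Per-lab catalog profiling and the quantitative-lab selection filters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import QCConfig
from .units import numeric_values

#: Fixed order in which drop reasons are assembled (never short-circuited).
DROP_REASON_ORDER = (
    "non_numeric_only",
    "single_patient",
    "unit_discordant",
    "too_few_patients",
    "too_few_observations",
)


@dataclass
class LabCatalogProfile:
    """QC summary for one lab; ``decision`` is unset until selection runs."""

    lab_id: str
    n_observations_total: int
    n_numeric_observations: int
    n_patients: int
    unit_counts: dict[str, int]
    modal_unit: str | None
    modal_unit_fraction: float
    decision: str | None = None
    drop_reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "lab_id": self.lab_id,
            "n_observations_total": self.n_observations_total,
            "n_numeric_observations": self.n_numeric_observations,
            "n_patients": self.n_patients,
            "unit_counts": dict(self.unit_counts),
            "modal_unit": self.modal_unit,
            "modal_unit_fraction": (
                None if np.isnan(self.modal_unit_fraction) else self.modal_unit_fraction
            ),
            "decision": self.decision,
            "drop_reasons": list(self.drop_reasons),
        }


def profile_labs(observations: pd.DataFrame) -> dict[str, LabCatalogProfile]:
    """Build a :class:`LabCatalogProfile` for every lab_id in ``observations``.

    Numeric-ness is decided by a strict decimal/scientific parse; infinite
    values do not count as numeric.  Unit statistics are computed over
    numeric observations only; patient counts cover all observations.
    Units are expected to be canonicalized already.
    """
    obs = observations
    values = numeric_values(obs["value"])
    is_num = values.notna()

    totals = obs.groupby("lab_id", sort=True).size()
    patients = obs.groupby("lab_id", sort=True)["patient_id"].nunique()
    numeric = obs.loc[is_num]
    n_numeric = numeric.groupby("lab_id").size()

    # unit counts over numeric observations; modal unit = highest count,
    # ties broken lexicographically for determinism
    uc = (
        numeric.groupby(["lab_id", "unit"], sort=True)
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["lab_id", "count", "unit"], ascending=[True, False, True],
                     kind="stable")
    )
    modal = uc.drop_duplicates("lab_id").set_index("lab_id")
    unit_counts_by_lab: dict[str, dict[str, int]] = {
        lab: dict(zip(g["unit"], g["count"])) for lab, g in uc.groupby("lab_id")
    }

    profiles: dict[str, LabCatalogProfile] = {}
    for lab_id in totals.index:
        n_num = int(n_numeric.get(lab_id, 0))
        counts = unit_counts_by_lab.get(lab_id, {})
        if n_num > 0:
            modal_unit = str(modal.loc[lab_id, "unit"])
            fraction = float(modal.loc[lab_id, "count"]) / float(sum(counts.values()))
        else:
            modal_unit, fraction = None, float("nan")
        profiles[str(lab_id)] = LabCatalogProfile(
            lab_id=str(lab_id),
            n_observations_total=int(totals[lab_id]),
            n_numeric_observations=n_num,
            n_patients=int(patients[lab_id]),
            unit_counts=counts,
            modal_unit=modal_unit,
            modal_unit_fraction=fraction,
        )
    return profiles


def select_quantitative_labs(
    profiles: dict[str, LabCatalogProfile], config: QCConfig | None = None
) -> dict[str, LabCatalogProfile]:
    """Set keep/drop decisions on every profile.

    All applicable drop reasons are recorded in :data:`DROP_REASON_ORDER`;
    thresholds are inclusive (fraction >= min, counts >= min).
    Returns the same mapping for convenience.
    """
    config = config or QCConfig()
    config.validate()
    for profile in profiles.values():
        reasons = []
        if profile.n_numeric_observations == 0:
            reasons.append("non_numeric_only")
        if profile.n_patients == 1:
            reasons.append("single_patient")
        if (
            profile.n_numeric_observations > 0
            and profile.modal_unit_fraction < config.min_modal_unit_fraction
        ):
            reasons.append("unit_discordant")
        if profile.n_patients < config.min_patients:
            reasons.append("too_few_patients")
        if profile.n_numeric_observations < config.min_numeric_observations:
            reasons.append("too_few_observations")
        profile.drop_reasons = reasons
        profile.decision = "keep" if not reasons else "drop"
    return profiles


def kept_labs(profiles: dict[str, LabCatalogProfile]) -> list[str]:
    return sorted(lab for lab, p in profiles.items() if p.decision == "keep")
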
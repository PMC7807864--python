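"""End-to-end cleaning: catalog filters, observation filters, medians, INT."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ..config import QCConfig
from .catalog import LabCatalogProfile, kept_labs, profile_labs, select_quantitative_labs
from .cleaning import CleaningResult, clean_observations, exclude_patients, filter_pre_event
from .summarize import compute_patient_medians
from .transform import add_int_column
from .units import UnitSynonymTable, canonicalize_units

log = logging.getLogger(__name__)


@dataclass
class QualityLabResult:
    """Clean per-patient table plus the full QC audit trail."""

    clean_table: pd.DataFrame
    profiles: dict[str, LabCatalogProfile]
    cleaning: dict[str, CleaningResult]
    n_removed_post_event: int
    n_excluded_patient_records: int
    config: QCConfig
    empty_labs: list[str] = field(default_factory=list)

    def report(self) -> dict:
        """JSON-serializable QC report with config echo for provenance."""
        return {
            "config": {
                "min_modal_unit_fraction": self.config.min_modal_unit_fraction,
                "min_patients": self.config.min_patients,
                "min_numeric_observations": self.config.min_numeric_observations,
                "outlier_sd_multiplier": self.config.outlier_sd_multiplier,
                "int_offset": self.config.int_offset,
                "keep_modal_unit_only": self.config.keep_modal_unit_only,
                "same_day_event_excluded": self.config.same_day_event_excluded,
            },
            "n_labs_total": len(self.profiles),
            "n_labs_kept": sum(p.decision == "keep" for p in self.profiles.values()),
            "n_removed_post_event": self.n_removed_post_event,
            "n_excluded_patient_records": self.n_excluded_patient_records,
            "empty_after_cleaning": list(self.empty_labs),
            "labs": {lab: p.to_dict() for lab, p in self.profiles.items()},
            "cleaning": {lab: r.counts() for lab, r in self.cleaning.items()},
        }


def run_qualitylab(
    observations: pd.DataFrame,
    config: QCConfig | None = None,
    synonyms: UnitSynonymTable | None = None,
    event_ages: pd.Series | None = None,
    exclude_ids=None,
) -> QualityLabResult:
    """Run the full cleaning cascade on a raw observation frame.

    Order of operations: unit canonicalization -> catalog profiling and
    quantitative-lab selection -> optional pre-event truncation -> per-lab
    observation cleaning -> per-patient medians -> optional patient
    exclusion -> per-lab inverse normal transformation.
    """
    config = config or QCConfig()
    config.validate()

    obs = canonicalize_units(observations, synonyms)
    profiles = select_quantitative_labs(profile_labs(obs), config)
    keep = kept_labs(profiles)
    log.info("catalog filters kept %d of %d labs", len(keep), len(profiles))

    obs = obs[obs["lab_id"].isin(keep)]
    n_removed_post_event = 0
    if event_ages is not None and len(event_ages):
        obs = filter_pre_event(obs, event_ages, config)
        n_removed_post_event = obs.attrs.get("n_removed_post_event", 0)

    cleaning: dict[str, CleaningResult] = {}
    summaries = []
    empty_labs = []
    for lab_id, lab_obs in obs.groupby("lab_id", sort=True):
        result = clean_observations(lab_obs, config,
                                    modal_unit=profiles[str(lab_id)].modal_unit)
        cleaning[str(lab_id)] = result
        if result.empty_after_cleaning:
            empty_labs.append(str(lab_id))
            continue
        summaries.append(compute_patient_medians(result.data))

    if summaries:
        table = pd.concat(summaries, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["patient_id", "lab_id", "median_value", "age_at_median", "n_obs"]
        )

    n_excluded = 0
    if exclude_ids is not None:
        table, n_excluded = exclude_patients(table, exclude_ids)

    if len(table):
        table = add_int_column(table, offset=config.int_offset)
        table = table.sort_values(["lab_id", "patient_id"], kind="stable").reset_index(
            drop=True
        )
    else:
        table["int_value"] = pd.Series(dtype=float)

    return QualityLabResult(
        clean_table=table,
        profiles=profiles,
        cleaning=cleaning,
        n_removed_post_event=n_removed_post_event,
        n_excluded_patient_records=n_excluded,
        config=config,
        empty_labs=empty_labs,
    )
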
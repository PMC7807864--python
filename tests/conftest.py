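import numpy as np
import pandas as pd
import pytest

from labscan.config import QCConfig, ScanConfig
from labscan.labwas import run_labwas
from labscan.qualitylab import run_qualitylab
from labscan.synthdata import (
    GeneratorConfig,
    generate_cohort,
    generate_observations,
)

# 17 null labs plus one lab per nonzero effect
RECOVERY_EFFECTS = {f"lab{i:02d}": 0.0 for i in range(1, 18)}
RECOVERY_EFFECTS.update({"lab18": 0.05, "lab19": 0.10, "lab20": 0.30})


def run_recovery_replicate(seed: int, n_patients: int = 5000) -> dict:
    """One full synth -> clean -> INT -> scan replicate; returns per-lab
    (beta, significant) plus the scan threshold."""
    config = GeneratorConfig.simple(
        n_patients,
        RECOVERY_EFFECTS,
        mean_obs=2.0,
        noise_sd=0.1,
        rate_non_numeric=0.01,
        rate_outlier=0.005,
        n_pcs=4,
    )
    cohort = generate_cohort(config, seed)
    observations, truth = generate_observations(cohort, config, seed)
    cleaned = run_qualitylab(observations, QCConfig(), synonyms=truth.synonyms)
    result = run_labwas(
        cleaned.clean_table,
        cohort.predictor,
        cohort.covariates,
        config=ScanConfig(min_n=100),
    )
    out = {r.lab_id: (r.beta, r.significant) for r in result.records}
    out["_threshold"] = result.threshold
    return out


@pytest.fixture(scope="session")
def recovery_simulation():
    """100 seeded full-pipeline replicates at 5000 patients x 20 labs."""
    return [run_recovery_replicate(1000 + i) for i in range(100)]


@pytest.fixture
def small_observations() -> pd.DataFrame:
    """Two labs, hand-written: one numeric multi-patient, one non-numeric."""
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2", "p2", "p3", "p1", "p2"],
            "lab_id": ["glucose"] * 5 + ["culture"] * 2,
            "value": ["5.1", "4.9", "6.0", "5.5", "5.0", "positive", "negative"],
            "unit": ["mg/dl"] * 5 + ["", ""],
            "age": [40.0, 41.0, 50.0, 51.0, 60.0, 45.0, 55.0],
        }
    )


@pytest.fixture(scope="session")
def generated_cohort():
    """Medium synthetic cohort with contamination, shared across tests."""
    config = GeneratorConfig.simple(
        400,
        {"alab": 0.3, "blab": 0.0, "clab": -0.2},
        mean_obs=5.0,
        rate_non_numeric=0.05,
        rate_infinite=0.02,
        rate_outlier=0.02,
        n_pcs=3,
    )
    cohort = generate_cohort(config, 42)
    observations, truth = generate_observations(cohort, config, 42)
    return config, cohort, observations, truth


def make_clean_table(labs: dict[str, np.ndarray], patient_ids) -> pd.DataFrame:
    """Assemble a per-patient INT table directly (bypassing the cleaner)."""
    frames = []
    for lab_id, y in labs.items():
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids[: len(y)],
                    "lab_id": lab_id,
                    "median_value": y,
                    "age_at_median": 50.0,
                    "n_obs": 1,
                    "int_value": y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
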
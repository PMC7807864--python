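import numpy as np
import pandas as pd
import pytest

from labscan.config import QCConfig
from labscan.qualitylab import numeric_values, run_qualitylab
from labscan.synthdata import (
    CohortSpec,
    GeneratorConfig,
    LabSpec,
    MedicationSpec,
    expected_pipeline_counts,
    generate_cohort,
    generate_observations,
)


def test_same_seed_is_byte_identical():
    config = GeneratorConfig.simple(200, {"a": 0.2, "b": 0.0}, rate_non_numeric=0.05)
    runs = []
    for _ in range(2):
        cohort = generate_cohort(config, 99)
        obs, truth = generate_observations(cohort, config, 99)
        runs.append((cohort, obs, truth))
    c1, o1, t1 = runs[0]
    c2, o2, t2 = runs[1]
    assert o1.to_csv() == o2.to_csv()
    assert c1.covariates.to_csv() == c2.covariates.to_csv()
    assert t1.ledger.to_csv() == t2.ledger.to_csv()


def test_patient_count_is_exact():
    config = GeneratorConfig.simple(1000, {"a": 0.0})
    cohort = generate_cohort(config, 0)
    assert len(cohort.demographics) == 1000
    assert len(cohort.covariates) == 1000
    assert len(cohort.predictor) == 1000


def test_null_effects_give_null_correlations():
    n = 2000
    config = GeneratorConfig.simple(n, {f"lab{i}": 0.0 for i in range(5)})
    cohort = generate_cohort(config, 123)
    g = cohort.predictor.to_numpy()
    for lab in cohort.liabilities.columns:
        r = np.corrcoef(g, cohort.liabilities[lab])[0, 1]
        assert abs(r) < 3 / np.sqrt(n)


def test_effects_induce_configured_correlation():
    n = 4000
    config = GeneratorConfig.simple(n, {"hot": 0.5, "cold": 0.0})
    cohort = generate_cohort(config, 7)
    g = cohort.predictor.to_numpy()
    r = np.corrcoef(g, cohort.liabilities["hot"])[0, 1]
    assert r == pytest.approx(0.5, abs=3 / np.sqrt(n))


def test_zero_contamination_means_all_numeric():
    config = GeneratorConfig.simple(100, {"a": 0.0})
    cohort = generate_cohort(config, 5)
    obs, truth = generate_observations(cohort, config, 5)
    assert numeric_values(obs["value"]).notna().all()
    assert (truth.ledger["label"] == "clean").all()


def test_non_numeric_rate_is_binomial():
    config = GeneratorConfig.simple(
        1000, {"a": 0.0}, mean_obs=10.0, rate_non_numeric=0.1
    )
    cohort = generate_cohort(config, 21)
    obs, truth = generate_observations(cohort, config, 21)
    n = len(obs)
    assert n >= 9000
    count = int((truth.ledger["label"] == "non_numeric").sum())
    sigma = np.sqrt(n * 0.1 * 0.9)
    assert abs(count - 0.1 * n) <= 3 * sigma
    # and the pipeline sees exactly what the ledger says
    parsed = numeric_values(obs["value"])
    assert int(parsed.isna().sum()) == count + int(
        (truth.ledger["label"] == "infinite").sum()
    )


def test_single_patient_lab_is_dropped_by_oracle_and_pipeline():
    config = GeneratorConfig(
        labs=[LabSpec(lab_id="solo")],
        cohort=CohortSpec(n_patients=1, n_pcs=0),
    )
    cohort = generate_cohort(config, 3)
    obs, truth = generate_observations(cohort, config, 3)
    oracle = expected_pipeline_counts(obs, truth, QCConfig())
    assert oracle["solo"]["decision"] == "drop"
    assert "single_patient" in oracle["solo"]["drop_reasons"]
    result = run_qualitylab(obs, QCConfig(), synonyms=truth.synonyms)
    assert result.profiles["solo"].drop_reasons == oracle["solo"]["drop_reasons"]


def test_ledger_conservation():
    config = GeneratorConfig.simple(
        300, {"a": 0.1, "b": 0.0}, rate_non_numeric=0.05, rate_infinite=0.02,
        rate_outlier=0.03,
    )
    cohort = generate_cohort(config, 8)
    obs, truth = generate_observations(cohort, config, 8)
    assert len(truth.ledger) == len(obs)  # every observation classified once
    assert set(truth.ledger["label"]) <= {"clean", "non_numeric", "infinite", "outlier"}
    pd.testing.assert_series_equal(
        truth.ledger["patient_id"], obs["patient_id"], check_names=False
    )


def test_oracle_equals_pipeline_on_default_fixture(generated_cohort):
    """The brute-force ledger oracle predicts every QC decision and stage
    count that the cleaning pipeline reports."""
    _, _, observations, truth = generated_cohort
    qc = QCConfig(min_patients=50, min_numeric_observations=100)
    oracle = expected_pipeline_counts(observations, truth, qc)
    result = run_qualitylab(observations, qc, synonyms=truth.synonyms)
    assert set(oracle) == set(result.profiles)
    for lab_id, expected in oracle.items():
        profile = result.profiles[lab_id]
        assert profile.decision == expected["decision"], lab_id
        assert profile.drop_reasons == expected["drop_reasons"], lab_id
        assert profile.n_numeric_observations == expected["n_numeric_observations"]
        assert profile.n_patients == expected["n_patients"]
        if expected["decision"] == "keep":
            counts = result.cleaning[lab_id].counts()
            assert counts["removed_non_numeric"] == expected["removed_non_numeric"]
            assert counts["removed_non_modal_unit"] == expected["removed_non_modal_unit"]
            assert counts["removed_outlier"] == expected["removed_outlier"]
            assert counts["n_output"] == expected["n_output"]


def test_all_clean_fixture_has_zero_removals():
    config = GeneratorConfig.simple(150, {"a": 0.0}, mean_obs=3.0, noise_sd=0.05)
    cohort = generate_cohort(config, 30)
    obs, truth = generate_observations(cohort, config, 30)
    qc = QCConfig(min_patients=50, min_numeric_observations=100)
    oracle = expected_pipeline_counts(obs, truth, qc)["a"]
    result = run_qualitylab(obs, qc, synonyms=truth.synonyms)
    counts = result.cleaning["a"].counts()
    # oracle agrees with the pipeline no matter what ...
    assert counts["removed_outlier"] == oracle["removed_outlier"]
    # ... and for this seed nothing genuine strays past the fence
    assert counts["removed_non_numeric"] == 0
    assert counts["removed_non_modal_unit"] == 0
    assert counts["removed_outlier"] == 0


def test_injected_gross_outliers_are_all_removed():
    """One 12-SD value per lab forces exactly one stage-2 removal per lab."""
    config = GeneratorConfig.simple(
        400, {f"lab{i}": 0.0 for i in range(4)}, mean_obs=3.0
    )
    cohort = generate_cohort(config, 44)
    obs, truth = generate_observations(cohort, config, 44)
    obs, ledger = obs.copy(), truth.ledger.copy()
    for lab_id, idx in obs.groupby("lab_id").indices.items():
        row = idx[0]
        obs.loc[row, "value"] = f"{100.0 + 12.0 * 10.0:.9g}"
        ledger.loc[row, "label"] = "outlier"
        ledger.loc[row, "true_value"] = 100.0 + 12.0 * 10.0
    truth.ledger = ledger
    qc = QCConfig(min_patients=50, min_numeric_observations=100)
    result = run_qualitylab(obs, qc, synonyms=truth.synonyms)
    oracle = expected_pipeline_counts(obs, truth, qc)
    total_removed = sum(r.counts()["removed_outlier"] for r in result.cleaning.values())
    assert total_removed == 4
    for lab_id in result.cleaning:
        assert result.cleaning[lab_id].counts()["removed_outlier"] == \
            oracle[lab_id]["removed_outlier"] == 1


def test_event_shift_applies_at_and_after_event_age():
    config = GeneratorConfig(
        labs=[LabSpec(lab_id="ldl", event_shift=-2.0, noise_sd=0.0, mean_obs=6.0)],
        cohort=CohortSpec(n_patients=50, n_pcs=0),
        medication=MedicationSpec(fraction=1.0, mode="random"),
    )
    cohort = generate_cohort(config, 9)
    obs, truth = generate_observations(cohort, config, 9)
    values = numeric_values(obs["value"])
    event = obs["patient_id"].map(truth.event_ages)
    latent = obs["patient_id"].map(
        cohort.liabilities["ldl"]
    ) * 10.0 + 100.0  # default location/scale
    post = obs["age"] >= event
    np.testing.assert_allclose(values[post], latent[post] - 20.0, rtol=1e-6)
    np.testing.assert_allclose(values[~post], latent[~post], rtol=1e-6)


def test_invalid_config_lists_violations():
    config = GeneratorConfig(
        labs=[LabSpec(lab_id="x", rate_non_numeric=1.5, patient_fraction=2.0)],
        cohort=CohortSpec(n_patients=0),
    )
    with pytest.raises(ValueError) as err:
        config.validate()
    message = str(err.value)
    assert "rate_non_numeric" in message
    assert "patient_fraction" in message
    assert "n_patients" in message


def test_config_round_trip():
    config = GeneratorConfig.simple(
        50, {"a": 0.2, "b": 0.0}, rate_non_numeric=0.05, event_fraction=0.3,
        event_mode="predictor_top", event_shift_labs={"a": -1.0},
    )
    rebuilt = GeneratorConfig.from_dict(config.to_dict())
    assert rebuilt == config
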
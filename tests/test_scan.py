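import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from labscan.config import ScanConfig
from labscan.labwas import (
    bonferroni_threshold,
    fit_single_lab,
    run_labwas,
)

from conftest import make_clean_table


def covariate_frame(n, rng, n_pcs=2):
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "sex": rng.choice(["F", "M"], size=n),
            "median_age": rng.uniform(20, 80, size=n),
        }
    )
    for k in range(n_pcs):
        df[f"pc{k + 1}"] = rng.standard_normal(n)
    return df


# --- bonferroni -----------------------------------------------------------

def test_bonferroni_paper_family():
    t = bonferroni_threshold(315, 4, 0.05)
    assert t == 0.05 / 1260
    assert f"{t:.3g}" == "3.97e-05"


@pytest.mark.parametrize(
    "n_labs,n_scans,alpha,expected",
    [(1, 1, 0.05, 0.05), (100, 1, 0.05, 5e-4), (10, 2, 0.01, 5e-4)],
)
def test_bonferroni_arithmetic(n_labs, n_scans, alpha, expected):
    assert bonferroni_threshold(n_labs, n_scans, alpha) == pytest.approx(expected)


def test_bonferroni_rejects_bad_input():
    with pytest.raises(ValueError):
        bonferroni_threshold(0, 1, 0.05)
    with pytest.raises(ValueError):
        bonferroni_threshold(10, 1, 1.5)


# --- fit_single_lab -------------------------------------------------------

def test_perfect_fit():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(10)
    X = np.column_stack([np.ones(10), x])
    record = fit_single_lab("lab", x.copy(), X)
    assert record.beta == pytest.approx(1.0, abs=1e-12)
    resid = x - X @ np.array([0.0, 1.0])
    assert float(resid @ resid) == pytest.approx(0.0, abs=1e-20)
    assert record.direction == "up"


def test_matches_statsmodels_oracle_on_random_designs():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n, p = 50, 4
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        y = rng.standard_normal(n)
        record = fit_single_lab("lab", y, X)
        fit = sm.OLS(y, X).fit()
        assert record.beta == pytest.approx(fit.params[1], rel=1e-8)
        assert record.se == pytest.approx(fit.bse[1], rel=1e-8)
        assert record.p_value == pytest.approx(fit.pvalues[1], rel=1e-8, abs=1e-300)
        lo, hi = fit.conf_int()[1]
        assert record.ci_low == pytest.approx(lo, rel=1e-8)
        assert record.ci_high == pytest.approx(hi, rel=1e-8)


def test_matches_normal_equations_oracle():
    rng = np.random.default_rng(8)
    n, p = 60, 5
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    y = X @ rng.standard_normal(p) + rng.standard_normal(n)
    record = fit_single_lab("lab", y, X)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - p)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    assert record.beta == pytest.approx(beta[1], rel=1e-10)
    assert record.se == pytest.approx(se[1], rel=1e-10)


def test_rank_deficient_design_is_skipped():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(30)
    X = np.column_stack([np.ones(30), x, 2 * x])
    record = fit_single_lab("lab", rng.standard_normal(30), X)
    assert record.skipped_reason == "degenerate_fit"


def test_type_one_error_under_null():
    """Monte-Carlo: ~5% rejections at alpha 0.05 under independence."""
    rng = np.random.default_rng(10)
    n, reps = 500, 2000
    rejections = 0
    for _ in range(reps):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        if fit_single_lab("lab", y, X).p_value < 0.05:
            rejections += 1
    assert 0.04 <= rejections / reps <= 0.06


def test_ci_coverage_of_true_effect():
    rng = np.random.default_rng(11)
    n, reps, effect = 300, 400, 0.1
    covered = 0
    for _ in range(reps):
        x = rng.standard_normal(n)
        y = effect * x + np.sqrt(1 - effect**2) * rng.standard_normal(n)
        record = fit_single_lab("lab", y, np.column_stack([np.ones(n), x]))
        covered += record.ci_low <= effect <= record.ci_high
    assert 0.91 <= covered / reps <= 0.99


# --- run_labwas -----------------------------------------------------------

def test_parameter_recovery_on_generator_truth():
    rng = np.random.default_rng(12)
    n = 2000
    g = rng.standard_normal(n)
    gz = (g - g.mean()) / g.std(ddof=1)
    labs = {}
    for i in range(20):
        eff = 0.3 if i == 0 else 0.0
        labs[f"lab{i:02d}"] = eff * gz + np.sqrt(1 - eff**2) * rng.standard_normal(n)
    cov = covariate_frame(n, rng)
    table = make_clean_table(labs, cov["patient_id"].to_numpy())
    predictor = pd.Series(g, index=cov["patient_id"].to_numpy())
    result = run_labwas(table, predictor, cov, config=ScanConfig())
    by_lab = {r.lab_id: r for r in result.records}
    assert by_lab["lab00"].significant
    assert by_lab["lab00"].ci_low <= 0.3 <= by_lab["lab00"].ci_high
    assert result.n_labs_tested == 20
    assert result.threshold == pytest.approx(0.05 / 20)


def test_small_lab_skipped_with_reason():
    rng = np.random.default_rng(13)
    n = 300
    cov = covariate_frame(n, rng)
    ids = cov["patient_id"].to_numpy()
    labs = {
        "big": rng.standard_normal(n),
        "small": rng.standard_normal(99),  # first 99 patients only
    }
    table = make_clean_table(labs, ids)
    predictor = pd.Series(rng.standard_normal(n), index=ids)
    result = run_labwas(table, predictor, cov, config=ScanConfig())
    by_lab = {r.lab_id: r for r in result.records}
    assert by_lab["small"].skipped_reason == "too_few_patients"
    assert by_lab["small"].n == 99
    assert by_lab["big"].tested
    assert result.n_labs_tested == 1  # skipped labs are excluded from the denominator
    assert result.threshold == pytest.approx(0.05)


def test_allowlist_restricts_labs():
    rng = np.random.default_rng(14)
    n = 150
    cov = covariate_frame(n, rng)
    ids = cov["patient_id"].to_numpy()
    labs = {f"lab{i:02d}": rng.standard_normal(n) for i in range(20)}
    table = make_clean_table(labs, ids)
    predictor = pd.Series(rng.standard_normal(n), index=ids)
    allow = [f"lab{i:02d}" for i in range(5)]
    result = run_labwas(table, predictor, cov, allowlist=allow, config=ScanConfig())
    assert len(result.records) == 5
    assert sorted(r.lab_id for r in result.records) == allow


def test_empty_patient_intersection_is_an_error():
    rng = np.random.default_rng(15)
    cov = covariate_frame(120, rng)
    ids = cov["patient_id"].to_numpy()
    table = make_clean_table({"lab": rng.standard_normal(120)}, ids)
    predictor = pd.Series(rng.standard_normal(3), index=["q1", "q2", "q3"])
    with pytest.raises(ValueError, match="shared"):
        run_labwas(table, predictor, cov, config=ScanConfig())


def test_predictor_affine_invariance():
    """Rescaling the continuous predictor changes nothing after standardization."""
    rng = np.random.default_rng(16)
    n = 400
    cov = covariate_frame(n, rng)
    ids = cov["patient_id"].to_numpy()
    g = rng.standard_normal(n)
    y = 0.2 * g + rng.standard_normal(n)
    table = make_clean_table({"lab": y}, ids)
    r1 = run_labwas(table, pd.Series(g, index=ids), cov, config=ScanConfig())
    r2 = run_labwas(table, pd.Series(5.0 - 3.0 * g, index=ids), cov,
                    config=ScanConfig())
    a, b = r1.records[0], r2.records[0]
    assert abs(a.beta) == pytest.approx(abs(b.beta), rel=1e-12)
    assert a.se == pytest.approx(b.se, rel=1e-12)
    assert a.p_value == pytest.approx(b.p_value, rel=1e-12)


def test_binary_predictor_used_as_is():
    rng = np.random.default_rng(17)
    n = 500
    cov = covariate_frame(n, rng)
    ids = cov["patient_id"].to_numpy()
    flag = (rng.random(n) < 0.4).astype(float)
    y = 0.5 * flag + rng.standard_normal(n)
    table = make_clean_table({"lab": y}, ids)
    result = run_labwas(table, pd.Series(flag, index=ids), cov, config=ScanConfig())
    # beta is the group contrast, not per-SD
    assert result.records[0].beta == pytest.approx(0.5, abs=0.2)


def test_extra_adjustment_column():
    rng = np.random.default_rng(18)
    n = 400
    cov = covariate_frame(n, rng)
    cov["diagnosis"] = (rng.random(n) < 0.2).astype(float)
    ids = cov["patient_id"].to_numpy()
    table = make_clean_table({"lab": rng.standard_normal(n)}, ids)
    result = run_labwas(
        table, pd.Series(rng.standard_normal(n), index=ids), cov,
        config=ScanConfig(extra_covariates=["diagnosis"]),
    )
    assert "diagnosis" in result.covariate_names


def test_scan_is_deterministic():
    rng = np.random.default_rng(19)
    n = 250
    cov = covariate_frame(n, rng)
    ids = cov["patient_id"].to_numpy()
    labs = {f"lab{i}": rng.standard_normal(n) for i in range(5)}
    table = make_clean_table(labs, ids)
    predictor = pd.Series(rng.standard_normal(n), index=ids)
    f1 = run_labwas(table, predictor, cov, config=ScanConfig()).to_frame()
    f2 = run_labwas(table, predictor, cov, config=ScanConfig()).to_frame()
    assert f1.to_csv() == f2.to_csv()


def test_family_wise_control_under_global_null():
    """With 200 null labs, at most ~5% of scans flag anything."""
    rng = np.random.default_rng(20)
    n, n_labs, reps = 50, 200, 500
    cov = covariate_frame(n, rng, n_pcs=0)
    ids = cov["patient_id"].to_numpy()
    config = ScanConfig(min_n=30)
    flagged_scans = 0
    for _ in range(reps):
        labs = {f"lab{i:03d}": rng.standard_normal(n) for i in range(n_labs)}
        table = make_clean_table(labs, ids)
        predictor = pd.Series(rng.standard_normal(n), index=ids)
        result = run_labwas(table, predictor, cov, config=config)
        flagged_scans += any(r.significant for r in result.records)
    assert flagged_scans / reps <= 0.07
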
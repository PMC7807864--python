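"""Per-lab linear-model association scan with Bonferroni control.

Each retained lab's inverse-normal-transformed median values are regressed
on a standardized predictor plus covariates (sex, a natural cubic spline of
median record age, principal components, optional extra adjustments).
Effects are reported per SD of a continuous predictor with t-based
two-sided p-values and 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import stdtr, stdtrit

from ..config import ScanConfig
from .predictor import PredictorVector
from .spline import build_spline_basis


def bonferroni_threshold(n_labs: int, n_scans: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / (n_labs * n_scans)."""
    if n_labs < 1 or n_scans < 1:
        raise ValueError("n_labs and n_scans must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / (n_labs * n_scans)


@dataclass
class AssociationRecord:
    """Scan result for one lab."""

    lab_id: str
    n: int
    beta: float = float("nan")
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    direction: str = ""  # "up" | "down"
    significant: bool = False
    skipped_reason: str | None = None  # "too_few_patients" | "degenerate_fit"
    category: str = ""

    @property
    def tested(self) -> bool:
        return self.skipped_reason is None


def fit_single_lab(
    lab_id: str,
    y: np.ndarray,
    X: np.ndarray,
    predictor_column: int = 1,
    ci_level: float = 0.95,
) -> AssociationRecord:
    """Ordinary least squares of y on a design X whose given column is the
    predictor of interest.

    Returns the predictor coefficient, its standard error, t-based two-sided
    p-value and confidence interval with residual degrees of freedom.
    A rank-deficient design or non-positive residual df yields
    ``skipped_reason = "degenerate_fit"``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != len(y):
        raise ValueError("y and X have incompatible shapes")
    if n <= p:
        return AssociationRecord(lab_id=lab_id, n=n, skipped_reason="degenerate_fit")

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= np.finfo(float).eps * max(n, p) * max(diag.max(), 1.0):
        return AssociationRecord(lab_id=lab_id, n=n, skipped_reason="degenerate_fit")

    beta_hat = linalg.solve_triangular(R, Q.T @ y)
    resid = y - X @ beta_hat
    df = n - p
    sigma2 = float(resid @ resid) / df
    r_inv = linalg.solve_triangular(R, np.eye(p))
    cov = sigma2 * (r_inv @ r_inv.T)

    beta = float(beta_hat[predictor_column])
    se = float(np.sqrt(cov[predictor_column, predictor_column]))
    if se == 0.0:
        t_stat, p_value = np.inf if beta != 0 else 0.0, 0.0 if beta != 0 else 1.0
    else:
        t_stat = beta / se
        p_value = float(2.0 * stdtr(df, -abs(t_stat)))
    t_crit = float(stdtrit(df, 0.5 + ci_level / 2.0))
    return AssociationRecord(
        lab_id=lab_id,
        n=n,
        beta=beta,
        se=se,
        ci_low=beta - t_crit * se,
        ci_high=beta + t_crit * se,
        p_value=p_value,
        direction="up" if beta > 0 else "down",
    )


@dataclass
class ScanResult:
    """Ordered association records plus the multiple-testing bookkeeping."""

    records: list[AssociationRecord]
    n_labs_tested: int
    n_scans: int
    alpha: float
    threshold: float
    covariate_names: list[str] = field(default_factory=list)
    config: ScanConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lab_id": r.lab_id,
                    "category": r.category,
                    "n": r.n,
                    "beta": r.beta,
                    "se": r.se,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "direction": r.direction,
                    "significant": r.significant,
                    "skipped_reason": r.skipped_reason or "",
                }
                for r in self.records
            ]
        )

    def manifest(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_labs_tested": self.n_labs_tested,
            "n_scans": self.n_scans,
            "threshold": self.threshold,
            "covariates": list(self.covariate_names),
        }


def _code_sex(sex: pd.Series) -> np.ndarray:
    values = sex.to_numpy()
    if np.issubdtype(np.asarray(values).dtype, np.number):
        return np.asarray(values, dtype=float)
    levels = sorted(pd.unique(sex.astype(str)))
    if len(levels) > 2:
        raise ValueError(f"sex column has more than two levels: {levels}")
    mapping = {level: float(i) for i, level in enumerate(levels)}
    return sex.astype(str).map(mapping).to_numpy(dtype=float)


def _pc_columns(covariates: pd.DataFrame, n_pcs: int | None) -> list[str]:
    found = sorted(
        (c for c in covariates.columns if c.startswith("pc") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    if n_pcs is None:
        return found
    want = [f"pc{i}" for i in range(1, n_pcs + 1)]
    missing = [c for c in want if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariate file missing principal components: {missing}")
    return want


def run_labwas(
    clean_table: pd.DataFrame,
    predictor: pd.Series | PredictorVector,
    covariates: pd.DataFrame,
    allowlist=None,
    config: ScanConfig | None = None,
    categories: dict[str, str] | None = None,
) -> ScanResult:
    """Scan every (allowlisted) lab for association with the predictor.

    ``clean_table`` is the per-patient median/INT table from the cleaning
    pipeline; ``covariates`` must carry patient_id, sex, median_age and
    pc<k> columns (plus any ``config.extra_covariates``).  Continuous
    predictors are standardized to mean 0 / SD 1; binary 0/1 predictors
    are used as-is.  Analysis is complete-case per lab; labs with fewer
    than ``config.min_n`` complete cases are reported as skipped and do
    not count toward the Bonferroni denominator.
    """
    config = config or ScanConfig()
    config.validate()

    if not isinstance(predictor, PredictorVector):
        predictor = PredictorVector.from_series(predictor)
    predictor = predictor.prepared()
    x_all = predictor.values.dropna()

    cov = covariates.set_index("patient_id")
    for col in ("sex", "median_age"):
        if col not in cov.columns:
            raise KeyError(f"covariate table missing column {col!r}")
    pc_cols = _pc_columns(cov, config.n_pcs)
    extra_cols = list(config.extra_covariates)
    missing_extra = [c for c in extra_cols if c not in cov.columns]
    if missing_extra:
        raise KeyError(f"covariate table missing adjustment column(s): {missing_extra}")
    used_cols = ["sex", "median_age", *pc_cols, *extra_cols]
    cov = cov[used_cols].dropna()

    # the scanned sample (spline knots, designs) is every patient with a
    # complete covariate row and a predictor value
    scanned = cov.index.intersection(x_all.index)
    table_patients = pd.Index(clean_table["patient_id"].unique())
    if len(table_patients.intersection(x_all.index)) == 0:
        raise ValueError("no patients shared between clean table and predictor")

    cov = cov.loc[scanned]
    x = x_all.loc[scanned].to_numpy(dtype=float)

    basis = build_spline_basis(
        cov["median_age"].to_numpy(dtype=float),
        n_knots=config.n_knots,
        n_columns_used=config.spline_columns,
    )
    spline_cols = basis.columns
    design_cols = np.column_stack(
        [
            np.ones(len(cov)),
            x,
            _code_sex(cov["sex"]),
            spline_cols,
            *(cov[c].to_numpy(dtype=float)[:, None] for c in (*pc_cols, *extra_cols)),
        ]
    )
    covariate_names = (
        ["intercept", "predictor", "sex"]
        + [f"age_spline{i + 1}" for i in range(spline_cols.shape[1])]
        + pc_cols
        + extra_cols
    )
    pos = pd.Series(np.arange(len(cov)), index=cov.index)

    table = clean_table
    if allowlist is not None:
        allow = set(allowlist)
        table = table[table["lab_id"].isin(allow)]

    categories = categories or {}
    records: list[AssociationRecord] = []
    for lab_id, lab_rows in table.groupby("lab_id", sort=True):
        lab_rows = lab_rows[lab_rows["patient_id"].isin(pos.index)]
        n = len(lab_rows)
        if n < config.min_n:
            record = AssociationRecord(
                lab_id=str(lab_id), n=n, skipped_reason="too_few_patients"
            )
        else:
            idx = pos.loc[lab_rows["patient_id"]].to_numpy()
            record = fit_single_lab(
                str(lab_id),
                lab_rows["int_value"].to_numpy(dtype=float),
                design_cols[idx],
            )
        record.category = categories.get(str(lab_id), "")
        records.append(record)

    n_tested = sum(r.tested for r in records)
    threshold = bonferroni_threshold(max(n_tested, 1), config.n_scans, config.alpha)
    for r in records:
        r.significant = bool(r.tested and r.p_value < threshold)
    records.sort(key=lambda r: (r.category, r.lab_id))

    return ScanResult(
        records=records,
        n_labs_tested=n_tested,
        n_scans=config.n_scans,
        alpha=config.alpha,
        threshold=threshold,
        covariate_names=covariate_names,
        config=config,
    )
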
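"""Synthetic cohort and observation generation with a ground-truth ledger.

A single global seed drives independent substreams (cohort, per-lab values,
per-lab contamination) so changing one contamination rate does not reshuffle
unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..qualitylab.units import UnitSynonymTable
from .config import GeneratorConfig

NON_NUMERIC_POOL = ("positive", "negative", "<5", ">100", "TNP", "pending", "1,200")
INFINITE_POOL = ("inf", "-inf", "Infinity")

_COHORT_STREAM = 0
_VALUE_STREAM = 1
_CONTAMINATION_STREAM = 2


@dataclass
class Cohort:
    demographics: pd.DataFrame  # patient_id, sex, race
    covariates: pd.DataFrame  # patient_id, sex, median_age, pc1..pck
    predictor: pd.Series  # patient_id -> value
    event_ages: pd.Series  # patient_id -> first event age (only event patients)
    spans: pd.DataFrame  # patient_id, age_start, age_end
    liabilities: pd.DataFrame  # patients x labs latent standardized values
    effects: dict[str, float]


@dataclass
class SyntheticTruth:
    """Ground truth: effects, per-observation labels, event ages, unit map."""

    effects: dict[str, float]
    ledger: pd.DataFrame  # aligned row-for-row with the observation table
    event_ages: pd.Series
    synonyms: UnitSynonymTable


def generate_cohort(config: GeneratorConfig, seed: int) -> Cohort:
    """Demographics, covariates, predictor, event ages and latent lab values.

    Reproducible given (config, seed).  Continuous predictors are standard
    normal; per-lab liabilities are ``effect * z(predictor) +
    sqrt(1 - effect^2) * noise`` so effects are standardized.
    PCs are independent standard-normal columns.
    """
    config.validate()
    rng = np.random.default_rng([seed, _COHORT_STREAM])
    c = config.cohort
    n = c.n_patients
    ids = np.array([f"P{i:06d}" for i in range(n)])

    sex = np.where(rng.random(n) < c.female_fraction, "F", "M")
    race_names = [r for r, _ in c.race_levels]
    race_probs = [p for _, p in c.race_levels]
    race = rng.choice(race_names, size=n, p=race_probs)

    age_start = rng.uniform(c.age_min, c.age_max - c.span_max, size=n)
    span = rng.uniform(c.span_min, c.span_max, size=n)
    age_end = age_start + span
    median_age = (age_start + age_end) / 2.0

    pcs = rng.standard_normal((n, c.n_pcs))

    if config.predictor.kind == "binary":
        g = (rng.random(n) < config.predictor.prevalence).astype(float)
        g_centered = g
    else:
        g = rng.standard_normal(n)
        sd = g.std(ddof=1) if n > 1 else 0.0
        g_centered = (g - g.mean()) / sd if sd > 0 else np.zeros(n)

    effects = {lab.lab_id: lab.effect for lab in config.labs}
    liab = np.empty((n, len(config.labs)))
    for j, lab in enumerate(config.labs):
        resid_sd = np.sqrt(max(1.0 - lab.effect**2, 0.0))
        liab[:, j] = lab.effect * g_centered + resid_sd * rng.standard_normal(n)

    n_events = int(round(config.medication.fraction * n))
    if n_events > 0:
        if config.medication.mode == "predictor_top":
            chosen = np.argsort(g)[-n_events:]
        else:
            chosen = rng.choice(n, size=n_events, replace=False)
        chosen = np.sort(chosen)
        event_ages = pd.Series(
            rng.uniform(age_start[chosen], age_end[chosen]), index=ids[chosen]
        )
    else:
        event_ages = pd.Series(dtype=float)
    event_ages.index.name = "patient_id"

    covariates = pd.DataFrame({"patient_id": ids, "sex": sex, "median_age": median_age})
    for k in range(c.n_pcs):
        covariates[f"pc{k + 1}"] = pcs[:, k]

    return Cohort(
        demographics=pd.DataFrame({"patient_id": ids, "sex": sex, "race": race}),
        covariates=covariates,
        predictor=pd.Series(g, index=ids, name="value"),
        event_ages=event_ages,
        spans=pd.DataFrame(
            {"patient_id": ids, "age_start": age_start, "age_end": age_end}
        ),
        liabilities=pd.DataFrame(liab, index=ids, columns=[l.lab_id for l in config.labs]),
        effects=effects,
    )


def _raw_scale(lab, liability: np.ndarray) -> np.ndarray:
    # lognormal interprets (location, scale) as log-mean and log-sd
    if lab.family == "lognormal":
        return np.exp(lab.location + lab.scale * liability)
    return lab.location + lab.scale * liability


def generate_observations(
    cohort: Cohort, config: GeneratorConfig, seed: int
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Long-format raw observation table plus the per-observation truth ledger.

    Every observation is classified exactly once in the ledger as one of
    ``clean``, ``non_numeric``, ``infinite`` or ``outlier``; numeric rows
    carry their injected value in ``true_value``.
    """
    config.validate()
    spans = cohort.spans.set_index("patient_id")
    ids = spans.index.to_numpy()
    a0 = spans["age_start"].to_numpy()
    a1 = spans["age_end"].to_numpy()
    event = cohort.event_ages.reindex(spans.index).to_numpy()

    frames = []
    ledger_frames = []
    synonym_map: dict[str, str] = {}
    for j, lab in enumerate(config.labs):
        rng_v = np.random.default_rng([seed, _VALUE_STREAM, j])
        rng_c = np.random.default_rng([seed, _CONTAMINATION_STREAM, j])

        participating = np.flatnonzero(rng_v.random(len(ids)) < lab.patient_fraction)
        if len(participating) == 0:
            continue
        counts = 1 + rng_v.poisson(max(lab.mean_obs - 1.0, 0.0), size=len(participating))
        pat = np.repeat(participating, counts)
        total = len(pat)

        ages = rng_v.uniform(a0[pat], a1[pat])
        order = np.lexsort((ages, pat))
        pat, ages = pat[order], ages[order]

        liability = cohort.liabilities.iloc[:, j].to_numpy()[pat]
        if lab.noise_sd > 0:
            liability = liability + lab.noise_sd * rng_v.standard_normal(total)
        if lab.event_shift != 0.0:
            past_event = ages >= np.where(np.isnan(event[pat]), np.inf, event[pat])
            liability = liability + lab.event_shift * past_event
        values = _raw_scale(lab, liability)

        u = rng_c.random(total)
        r1 = lab.rate_non_numeric
        r2 = r1 + lab.rate_infinite
        r3 = r2 + lab.rate_outlier
        label = np.full(total, "clean", dtype=object)
        label[u < r3] = "outlier"
        label[u < r2] = "infinite"
        label[u < r1] = "non_numeric"

        is_outlier = label == "outlier"
        if is_outlier.any():
            # injected 12-14 latent SD above center: guaranteed past any
            # 4-SD fence at the configured (small) contamination rates
            values = values.copy()
            values[is_outlier] = _raw_scale(
                lab, 12.0 + 2.0 * rng_c.random(int(is_outlier.sum()))
            )

        text = np.array([f"{v:.9g}" for v in values], dtype=object)
        nn = label == "non_numeric"
        if nn.any():
            text[nn] = rng_c.choice(NON_NUMERIC_POOL, size=int(nn.sum()))
        inf_mask = label == "infinite"
        if inf_mask.any():
            text[inf_mask] = rng_c.choice(INFINITE_POOL, size=int(inf_mask.sum()))

        unit_names = [u_ for u_, _ in lab.units]
        unit_probs = [p for _, p in lab.units]
        units = rng_c.choice(unit_names, size=total, p=unit_probs)
        canonical = unit_names[0].strip().casefold()
        for raw in unit_names:
            synonym_map[raw] = canonical

        true_value = values.astype(float).copy()
        true_value[nn | inf_mask] = np.nan

        frames.append(
            pd.DataFrame(
                {
                    "patient_id": ids[pat],
                    "lab_id": lab.lab_id,
                    "value": text,
                    "unit": units,
                    "age": ages,
                }
            )
        )
        ledger_frames.append(
            pd.DataFrame(
                {
                    "patient_id": ids[pat],
                    "lab_id": lab.lab_id,
                    "label": label,
                    "true_value": true_value,
                    "unit": units,
                }
            )
        )

    observations = pd.concat(frames, ignore_index=True)
    ledger = pd.concat(ledger_frames, ignore_index=True)
    truth = SyntheticTruth(
        effects=dict(cohort.effects),
        ledger=ledger,
        event_ages=cohort.event_ages,
        synonyms=UnitSynonymTable(synonym_map),
    )
    return observations, truth


def generate_catalog_fixture(
    n_total: int = 11061,
    n_non_numeric_only: int = 5028,
    n_single_patient: int = 1618,
    seed: int = 0,
) -> pd.DataFrame:
    """A minimal raw catalog with a prescribed composition of lab kinds.

    ``n_non_numeric_only`` labs contain only non-numeric values (two
    patients each, so the sets are disjoint), a further ``n_single_patient``
    labs are numeric but belong to exactly one patient, and the remainder
    are numeric multi-patient labs.
    """
    if n_non_numeric_only + n_single_patient > n_total:
        raise ValueError("catalog composition exceeds total")
    rng = np.random.default_rng(seed)
    rows = {"patient_id": [], "lab_id": [], "value": [], "unit": [], "age": []}

    def add(lab: str, patient: str, value: str):
        rows["patient_id"].append(patient)
        rows["lab_id"].append(lab)
        rows["value"].append(value)
        rows["unit"].append("mg/dl")
        rows["age"].append(float(rng.uniform(20, 80)))

    for i in range(n_total):
        lab = f"L{i:05d}"
        if i < n_non_numeric_only:
            add(lab, f"P{2 * i}", str(rng.choice(NON_NUMERIC_POOL)))
            add(lab, f"P{2 * i + 1}", str(rng.choice(NON_NUMERIC_POOL)))
        elif i < n_non_numeric_only + n_single_patient:
            patient = f"P{2 * i}"
            add(lab, patient, f"{rng.normal(100, 10):.6g}")
            add(lab, patient, f"{rng.normal(100, 10):.6g}")
        else:
            add(lab, f"P{2 * i}", f"{rng.normal(100, 10):.6g}")
            add(lab, f"P{2 * i + 1}", f"{rng.normal(100, 10):.6g}")
    return pd.DataFrame(rows)
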
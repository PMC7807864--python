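"""Brute-force re-derivation of QC decisions from the truth ledger.

Deliberately independent of the cleaning implementation: pure Python over
row tuples with :mod:`collections` and :mod:`statistics`, no pandas group
operations and no shared helper code, so it can serve as an oracle.
"""

from __future__ import annotations

import math
import statistics
from collections import Counter, defaultdict

import pandas as pd

from ..config import QCConfig
from .generate import SyntheticTruth


def expected_pipeline_counts(
    observations: pd.DataFrame,
    truth: SyntheticTruth,
    qc_config: QCConfig | None = None,
) -> dict[str, dict]:
    """Predict per-lab keep/drop decisions and per-stage removal counts.

    Numeric-ness comes from the ledger labels (``clean`` / ``outlier`` rows
    are numeric by construction); everything else is recomputed from first
    principles.
    """
    config = qc_config or QCConfig()
    rows = defaultdict(list)
    ledger = truth.ledger
    for lab_id, patient_id, label, value, unit in zip(
        ledger["lab_id"], ledger["patient_id"], ledger["label"],
        ledger["true_value"], ledger["unit"],
    ):
        rows[lab_id].append((patient_id, label, value, truth.synonyms.canonical(unit)))

    out: dict[str, dict] = {}
    for lab_id, items in rows.items():
        patients = {p for p, _, _, _ in items}
        numeric = [(p, v, u) for p, lbl, v, u in items if lbl in ("clean", "outlier")]
        unit_counts = Counter(u for _, _, u in numeric)

        reasons = []
        if len(numeric) == 0:
            reasons.append("non_numeric_only")
        if len(patients) == 1:
            reasons.append("single_patient")
        if numeric:
            top = max(unit_counts.values())
            fraction = top / sum(unit_counts.values())
            if fraction < config.min_modal_unit_fraction:
                reasons.append("unit_discordant")
        if len(patients) < config.min_patients:
            reasons.append("too_few_patients")
        if len(numeric) < config.min_numeric_observations:
            reasons.append("too_few_observations")

        record = {
            "decision": "keep" if not reasons else "drop",
            "drop_reasons": reasons,
            "n_observations_total": len(items),
            "n_numeric_observations": len(numeric),
            "n_patients": len(patients),
        }
        if not reasons:
            modal = sorted(
                unit_counts, key=lambda u: (-unit_counts[u], u)
            )[0]
            if config.keep_modal_unit_only:
                stage1 = [v for _, v, u in numeric if u == modal]
            else:
                stage1 = [v for _, v, _ in numeric]
            removed_non_numeric = len(items) - len(numeric)
            removed_non_modal = len(numeric) - len(stage1)
            if len(stage1) > 1:
                m = statistics.fmean(stage1)
                s = statistics.stdev(stage1)
                fence = config.outlier_sd_multiplier * s
                survivors = [v for v in stage1 if math.fabs(v - m) <= fence]
            else:
                survivors = list(stage1)
            record.update(
                {
                    "removed_non_numeric": removed_non_numeric,
                    "removed_non_modal_unit": removed_non_modal,
                    "removed_outlier": len(stage1) - len(survivors),
                    "n_output": len(survivors),
                }
            )
        out[lab_id] = record
    return out
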
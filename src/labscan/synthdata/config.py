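"""Configuration of the synthetic EHR generator."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass
class LabSpec:
    """How one synthetic lab behaves.

    ``effect`` is the predictor's standardized effect on the lab's latent
    (liability) scale, which the inverse-normal transform recovers; the raw
    scale is induced through the base distribution (normal or lognormal).
    ``event_shift`` is added to the liability of draws at or after the
    patient's event age.  Contamination rates are per observation.
    """

    lab_id: str
    family: str = "normal"  # "normal" | "lognormal"
    location: float = 100.0
    scale: float = 10.0
    units: list[tuple[str, float]] = field(default_factory=lambda: [("mg/dl", 1.0)])
    effect: float = 0.0
    rate_non_numeric: float = 0.0
    rate_infinite: float = 0.0
    rate_outlier: float = 0.0
    patient_fraction: float = 1.0
    mean_obs: float = 3.0  # expected draws per participating patient, >= 1
    noise_sd: float = 0.1
    event_shift: float = 0.0

    def violations(self) -> list[str]:
        out = []
        if self.family not in ("normal", "lognormal"):
            out.append(f"{self.lab_id}: unknown family {self.family!r}")
        if not self.units:
            out.append(f"{self.lab_id}: needs at least one unit dialect")
        total = sum(p for _, p in self.units)
        if self.units and abs(total - 1.0) > 1e-9:
            out.append(f"{self.lab_id}: unit probabilities sum to {total}, not 1")
        rates = self.rate_non_numeric + self.rate_infinite + self.rate_outlier
        for name in ("rate_non_numeric", "rate_infinite", "rate_outlier"):
            if not 0 <= getattr(self, name) <= 1:
                out.append(f"{self.lab_id}: {name} outside [0, 1]")
        if rates > 1:
            out.append(f"{self.lab_id}: contamination rates sum to {rates} > 1")
        if not 0 <= self.patient_fraction <= 1:
            out.append(f"{self.lab_id}: patient_fraction outside [0, 1]")
        if self.mean_obs < 1:
            out.append(f"{self.lab_id}: mean_obs must be >= 1")
        if not -1 <= self.effect <= 1:
            out.append(f"{self.lab_id}: effect outside [-1, 1]")
        if self.noise_sd < 0:
            out.append(f"{self.lab_id}: noise_sd must be >= 0")
        if self.scale <= 0:
            out.append(f"{self.lab_id}: scale must be > 0")
        if self.family == "lognormal" and (abs(self.location) > 20 or self.scale > 5):
            out.append(
                f"{self.lab_id}: lognormal interprets location/scale on the log "
                "scale; keep |location| <= 20 and scale <= 5 to avoid overflow"
            )
        return out


@dataclass
class CohortSpec:
    n_patients: int = 1000
    female_fraction: float = 0.5
    age_min: float = 18.0
    age_max: float = 85.0
    span_min: float = 2.0
    span_max: float = 10.0
    n_pcs: int = 10
    race_levels: list[tuple[str, float]] = field(
        default_factory=lambda: [("groupA", 0.5), ("groupB", 0.5)]
    )

    def violations(self) -> list[str]:
        out = []
        if self.n_patients < 1:
            out.append("cohort: n_patients must be >= 1")
        if not 0 <= self.female_fraction <= 1:
            out.append("cohort: female_fraction outside [0, 1]")
        if not 0 <= self.age_min < self.age_max:
            out.append("cohort: need 0 <= age_min < age_max")
        if not 0 < self.span_min <= self.span_max:
            out.append("cohort: need 0 < span_min <= span_max")
        if self.age_min + self.span_max > self.age_max:
            out.append("cohort: span_max exceeds the available age range")
        if self.n_pcs < 0:
            out.append("cohort: n_pcs must be >= 0")
        total = sum(p for _, p in self.race_levels)
        if abs(total - 1.0) > 1e-9:
            out.append(f"cohort: race probabilities sum to {total}, not 1")
        return out


@dataclass
class PredictorSpec:
    kind: str = "continuous"  # "continuous" | "binary"
    prevalence: float = 0.5  # binary only

    def violations(self) -> list[str]:
        out = []
        if self.kind not in ("continuous", "binary"):
            out.append(f"predictor: unknown kind {self.kind!r}")
        if not 0 < self.prevalence < 1:
            out.append("predictor: prevalence outside (0, 1)")
        return out


@dataclass
class MedicationSpec:
    """Which patients receive an event age (e.g., first medication mention).

    ``mode = "predictor_top"`` assigns events to the patients with the
    highest predictor values, emulating treatment targeted at high-risk
    individuals; ``"random"`` assigns uniformly.
    """

    fraction: float = 0.0
    mode: str = "random"  # "random" | "predictor_top"

    def violations(self) -> list[str]:
        out = []
        if not 0 <= self.fraction <= 1:
            out.append("medication: fraction outside [0, 1]")
        if self.mode not in ("random", "predictor_top"):
            out.append(f"medication: unknown mode {self.mode!r}")
        return out


@dataclass
class GeneratorConfig:
    labs: list[LabSpec] = field(default_factory=list)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    predictor: PredictorSpec = field(default_factory=PredictorSpec)
    medication: MedicationSpec = field(default_factory=MedicationSpec)

    def validate(self) -> None:
        problems: list[str] = []
        if not self.labs:
            problems.append("generator: needs at least one lab")
        seen = set()
        for lab in self.labs:
            if lab.lab_id in seen:
                problems.append(f"duplicate lab_id {lab.lab_id!r}")
            seen.add(lab.lab_id)
            problems.extend(lab.violations())
        problems.extend(self.cohort.violations())
        problems.extend(self.predictor.violations())
        problems.extend(self.medication.violations())
        # a raw unit spelling may not map to two different canonical units
        canon: dict[str, str] = {}
        for lab in self.labs:
            target = lab.units[0][0].strip().casefold() if lab.units else ""
            for raw, _ in lab.units:
                key = raw.strip().casefold()
                if canon.setdefault(key, target) != target:
                    problems.append(
                        f"unit {raw!r} maps to both {canon[key]!r} and {target!r}"
                    )
        if problems:
            raise ValueError("invalid generator config: " + "; ".join(problems))

    @classmethod
    def simple(
        cls,
        n_patients: int,
        effects: dict[str, float],
        *,
        mean_obs: float = 3.0,
        noise_sd: float = 0.1,
        rate_non_numeric: float = 0.0,
        rate_infinite: float = 0.0,
        rate_outlier: float = 0.0,
        event_fraction: float = 0.0,
        event_mode: str = "random",
        event_shift_labs: dict[str, float] | None = None,
        n_pcs: int = 4,
    ) -> "GeneratorConfig":
        """One-liner for a uniform cohort with per-lab effects."""
        shifts = event_shift_labs or {}
        labs = [
            LabSpec(
                lab_id=lab_id,
                effect=eff,
                mean_obs=mean_obs,
                noise_sd=noise_sd,
                rate_non_numeric=rate_non_numeric,
                rate_infinite=rate_infinite,
                rate_outlier=rate_outlier,
                event_shift=shifts.get(lab_id, 0.0),
            )
            for lab_id, eff in sorted(effects.items())
        ]
        config = cls(
            labs=labs,
            cohort=CohortSpec(n_patients=n_patients, n_pcs=n_pcs),
            medication=MedicationSpec(fraction=event_fraction, mode=event_mode),
        )
        config.validate()
        return config

    def to_dict(self) -> dict:
        d = asdict(self)
        for lab in d["labs"]:
            lab["units"] = [[u, p] for u, p in lab["units"]]
        d["cohort"]["race_levels"] = [[r, p] for r, p in d["cohort"]["race_levels"]]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        labs = [
            LabSpec(**{**lab, "units": [tuple(u) for u in lab.get("units", [["mg/dl", 1.0]])]})
            for lab in data.pop("labs", [])
        ]
        cohort_d = dict(data.pop("cohort", {}))
        if "race_levels" in cohort_d:
            cohort_d["race_levels"] = [tuple(r) for r in cohort_d["race_levels"]]
        config = cls(
            labs=labs,
            cohort=CohortSpec(**cohort_d),
            predictor=PredictorSpec(**data.pop("predictor", {})),
            medication=MedicationSpec(**data.pop("medication", {})),
        )
        if data:
            raise ValueError(f"unknown generator key(s): {', '.join(sorted(data))}")
        return config
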
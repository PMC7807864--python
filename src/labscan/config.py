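"""Configuration objects and the YAML config loader shared by all stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class QCConfig:
    """Thresholds for the catalog and observation-level cleaning cascade."""

    min_modal_unit_fraction: float = 0.70
    min_patients: int = 100
    min_numeric_observations: int = 1000
    outlier_sd_multiplier: float = 4.0
    int_offset: float = 0.375  # Blom
    keep_modal_unit_only: bool = True
    same_day_event_excluded: bool = True

    def validate(self) -> None:
        errors = []
        if not (0 < self.min_modal_unit_fraction <= 1):
            errors.append("min_modal_unit_fraction must be in (0, 1]")
        if self.min_patients <= 0:
            errors.append("min_patients must be strictly positive")
        if self.min_numeric_observations <= 0:
            errors.append("min_numeric_observations must be strictly positive")
        if self.outlier_sd_multiplier <= 0:
            errors.append("outlier_sd_multiplier must be strictly positive")
        if not (0 <= self.int_offset <= 0.5):
            errors.append("int_offset must be in [0, 0.5]")
        if errors:
            raise ConfigError("; ".join(errors))


@dataclass
class StratumSpec:
    """Factor levels for stratified summaries; each factor includes a pooled level."""

    sex_levels: list[str] = field(default_factory=lambda: ["F", "M"])
    age_groups: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("pediatric", 0.0, 18.0), ("adult", 18.0, float("inf"))]
    )
    race_levels: list[str] = field(default_factory=lambda: ["groupA", "groupB"])
    pooled_label: str = "all"

    def validate(self) -> None:
        errors = []
        if self.pooled_label in self.sex_levels or self.pooled_label in self.race_levels:
            errors.append("pooled label must not duplicate a non-pooled level")
        spans = sorted((lo, hi) for _, lo, hi in self.age_groups)
        for (lo, hi) in spans:
            if not lo < hi:
                errors.append(f"age group [{lo}, {hi}) is empty")
        for (_, hi0), (lo1, _) in zip(spans, spans[1:]):
            if lo1 < hi0:
                errors.append("age groups overlap")
        if errors:
            raise ConfigError("; ".join(errors))

    @property
    def n_strata(self) -> int:
        return (
            (len(self.sex_levels) + 1)
            * (len(self.age_groups) + 1)
            * (len(self.race_levels) + 1)
        )


@dataclass
class ScanConfig:
    """Settings for one association scan."""

    min_n: int = 100
    alpha: float = 0.05
    n_scans: int = 1
    n_knots: int = 4
    spline_columns: int | None = None  # None -> all n_knots - 1 columns
    n_pcs: int | None = None  # None -> every pc<k> column present
    extra_covariates: list[str] = field(default_factory=list)

    def validate(self) -> None:
        errors = []
        if self.min_n < 1:
            errors.append("min_n must be >= 1")
        if not (0 < self.alpha < 1):
            errors.append("alpha must be in (0, 1)")
        if self.n_scans < 1:
            errors.append("n_scans must be >= 1")
        if self.n_knots < 3:
            errors.append("n_knots must be >= 3")
        if self.spline_columns is not None and self.spline_columns < 1:
            errors.append("spline_columns must be >= 1")
        if errors:
            raise ConfigError("; ".join(errors))


class ConfigError(ValueError):
    """Raised for unknown keys, type mismatches, or invariant violations."""


def _build(cls, section: str, data: dict):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {', '.join(sorted(unknown))}"
        )
    kwargs = {}
    for key, value in data.items():
        f = known[key]
        if f.type in ("int", int) and isinstance(value, bool):
            raise ConfigError(f"{section}.{key}: expected int, got bool")
        if f.type in ("int", int):
            if not isinstance(value, int):
                raise ConfigError(f"{section}.{key}: expected int, got {type(value).__name__}")
        elif f.type in ("float", float):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"{section}.{key}: expected number, got {type(value).__name__}")
            value = float(value)
        elif f.type in ("bool", bool) and not isinstance(value, bool):
            raise ConfigError(f"{section}.{key}: expected bool, got {type(value).__name__}")
        kwargs[key] = value
    obj = cls(**kwargs)
    return obj


def _build_strata(data: dict) -> StratumSpec:
    data = dict(data)
    groups = data.pop("age_groups", None)
    spec = _build(StratumSpec, "strata", data)
    if groups is not None:
        parsed = []
        for item in groups:
            label, lo, hi = item
            parsed.append((str(label), float(lo), float(hi) if hi is not None else float("inf")))
        spec.age_groups = parsed
    return spec


@dataclass
class LoadedConfig:
    qc: QCConfig
    strata: StratumSpec | None
    scan: ScanConfig
    generator: "object | None"  # labscan.synthdata.GeneratorConfig when present


_SECTIONS = ("qc", "strata", "scan", "generator")


def load_config(path: str | Path) -> LoadedConfig:
    """Load and validate a YAML config file.

    Absent sections and keys fall back to defaults; unknown keys anywhere
    raise :class:`ConfigError` naming the offending key.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {', '.join(sorted(unknown))}")

    qc = _build(QCConfig, "qc", data.get("qc", {}) or {})
    qc.validate()
    strata = None
    if "strata" in data:
        strata = _build_strata(data.get("strata") or {})
        strata.validate()
    scan = _build(ScanConfig, "scan", data.get("scan", {}) or {})
    scan.validate()
    generator = None
    if "generator" in data:
        from .synthdata import GeneratorConfig

        generator = GeneratorConfig.from_dict(data.get("generator") or {})
        generator.validate()
    return LoadedConfig(qc=qc, strata=strata, scan=scan, generator=generator)


def dump_config(config: LoadedConfig, path: str | Path) -> None:
    """Serialize a configuration back to YAML (round-trips with load_config)."""
    payload: dict = {"qc": dataclasses.asdict(config.qc), "scan": dataclasses.asdict(config.scan)}
    if config.strata is not None:
        d = dataclasses.asdict(config.strata)
        d["age_groups"] = [[lab, lo, None if hi == float("inf") else hi]
                           for lab, lo, hi in config.strata.age_groups]
        payload["strata"] = d
    if config.generator is not None:
        payload["generator"] = config.generator.to_dict()
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")
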
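"""Configuration objects shared across the pipeline.

Every knob that defines a simulation or an analysis run lives here as a
frozen dataclass with an explicit ``validate`` step, so that a bad value
fails loudly with the offending field named, and so that identical
(config, seed) pairs reproduce identical outputs downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value is invalid; names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class ErrorSpec:
    """Entry-error model applied to the raw visit table.

    ``p_missing_height`` blanks the height cell; ``p_height_typo`` and
    ``p_weight_typo`` corrupt the value, splitting between unit confusion
    (height recorded in centimetres, weight in kilograms) and a
    transposition of the two leading digits with probability
    ``p_unit_confusion`` / ``1 - p_unit_confusion``.
    """

    p_missing_height: float = 0.05
    p_height_typo: float = 0.01
    p_weight_typo: float = 0.01
    p_unit_confusion: float = 0.5

    def validate(self) -> "ErrorSpec":
        for name in ("p_missing_height", "p_height_typo", "p_weight_typo",
                     "p_unit_confusion"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, f"probability {v!r} not in [0, 1]")
        return self

    @classmethod
    def none(cls) -> "ErrorSpec":
        """An error model that corrupts nothing."""
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ComorbidityModel:
    """Ground-truth disease model for one comorbidity.

    Baseline prevalence is logistic in BMI and age:
    ``logit p = prevalence_intercept + prevalence_bmi_slope * bmi
    + age_slope * (age - 45) + sex_modifier * male + race modifier``.

    Yearly incidence among the disease-free is logistic with a step at the
    true threshold theta:
    ``logit h = logit(incidence_base_rate) + incidence_effect * [bmi >= theta]
    + age_slope * (age - 45) + modifiers``.
    With ``smooth=True`` the step is replaced by
    ``smooth_slope * (bmi - theta)`` so no true cut point exists by
    construction.
    """

    name: str
    codes: tuple[str, ...]
    prevalence_intercept: float
    prevalence_bmi_slope: float
    incidence_base_rate: float
    incidence_threshold: float
    incidence_effect: float
    age_slope: float = 0.0
    sex_modifier: float = 0.0
    race_modifiers: Mapping[str, float] = field(default_factory=dict)
    smooth: bool = False
    smooth_slope: float = 0.3

    def validate(self) -> "ComorbidityModel":
        _require(bool(self.name), "name", "must be non-empty")
        _require(len(self.codes) > 0, "codes", "must list at least one code")
        _require(0.0 < self.incidence_base_rate < 1.0, "incidence_base_rate",
                 f"{self.incidence_base_rate!r} not in (0, 1)")
        _require(15.0 <= self.incidence_threshold <= 60.0,
                 "incidence_threshold",
                 f"{self.incidence_threshold!r} outside plausible BMI range 15-60")
        _require(self.incidence_effect >= 0.0, "incidence_effect",
                 f"{self.incidence_effect!r} must be >= 0")
        return self


RACE_LEVELS = ("White-NH", "Black-NH", "Asian-NH", "Native-American-NH",
               "Hispanic", "other/unspecified")
INSURANCE_LEVELS = ("commercial", "Medicare", "Medicaid", "other/unspecified")
SMOKING_LEVELS = ("active", "former", "passive", "non")


def default_comorbidity_models() -> tuple[ComorbidityModel, ...]:
    """A toy four-disease ground truth.

    Intercepts are set so baseline prevalence near BMI 29, age 45 lands at
    roughly the population frequencies one sees for these diseases in US
    adult primary-care populations (T2DM ~7%, hypertension ~21%,
    hyperlipidemia ~24%, anxiety ~14%). Code sets are deliberately toy
    prefixes, not a curated phenotyping list. Anxiety carries no BMI
    threshold effect, giving the suite a built-in null disease.
    """
    return (
        ComorbidityModel(
            name="type_2_diabetes", codes=("E11", "250"),
            prevalence_intercept=-5.41, prevalence_bmi_slope=0.10,
            incidence_base_rate=0.012, incidence_threshold=31.0,
            incidence_effect=2.0, age_slope=0.02),
        ComorbidityModel(
            name="hypertension", codes=("I10", "401"),
            prevalence_intercept=-3.62, prevalence_bmi_slope=0.08,
            incidence_base_rate=0.036, incidence_threshold=28.5,
            incidence_effect=1.5, age_slope=0.04),
        ComorbidityModel(
            name="hyperlipidemia", codes=("E78", "272"),
            prevalence_intercept=-2.88, prevalence_bmi_slope=0.06,
            incidence_base_rate=0.040, incidence_threshold=27.0,
            incidence_effect=1.2, age_slope=0.04),
        ComorbidityModel(
            name="anxiety", codes=("F41", "3000"),
            prevalence_intercept=-1.82, prevalence_bmi_slope=0.0,
            incidence_base_rate=0.025, incidence_threshold=30.0,
            incidence_effect=0.0, age_slope=-0.01),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the synthetic-EHR generator needs besides a seed.

    Demographic mixtures default to the composition of a large Midwestern
    US academic-medical-center cohort (55% female, 89% White non-Hispanic,
    mean BMI 29.1 kg/m^2, SD 7.0); visits follow a per-patient Poisson
    count over a ~10.6-year observation window, matching a multi-visit
    primary-care panel.
    """

    n_patients: int
    start_date: date = date(2008, 6, 1)
    end_date: date = date(2018, 12, 31)
    visits_per_patient: float = 6.0
    age_range: tuple[float, float] = (18.0, 75.0)
    p_female: float = 0.549
    race_probs: tuple[float, ...] = (0.887, 0.039, 0.027, 0.005, 0.030, 0.012)
    insurance_probs: tuple[float, ...] = (0.788, 0.131, 0.025, 0.056)
    smoking_probs: tuple[float, ...] = (0.141, 0.264, 0.011, 0.584)
    bmi_mean: float = 29.1
    bmi_sd: float = 7.0
    bmi_bounds: tuple[float, float] = (15.0, 60.0)
    bmi_drift_sd: float = 0.3
    bmi_visit_noise_sd: float = 0.5
    height_mean_female: float = 64.0
    height_mean_male: float = 69.5
    height_sd: float = 2.8
    height_measure_noise_sd: float = 0.25
    comorbidities: tuple[ComorbidityModel, ...] = field(
        default_factory=default_comorbidity_models)
    errors: ErrorSpec = field(default_factory=ErrorSpec)
    p_pregnancy: float = 0.04
    p_cancer: float = 0.03
    p_registry: float = 0.01
    pregnancy_codes: tuple[str, ...] = ("Z34", "V22")
    cancer_codes: tuple[str, ...] = ("C50", "174")

    def validate(self) -> "GeneratorConfig":
        _require(self.n_patients >= 0, "n_patients",
                 f"{self.n_patients!r} must be >= 0")
        _require(self.end_date > self.start_date, "end_date",
                 "observation window is empty (end_date <= start_date)")
        _require(self.visits_per_patient > 0, "visits_per_patient",
                 "mean visit count must be positive")
        _require(self.age_range[0] < self.age_range[1], "age_range",
                 "lower bound must be below upper bound")
        for name in ("p_female", "p_pregnancy", "p_cancer", "p_registry"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, f"probability {v!r} not in [0, 1]")
        for name, levels in (("race_probs", RACE_LEVELS),
                             ("insurance_probs", INSURANCE_LEVELS),
                             ("smoking_probs", SMOKING_LEVELS)):
            probs = getattr(self, name)
            _require(len(probs) == len(levels), name,
                     f"needs {len(levels)} probabilities, got {len(probs)}")
            _require(abs(sum(probs) - 1.0) < 1e-6, name,
                     f"probabilities sum to {sum(probs)!r}, not 1")
        _require(self.bmi_bounds[0] < self.bmi_bounds[1], "bmi_bounds",
                 "lower bound must be below upper bound")
        self.errors.validate()
        names = [m.name for m in self.comorbidities]
        _require(len(names) == len(set(names)), "comorbidities",
                 "duplicate comorbidity names")
        for m in self.comorbidities:
            m.validate()
        return self

    @property
    def window_days(self) -> int:
        return (self.end_date - self.start_date).days

    @property
    def window_years(self) -> float:
        return self.window_days / 365.25

    def code_sets(self) -> dict[str, list[str]]:
        """Diagnosis code prefixes per comorbidity, as consumed downstream."""
        return {m.name: list(m.codes) for m in self.comorbidities}


@dataclass(frozen=True)
class PipelineConfig:
    """One end-to-end run: generator (or input paths), analysis knobs, outputs."""

    seed: int
    output_dir: str
    generator: GeneratorConfig | None = None
    visits_path: str | None = None
    diagnoses_path: str | None = None
    demographics_path: str | None = None
    registry_path: str | None = None
    code_sets_path: str | None = None
    window_days: int = 365
    age_bounds: tuple[float, float] = (18.0, 75.0)
    auroc_gate: float = 0.6
    n_bootstrap: int = 1000
    make_plots: bool = False

    def validate(self) -> "PipelineConfig":
        _require(0.5 < self.auroc_gate < 1.0, "auroc_gate",
                 f"{self.auroc_gate!r} not in (0.5, 1)")
        _require(self.n_bootstrap >= 1, "n_bootstrap", "must be >= 1")
        _require(self.window_days > 0, "window_days", "must be positive")
        if self.generator is not None:
            self.generator.validate()
        else:
            for name in ("visits_path", "diagnoses_path", "demographics_path"):
                _require(getattr(self, name) is not None, name,
                         "required when no generator config is given")
        return self


# --- YAML round-trip -------------------------------------------------------

def _as_dict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def conv(v):
        if isinstance(v, date):
            return v.isoformat()
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        return v

    return {k: conv(v) for k, v in d.items()}


def generator_config_to_yaml(config: GeneratorConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_dict(config), fh, sort_keys=False)


def generator_config_from_dict(raw: Mapping) -> GeneratorConfig:
    raw = dict(raw)
    for key in ("start_date", "end_date"):
        if key in raw and isinstance(raw[key], str):
            raw[key] = date.fromisoformat(raw[key])
    if "errors" in raw and isinstance(raw["errors"], Mapping):
        raw["errors"] = ErrorSpec(**raw["errors"])
    if "comorbidities" in raw:
        models = []
        for m in raw["comorbidities"]:
            if isinstance(m, Mapping):
                m = dict(m)
                m["codes"] = tuple(m["codes"])
                m = ComorbidityModel(**m)
            models.append(m)
        raw["comorbidities"] = tuple(models)
    for key in ("age_range", "race_probs", "insurance_probs", "smoking_probs",
                "bmi_bounds", "pregnancy_codes", "cancer_codes"):
        if key in raw and isinstance(raw[key], Sequence):
            raw[key] = tuple(raw[key])
    return GeneratorConfig(**raw).validate()


def generator_config_from_yaml(path: str) -> GeneratorConfig:
    with open(path) as fh:
        return generator_config_from_dict(yaml.safe_load(fh))
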
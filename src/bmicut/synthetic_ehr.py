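"""Synthetic longitudinal EHR generator with known ground truth.

Emulates the raw material of an anthropometric EHR study: a visit table
with heights (inches) and weights (pounds) subject to entry errors, a
dated diagnosis-code table, a demographics table, and a surgery-registry
id list — together with the latent truth (per-patient BMI trajectories and
true disease-onset dates) that generated them, so every downstream stage
can be checked against a verifiable oracle rather than against itself.

The disease model is deliberately simple: baseline prevalence logistic in
BMI and age, and a yearly incidence hazard that is logistic with a *step*
of ``incidence_effect`` log-odds at the true threshold
``incidence_threshold`` — so a true BMI cut point exists by construction
and threshold-recovery tests have a known answer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .config import (ComorbidityModel, ErrorSpec, GeneratorConfig,
                     INSURANCE_LEVELS, RACE_LEVELS, SMOKING_LEVELS)

VISIT_COLUMNS = ["patient_id", "date", "height_in", "weight_lb"]
DIAGNOSIS_COLUMNS = ["patient_id", "date", "code"]
DEMOGRAPHICS_COLUMNS = ["patient_id", "birth_date", "sex", "race_ethnicity",
                        "insurance", "smoking"]


@dataclass(frozen=True)
class SyntheticCohortTruth:
    """The generator's latent state: what downstream stages try to recover.

    ``patients`` holds one row per patient with the latent BMI intercept,
    yearly drift and true height; ``onsets`` holds one row per realized
    disease onset (patient_id, comorbidity, onset_date, prevalent_at_start).
    """

    patients: pd.DataFrame
    onsets: pd.DataFrame
    models: tuple[ComorbidityModel, ...]

    def onset_dates(self, comorbidity: str) -> pd.Series:
        sub = self.onsets[self.onsets["comorbidity"] == comorbidity]
        return sub.set_index("patient_id")["onset_date"]

    def to_json(self, path: str) -> None:
        payload = {
            "models": [dataclasses.asdict(m) for m in self.models],
            "patients": self.patients.assign(
                **{c: self.patients[c] for c in ()}).to_dict("records"),
            "onsets": [
                {**r, "onset_date": r["onset_date"].date().isoformat()}
                for r in self.onsets.to_dict("records")
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


@dataclass(frozen=True)
class Population:
    """One generated data set: public tables plus private truth."""

    demographics: pd.DataFrame
    visits: pd.DataFrame              # corrupted, as an EHR would hold it
    visits_uncorrupted: pd.DataFrame  # pre-corruption, for accounting only
    diagnoses: pd.DataFrame
    registry_ids: list[str]
    truth: SyntheticCohortTruth
    corruption_log: pd.DataFrame      # one row per injected error
    corruption_counts: dict[str, int]


def true_cutpoint(models: Sequence[ComorbidityModel], comorbidity: str) -> float:
    """The generator's threshold theta for one comorbidity (for recovery tests)."""
    for m in models:
        if m.name == comorbidity:
            return m.incidence_threshold
    known = ", ".join(m.name for m in models)
    raise KeyError(f"unknown comorbidity {comorbidity!r}; known: {known}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float], size: int) -> np.ndarray:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _transpose_leading_digits(values: np.ndarray) -> np.ndarray:
    """Swap the two leading digits of the integer part (18x -> 81x)."""
    out = np.empty_like(values, dtype=float)
    for i, v in enumerate(values):
        whole = int(v)
        frac = round(v - whole, 1)
        s = str(whole)
        if len(s) >= 2:
            s = s[1] + s[0] + s[2:]
        out[i] = int(s) + frac
    return np.round(out, 1)


def _disease_modifier(model: ComorbidityModel, male: np.ndarray,
                      race: np.ndarray) -> np.ndarray:
    mod = model.sex_modifier * male.astype(float)
    if model.race_modifiers:
        race_mod = np.zeros(len(race))
        for level, value in model.race_modifiers.items():
            race_mod[race == level] = value
        mod = mod + race_mod
    return mod


def _emit_code(rng: np.random.Generator, prefixes: tuple[str, ...]) -> str:
    """A concrete code under a random prefix, sometimes dotted (E11.4 vs E114)."""
    prefix = prefixes[rng.integers(len(prefixes))]
    suffix = str(rng.integers(10))
    code = prefix + suffix
    if rng.random() < 0.5 and len(code) > 3:
        code = code[:3] + "." + code[3:]
    return code


def _empty_population(config: GeneratorConfig) -> Population:
    empty_visits = pd.DataFrame(columns=VISIT_COLUMNS)
    truth = SyntheticCohortTruth(
        patients=pd.DataFrame(columns=["patient_id", "bmi_intercept",
                                       "bmi_drift", "height_in", "age_at_start"]),
        onsets=pd.DataFrame(columns=["patient_id", "comorbidity",
                                     "onset_date", "prevalent_at_start"]),
        models=config.comorbidities)
    return Population(
        demographics=pd.DataFrame(columns=DEMOGRAPHICS_COLUMNS),
        visits=empty_visits, visits_uncorrupted=empty_visits.copy(),
        diagnoses=pd.DataFrame(columns=DIAGNOSIS_COLUMNS),
        registry_ids=[], truth=truth,
        corruption_log=pd.DataFrame(columns=["patient_id", "date", "field",
                                             "kind", "original", "corrupted"]),
        corruption_counts={"missing_height": 0, "height_typo": 0,
                           "weight_typo": 0})


def generate_population(config: GeneratorConfig, seed: int) -> Population:
    """Generate one full synthetic EHR. Identical (config, seed) pairs
    reproduce byte-identical tables."""
    config.validate()
    if config.n_patients == 0:
        return _empty_population(config)

    rng = np.random.default_rng(seed)
    n = config.n_patients
    start = pd.Timestamp(config.start_date)
    window_days = config.window_days

    patient_id = np.array([f"P{i:07d}" for i in range(n)])
    female = rng.random(n) < config.p_female
    race = rng.choice(np.array(RACE_LEVELS, dtype=object), size=n,
                      p=config.race_probs)
    insurance = rng.choice(np.array(INSURANCE_LEVELS, dtype=object), size=n,
                           p=config.insurance_probs)
    smoking = rng.choice(np.array(SMOKING_LEVELS, dtype=object), size=n,
                         p=config.smoking_probs)
    age_at_start = rng.uniform(*config.age_range, size=n)
    birth_date = start - pd.to_timedelta(
        np.round(age_at_start * 365.25).astype(int), unit="D")

    height = np.where(female,
                      rng.normal(config.height_mean_female, config.height_sd, n),
                      rng.normal(config.height_mean_male, config.height_sd, n))
    bmi0 = _truncated_normal(rng, config.bmi_mean, config.bmi_sd,
                             config.bmi_bounds, n)
    drift = rng.normal(0.0, config.bmi_drift_sd, n)

    demographics = pd.DataFrame({
        "patient_id": patient_id, "birth_date": birth_date,
        "sex": np.where(female, "female", "male"),
        "race_ethnicity": race, "insurance": insurance, "smoking": smoking,
    })

    # --- visits: per-patient Poisson count, dates strictly inside window ---
    n_visits = rng.poisson(config.visits_per_patient, n)
    owner = np.repeat(np.arange(n), n_visits)
    day = rng.integers(1, window_days, size=owner.size)
    order = np.lexsort((day, owner))
    owner, day = owner[order], day[order]
    t_years = day / 365.25

    bmi_visit = (bmi0[owner] + drift[owner] * t_years
                 + rng.normal(0.0, config.bmi_visit_noise_sd, owner.size))
    height_rec = np.round(
        height[owner] + rng.normal(0.0, config.height_measure_noise_sd,
                                   owner.size), 1)
    weight_rec = np.round(bmi_visit * height[owner] ** 2 / 703.0, 1)

    visits_clean = pd.DataFrame({
        "patient_id": patient_id[owner],
        "date": start + pd.to_timedelta(day, unit="D"),
        "height_in": height_rec, "weight_lb": weight_rec,
    })

    visits, corruption_log, counts = _corrupt_visits(visits_clean, config.errors,
                                                     rng)

    # --- disease onsets -----------------------------------------------------
    male = ~female
    k_years = int(np.floor(config.window_years))
    onset_rows = []
    diag_rows: list[tuple[str, pd.Timestamp, str]] = []
    for model in config.comorbidities:
        mod = _disease_modifier(model, male, race)
        lp_prev = (model.prevalence_intercept
                   + model.prevalence_bmi_slope * bmi0
                   + model.age_slope * (age_at_start - 45.0) + mod)
        prevalent = rng.random(n) < expit(lp_prev)
        onset_day = np.full(n, -1, dtype=float)
        onset_day[prevalent] = rng.integers(0, 31, size=int(prevalent.sum()))

        # yearly incidence hazard for the disease-free
        years = np.arange(k_years)
        bmi_y = bmi0[:, None] + drift[:, None] * years[None, :]
        if model.smooth:
            eff = model.smooth_slope * (bmi_y - model.incidence_threshold)
        else:
            eff = model.incidence_effect * (bmi_y >= model.incidence_threshold)
        lp_inc = (logit(model.incidence_base_rate) + eff
                  + model.age_slope * (age_at_start[:, None] + years[None, :]
                                       - 45.0)
                  + mod[:, None])
        hit = rng.random((n, k_years)) < expit(lp_inc)
        hit[prevalent] = False
        any_hit = hit.any(axis=1)
        first_year = np.where(any_hit, hit.argmax(axis=1), -1)
        frac = rng.random(n)
        incident_day = np.round((first_year + frac) * 365.25)
        onset_day[any_hit] = incident_day[any_hit]

        has_onset = onset_day >= 0
        onset_ts = start + pd.to_timedelta(
            onset_day[has_onset].astype(int), unit="D")
        for pid, ts, prev in zip(patient_id[has_onset], onset_ts,
                                 prevalent[has_onset]):
            onset_rows.append((pid, model.name, ts, bool(prev)))
            diag_rows.append((pid, ts, _emit_code(rng, model.codes)))
            repeat = ts + pd.Timedelta(days=180)
            if repeat <= pd.Timestamp(config.end_date):
                diag_rows.append((pid, repeat, _emit_code(rng, model.codes)))

    # --- exclusion material -------------------------------------------------
    pregnant = female & (rng.random(n) < config.p_pregnancy)
    cancer = rng.random(n) < config.p_cancer
    for mask, prefixes in ((pregnant, config.pregnancy_codes),
                           (cancer, config.cancer_codes)):
        idx = np.flatnonzero(mask)
        days = rng.integers(1, window_days, size=idx.size)
        for i, d in zip(idx, days):
            diag_rows.append((patient_id[i],
                              start + pd.Timedelta(days=int(d)),
                              _emit_code(rng, prefixes)))
    registry_ids = list(patient_id[rng.random(n) < config.p_registry])

    diagnoses = pd.DataFrame(diag_rows, columns=DIAGNOSIS_COLUMNS)
    diagnoses = diagnoses.sort_values(
        ["patient_id", "date", "code"], kind="mergesort").reset_index(drop=True)

    truth = SyntheticCohortTruth(
        patients=pd.DataFrame({
            "patient_id": patient_id, "bmi_intercept": bmi0,
            "bmi_drift": drift, "height_in": height,
            "age_at_start": age_at_start}),
        onsets=pd.DataFrame(onset_rows,
                            columns=["patient_id", "comorbidity",
                                     "onset_date", "prevalent_at_start"]),
        models=config.comorbidities)

    return Population(demographics=demographics, visits=visits,
                      visits_uncorrupted=visits_clean, diagnoses=diagnoses,
                      registry_ids=registry_ids, truth=truth,
                      corruption_log=corruption_log, corruption_counts=counts)


def _corrupt_visits(visits: pd.DataFrame, errors: ErrorSpec,
                    rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Inject missing heights and unit/transposition typos per ErrorSpec."""
    out = visits.copy()
    m = len(out)
    log_rows = []

    u = rng.random(m)
    missing = u < errors.p_missing_height
    typo_h = (~missing) & (rng.random(m) < errors.p_height_typo)
    typo_w = rng.random(m) < errors.p_weight_typo

    for i in np.flatnonzero(missing):
        log_rows.append((out.at[i, "patient_id"], out.at[i, "date"],
                         "height_in", "missing", out.at[i, "height_in"],
                         np.nan))
    out.loc[missing, "height_in"] = np.nan

    for field, mask, unit_factor in (("height_in", typo_h, 2.54),
                                     ("weight_lb", typo_w, 1 / 2.20462)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        unit = rng.random(idx.size) < errors.p_unit_confusion
        orig = out.loc[idx, field].to_numpy(dtype=float)
        corrupted = _transpose_leading_digits(orig)
        # a transposition that changes nothing is no error; use units instead
        unit = unit | (corrupted == orig)
        corrupted[unit] = np.round(orig[unit] * unit_factor, 1)
        out.loc[idx, field] = corrupted
        for j, i in enumerate(idx):
            kind = "unit_confusion" if unit[j] else "digit_transposition"
            log_rows.append((out.at[i, "patient_id"], out.at[i, "date"],
                             field, kind, orig[j], corrupted[j]))

    log = pd.DataFrame(log_rows, columns=["patient_id", "date", "field",
                                          "kind", "original", "corrupted"])
    counts = {"missing_height": int(missing.sum()),
              "height_typo": int(typo_h.sum()),
              "weight_typo": int(typo_w.sum())}
    return out, log, counts


def simulate_screening_sample(model: ComorbidityModel, n: int, seed: int,
                              bmi_mean: float = 29.1, bmi_sd: float = 7.0,
                              bmi_bounds: tuple[float, float] = (15.0, 60.0),
                              age: float = 45.0,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (baseline BMI, 1-year incidence label) pairs from one disease model.

    A desk-scale shortcut past the visit machinery: BMIs come from the
    population BMI distribution and labels from the model's one-year
    hazard at a fixed age. Used for screening-test calibration studies
    where thousands of replicates are needed.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    bmi = _truncated_normal(rng, bmi_mean, bmi_sd, bmi_bounds, n)
    if model.smooth:
        eff = model.smooth_slope * (bmi - model.incidence_threshold)
    else:
        eff = model.incidence_effect * (bmi >= model.incidence_threshold)
    p = expit(logit(model.incidence_base_rate) + eff
              + model.age_slope * (age - 45.0))
    label = (rng.random(n) < p).astype(int)
    return bmi, label


# --- CSV writers (RFC 4180, ISO-8601 dates, empty string = missing) --------

def write_population(pop: Population, outdir: str) -> dict[str, str]:
    """Write the three tables, the registry list and the truth sidecar."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "visits": os.path.join(outdir, "visits.csv"),
        "diagnoses": os.path.join(outdir, "diagnoses.csv"),
        "demographics": os.path.join(outdir, "demographics.csv"),
        "registry": os.path.join(outdir, "registry_ids.txt"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    for name, df in (("visits", pop.visits), ("diagnoses", pop.diagnoses),
                     ("demographics", pop.demographics)):
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(paths[name], index=False, lineterminator="\r\n")
    with open(paths["registry"], "w") as fh:
        fh.write("\n".join(pop.registry_ids) + ("\n" if pop.registry_ids else ""))
    pop.truth.to_json(paths["truth"])
    return paths


def read_visits(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, parse_dates=["date"])
    return df


def read_diagnoses(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str, "code": str},
                       parse_dates=["date"])


def read_demographics(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str},
                       parse_dates=["birth_date"])


def read_registry(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
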
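"""Cohort construction: eligibility, index-visit selection, exclusions.

A patient is eligible if some BMI-bearing visit (the candidate *index
visit*) has another visit at least 365 days before it and another at
least 365 days after it — which also guarantees >= 3 visits spanning
>= 2 years and a full year of follow-up for incidence. Patients with
several candidate index visits have one chosen uniformly at random from a
per-patient stream keyed by (seed, patient_id), so the choice is stable
under row reordering. Patients with a pregnancy or cancer code at any
time, or listed in the bariatric-surgery registry, are excluded; ages
outside 18-75 years at the index visit are filtered.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anthro_cleaning import clean_visits
from .comorbidity_timing import CodeSet, classify_cohort, normalize_code
from .config import ConfigurationError

YEAR_DAYS = 365


@dataclass(frozen=True)
class EligibleInterval:
    patient_id: str
    index_date: pd.Timestamp
    prior_visit_date: pd.Timestamp
    followup_visit_date: pd.Timestamp


def patient_uniform(seed: int, patient_id: str) -> float:
    """A deterministic U(0,1) draw keyed by (seed, patient_id).

    Hash-derived rather than positional so that cohort membership does not
    depend on the order patients appear in the input files.
    """
    digest = hashlib.blake2b(f"{seed}:{patient_id}".encode(),
                             digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2.0 ** 64


def find_eligible_intervals(visits: pd.DataFrame) -> list[EligibleInterval]:
    """All candidate index visits for one patient.

    ``visits`` holds one patient's cleaned visits with a ``bmi`` column
    (NaN where no BMI could be computed). Any visit counts as the prior or
    follow-up anchor; only the index visit itself needs a BMI.
    """
    if visits.empty:
        return []
    pid = visits["patient_id"].iloc[0]
    dates = pd.to_datetime(visits["date"]).sort_values().reset_index(drop=True)
    first, last = dates.iloc[0], dates.iloc[-1]
    out = []
    sub = visits.dropna(subset=["bmi"]).sort_values("date")
    for d in pd.to_datetime(sub["date"]):
        if (d - first).days >= YEAR_DAYS and (last - d).days >= YEAR_DAYS:
            prior = dates[dates <= d - pd.Timedelta(days=YEAR_DAYS)].max()
            follow = dates[dates >= d + pd.Timedelta(days=YEAR_DAYS)].min()
            out.append(EligibleInterval(pid, d, prior, follow))
    return out


def select_index_visit(intervals: Sequence[EligibleInterval],
                       seed: int) -> EligibleInterval:
    """Uniform random choice among a patient's candidate index visits."""
    if not intervals:
        raise ValueError("no eligible intervals to choose from")
    ordered = sorted(intervals, key=lambda iv: iv.index_date)
    u = patient_uniform(seed, ordered[0].patient_id)
    return ordered[min(int(u * len(ordered)), len(ordered) - 1)]


def apply_exclusions(patient_ids: Sequence[str], diagnoses: pd.DataFrame,
                     registry_ids: Sequence[str],
                     exclusion_code_sets: Mapping[str, Sequence[str]],
                     ) -> tuple[list[str], pd.DataFrame]:
    """Drop patients with any matching code at any date or in the registry.

    Returns (retained ids, audit). The audit records each excluded patient
    once with the first triggering reason: code-set categories in the
    order configured, then registry membership.
    """
    for category, prefixes in exclusion_code_sets.items():
        if not prefixes:
            raise ConfigurationError(f"{category}: empty exclusion code set")
    ids = pd.Index(patient_ids)
    reason = pd.Series(index=ids, dtype=object)
    if len(diagnoses):
        codes = diagnoses["code"].map(normalize_code)
        for category, prefixes in exclusion_code_sets.items():
            pref = tuple(normalize_code(p) for p in prefixes)
            hit_ids = diagnoses.loc[codes.str.startswith(pref), "patient_id"]
            mask = reason.isna() & ids.isin(set(hit_ids))
            reason[mask] = category
    mask = reason.isna() & ids.isin(set(registry_ids))
    reason[mask] = "registry"

    audit = (reason.dropna().rename("reason").rename_axis("patient_id")
             .reset_index())
    retained = list(ids[reason.isna()])
    return retained, audit


def _candidate_index_table(cleaned: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Vectorized index-visit selection over all patients at once.

    Equivalent to find_eligible_intervals + select_index_visit per
    patient, but linear-time over the whole visit table.
    """
    g = cleaned.groupby("patient_id")["date"]
    first = g.transform("min")
    last = g.transform("max")
    ok = (cleaned["bmi"].notna()
          & ((cleaned["date"] - first).dt.days >= YEAR_DAYS)
          & ((last - cleaned["date"]).dt.days >= YEAR_DAYS))
    cand = cleaned.loc[ok, ["patient_id", "date", "bmi"]]
    cand = cand.sort_values(["patient_id", "date"], kind="mergesort")
    sizes = cand.groupby("patient_id")["date"].transform("size")
    rank = cand.groupby("patient_id").cumcount()
    u = cand["patient_id"].map(
        lambda p: patient_uniform(seed, p)).to_numpy(dtype=float)
    pick = np.minimum((u * sizes.to_numpy()).astype(int),
                      sizes.to_numpy() - 1)
    chosen = cand[rank.to_numpy() == pick]
    return chosen.rename(columns={"date": "index_date",
                                  "bmi": "baseline_bmi"})


def build_cohort(visits: pd.DataFrame, diagnoses: pd.DataFrame,
                 demographics: pd.DataFrame, registry_ids: Sequence[str],
                 code_sets: Mapping[str, CodeSet], seed: int,
                 exclusion_code_sets: Mapping[str, Sequence[str]] | None = None,
                 age_bounds: tuple[float, float] = (18.0, 75.0),
                 window_days: int = YEAR_DAYS) -> pd.DataFrame:
    """Full cohort assembly: cleaning -> eligibility -> random index ->
    exclusions -> age filter -> covariates and per-comorbidity status.

    Returns one row per retained patient with baseline BMI, age at index,
    demographic covariates and a status column per comorbidity. The result
    is deterministic given (inputs, seed) and invariant to input row order.
    """
    if exclusion_code_sets is None:
        exclusion_code_sets = {"pregnancy": ["Z34", "V22"],
                               "cancer": ["C50", "174"]}
    cleaned = clean_visits(visits)
    chosen = _candidate_index_table(cleaned, seed)
    if chosen.empty:
        import warnings
        warnings.warn("cohort is empty: no patient satisfies the visit windows")
        cols = (["patient_id", "index_date", "baseline_bmi", "age_at_index",
                 "sex", "race_ethnicity", "insurance", "smoking"]
                + list(code_sets))
        return pd.DataFrame(columns=cols)

    retained, _ = apply_exclusions(chosen["patient_id"].tolist(), diagnoses,
                                   registry_ids, exclusion_code_sets)
    chosen = chosen[chosen["patient_id"].isin(set(retained))]

    cohort = chosen.merge(demographics, on="patient_id", how="left")
    age = (cohort["index_date"]
           - cohort["birth_date"]).dt.days / 365.25
    cohort["age_at_index"] = age
    cohort = cohort[(age >= age_bounds[0]) & (age <= age_bounds[1])]

    index_dates = cohort.set_index("patient_id")["index_date"]
    status = classify_cohort(diagnoses, index_dates, code_sets,
                             window_days=window_days)
    cohort = cohort.set_index("patient_id").join(status).reset_index()
    cols = (["patient_id", "index_date", "baseline_bmi", "age_at_index",
             "sex", "race_ethnicity", "insurance", "smoking"]
            + list(code_sets))
    return (cohort[cols].sort_values("patient_id", kind="mergesort")
            .reset_index(drop=True))
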
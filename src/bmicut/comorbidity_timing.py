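"""Prevalent/incident classification and 1-year incidence rates.

A patient is *prevalent* for a comorbidity if any matching diagnosis code
is dated at or before the index visit, *incident* if the first matching
code falls within the year after the index visit (half-open window
``(index, index + 365 d]``), and *free* otherwise. Because the study
design guarantees at least one year of follow-up after the index visit,
each at-risk (non-prevalent) patient contributes exactly one person-year,
and the rate per 100 person-years equals 100 x incident / at-risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .config import ConfigurationError

PREVALENT, INCIDENT, FREE = "prevalent", "incident", "free"


def normalize_code(code: str) -> str:
    """Case- and dot-insensitive code spelling: 'e11.9' == 'E119'."""
    return code.replace(".", "").strip().upper()


@dataclass(frozen=True)
class CodeSet:
    """Diagnosis-code prefixes naming one comorbidity ('E11' matches E11.9)."""

    name: str
    prefixes: tuple[str, ...]

    def __post_init__(self):
        if not self.prefixes:
            raise ConfigurationError(f"{self.name}: empty code set")
        object.__setattr__(self, "prefixes",
                           tuple(normalize_code(p) for p in self.prefixes))

    def matches(self, code: str) -> bool:
        return normalize_code(code).startswith(self.prefixes)


def load_code_sets(path: str) -> dict[str, CodeSet]:
    """Read a YAML mapping {comorbidity: [prefixes]}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: CodeSet(name, tuple(str(p) for p in prefixes))
            for name, prefixes in raw.items()}


def dump_code_sets(code_sets: Mapping[str, CodeSet | Sequence[str]],
                   path: str) -> None:
    raw = {name: (list(cs.prefixes) if isinstance(cs, CodeSet) else list(cs))
           for name, cs in code_sets.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def classify_disease_status(events: Iterable[tuple], index_date,
                            code_set: CodeSet,
                            window_days: int = 365) -> str:
    """Classify one patient for one comorbidity from (date, code) events."""
    index_date = pd.Timestamp(index_date)
    horizon = index_date + pd.Timedelta(days=window_days)
    status = FREE
    for date, code in events:
        if not code_set.matches(code):
            continue
        date = pd.Timestamp(date)
        if date <= index_date:
            return PREVALENT
        if date <= horizon:
            status = INCIDENT
    return status


def classify_cohort(diagnoses: pd.DataFrame, index_dates: pd.Series,
                    code_sets: Mapping[str, CodeSet],
                    window_days: int = 365) -> pd.DataFrame:
    """Vectorized status per patient (rows = index_dates.index) per comorbidity.

    ``index_dates`` maps patient_id -> index date; patients without any
    matching code are ``free``.
    """
    out = pd.DataFrame(index=index_dates.index)
    if len(diagnoses):
        codes = diagnoses["code"].map(normalize_code)
    for name, cs in code_sets.items():
        col = pd.Series(FREE, index=index_dates.index, dtype=object)
        if len(diagnoses):
            hit = diagnoses[codes.str.startswith(cs.prefixes)]
            hit = hit[hit["patient_id"].isin(index_dates.index)]
            if len(hit):
                first = hit.groupby("patient_id")["date"].min()
                idx = index_dates.loc[first.index]
                col.loc[first.index[first <= idx]] = PREVALENT
                inc = (first > idx) & (first <= idx
                                       + pd.Timedelta(days=window_days))
                col.loc[first.index[inc]] = INCIDENT
        out[name] = col
    return out


@dataclass(frozen=True)
class IncidenceResult:
    """1-year incidence for one comorbidity on one subset of the cohort."""

    comorbidity: str
    n_at_risk: int
    n_incident: int
    rate: float | None  # cases per 100 person-years; None if no one at risk

    @property
    def defined(self) -> bool:
        return self.rate is not None


def incidence_rate(cohort: pd.DataFrame, comorbidity: str,
                   subset: pd.Series | None = None) -> IncidenceResult:
    """Rate per 100 person-years on a cohort subset (boolean mask or None).

    Prevalent patients are removed from the denominator; each remaining
    patient contributes one person-year.
    """
    status = cohort[comorbidity]
    mask = pd.Series(True, index=cohort.index) if subset is None else subset
    at_risk = mask & (status != PREVALENT)
    n_at_risk = int(at_risk.sum())
    n_incident = int((status[at_risk] == INCIDENT).sum())
    rate = 100.0 * n_incident / n_at_risk if n_at_risk else None
    return IncidenceResult(comorbidity, n_at_risk, n_incident, rate)


def incidence_table(cohort: pd.DataFrame,
                    comorbidities: Sequence[str]) -> pd.DataFrame:
    """Per-comorbidity at-risk counts, incident counts and rates."""
    rows = []
    for name in comorbidities:
        r = incidence_rate(cohort, name)
        rows.append((name, r.n_at_risk, r.n_incident, r.rate))
    return pd.DataFrame(rows, columns=["comorbidity", "n_at_risk",
                                       "n_incident", "rate_per_100py"])
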
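import pandas as pd
import pytest

from bmicut import GeneratorConfig, build_cohort, generate_population
from bmicut.comorbidity_timing import CodeSet


@pytest.fixture(scope="session")
def small_population():
    """One modest synthetic EHR shared across tests (config, population)."""
    config = GeneratorConfig(n_patients=800)
    return config, generate_population(config, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_population):
    config, pop = small_population
    code_sets = {name: CodeSet(name, tuple(prefixes))
                 for name, prefixes in config.code_sets().items()}
    cohort = build_cohort(pop.visits, pop.diagnoses, pop.demographics,
                          pop.registry_ids, code_sets, seed=11)
    return config, pop, cohort


def _mk_visits(patient_days: dict[str, list[int]],
               base: str = "2010-01-01") -> pd.DataFrame:
    rows = []
    start = pd.Timestamp(base)
    for pid, days in patient_days.items():
        for d in days:
            rows.append((pid, start + pd.Timedelta(days=d), 70.0, 180.0))
    return pd.DataFrame(rows, columns=["patient_id", "date", "height_in",
                                       "weight_lb"])


@pytest.fixture
def handcrafted_six():
    """Six handcrafted patients: 2 fail visit spacing, 1 carries an
    exclusion code, 3 should survive into the cohort."""
    visits = _mk_visits({
        "A": [0, 400, 800],
        "B": [0, 400, 800],      # excluded: pregnancy code
        "C": [0, 100, 200],      # spacing failure
        "D": [0, 300, 600],      # spacing failure
        "E": [0, 370, 500, 900],
        "F": [10, 380, 800, 1200],
    })
    diagnoses = pd.DataFrame(
        [("B", pd.Timestamp("2011-05-01"), "Z34.9"),
         ("A", pd.Timestamp("2011-03-01"), "E11.4"),
         ("E", pd.Timestamp("2008-01-01"), "I10")],
        columns=["patient_id", "date", "code"])
    demographics = pd.DataFrame(
        [(p, pd.Timestamp("1970-06-15"), "female", "White-NH",
          "commercial", "non") for p in "ABCDEF"],
        columns=["patient_id", "birth_date", "sex", "race_ethnicity",
                 "insurance", "smoking"])
    return visits, diagnoses, demographics
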
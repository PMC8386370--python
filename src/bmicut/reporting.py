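"""End-to-end pipeline runs and descriptive reporting tables.

``run_pipeline`` takes a PipelineConfig, obtains the three input tables
(from the synthetic generator or from CSV paths), and writes every output
of the analysis — cleaning audit, cohort, incidence table, median-BMI
contrasts, cut-point tables overall / by sex / by race-ethnicity, the
incidence-vs-prevalence comparison and per-comorbidity baseline
comparison tables — plus a JSON manifest with row counts and content
hashes. A rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import synthetic_ehr
from .anthro_cleaning import clean_visits, cleaning_audit
from .cohort_builder import build_cohort
from .comorbidity_timing import (CodeSet, INCIDENT, PREVALENT, incidence_table,
                                 load_code_sets)
from .config import PipelineConfig
from .cutpoint_analysis import (cohort_cutpoint, cutpoint_table,
                                incidence_vs_prevalence_table, rates_above_below,
                                subgroup_table)
from .quantile_assoc import contrast_table

log = logging.getLogger("bmicut")


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """A printed cohort percentage: 100 * count / total, rounded."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def baseline_comparison_table(cohort: pd.DataFrame, comorbidity: str,
                              comorbidities=None) -> pd.DataFrame:
    """Baseline characteristics of incident vs non-incident patients.

    At-risk patients only (prevalent cases excluded). Continuous rows give
    mean (SD); categorical rows give n (%); the remaining comorbidities
    contribute their baseline-prevalence rows. Empty groups yield NaN
    cells rather than an error.
    """
    at_risk = cohort[cohort[comorbidity] != PREVALENT]
    inc = at_risk[at_risk[comorbidity] == INCIDENT]
    ref = at_risk[at_risk[comorbidity] != INCIDENT]
    rows = [("n", len(inc), len(ref))]

    def mean_sd(g, col):
        return (f"{g[col].mean():.1f} ({g[col].std():.1f})"
                if len(g) else float("nan"))

    for label, col in (("age, mean (SD)", "age_at_index"),
                       ("baseline BMI, mean (SD)", "baseline_bmi")):
        rows.append((label, mean_sd(inc, col), mean_sd(ref, col)))

    def counts(g, col, level):
        n = int((g[col] == level).sum())
        return f"{n} ({100 * n / len(g):.1f}%)" if len(g) else float("nan")

    for col in ("sex", "race_ethnicity", "smoking"):
        for level in sorted(cohort[col].dropna().unique()):
            rows.append((f"{col}={level}", counts(inc, col, level),
                         counts(ref, col, level)))
    for other in (comorbidities or []):
        if other == comorbidity:
            continue
        rows.append((f"prevalent {other}",
                     counts(inc, other, PREVALENT),
                     counts(ref, other, PREVALENT)))
    return pd.DataFrame(rows, columns=["characteristic", "incident",
                                       "non_incident"])


def plot_incidence_vs_bmi(cohort: pd.DataFrame, comorbidity: str,
                          cutpoint: float, path: str,
                          bin_width: float = 2.0) -> None:
    """Incidence per 100 person-years across BMI bins with the cut point
    marked, in the style of a cut-point figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    at_risk = cohort[cohort[comorbidity] != PREVALENT]
    bins = np.arange(15, 62, bin_width)
    mids, rates = [], []
    for lo in bins[:-1]:
        sub = at_risk[(at_risk["baseline_bmi"] >= lo)
                      & (at_risk["baseline_bmi"] < lo + bin_width)]
        if len(sub) >= 20:
            mids.append(lo + bin_width / 2)
            rates.append(100 * (sub[comorbidity] == INCIDENT).mean())
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(mids, rates, "o-", color="tab:blue")
    ax.axvline(cutpoint, ls=":", color="black")
    ax.annotate(f"{cutpoint:.1f}", (cutpoint, ax.get_ylim()[1] * 0.9))
    ax.set_xlabel("baseline BMI (kg/m$^2$)")
    ax.set_ylabel("incidence per 100 PY")
    ax.set_title(comorbidity)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_csv(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.6g")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis once; returns the manifest dictionary."""
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    t0 = time.time()

    if config.generator is not None:
        pop = synthetic_ehr.generate_population(config.generator, config.seed)
        visits, diagnoses = pop.visits, pop.diagnoses
        demographics, registry = pop.demographics, pop.registry_ids
        code_sets = {name: CodeSet(name, tuple(prefixes))
                     for name, prefixes in
                     config.generator.code_sets().items()}
    else:
        visits = synthetic_ehr.read_visits(config.visits_path)
        diagnoses = synthetic_ehr.read_diagnoses(config.diagnoses_path)
        demographics = synthetic_ehr.read_demographics(
            config.demographics_path)
        registry = (synthetic_ehr.read_registry(config.registry_path)
                    if config.registry_path else [])
        if config.code_sets_path is None:
            raise FileNotFoundError("code_sets_path is required when "
                                    "reading CSV inputs")
        code_sets = load_code_sets(config.code_sets_path)
    comorbidities = list(code_sets)
    log.info("inputs: %d visits, %d diagnoses, %d patients (%.1fs)",
             len(visits), len(diagnoses), len(demographics), time.time() - t0)

    cleaned = clean_visits(visits)
    cohort = build_cohort(visits, diagnoses, demographics, registry,
                          code_sets, seed=config.seed,
                          age_bounds=config.age_bounds,
                          window_days=config.window_days)
    log.info("cohort: %d rows (%.1fs)", len(cohort), time.time() - t0)

    outputs: dict[str, pd.DataFrame] = {
        "cleaning_audit.csv": cleaning_audit(cleaned),
        "cohort.csv": cohort,
        "incidence.csv": incidence_table(cohort, comorbidities),
        "median_contrasts.csv": contrast_table(
            cohort, comorbidities, seed=config.seed + 1,
            n_bootstrap=config.n_bootstrap),
        "cutpoints_overall.csv": cutpoint_table(cohort, comorbidities,
                                                gate=config.auroc_gate),
    }
    log.info("contrasts done (%.1fs)", time.time() - t0)

    outputs["cutpoints_by_sex.csv"] = subgroup_table(
        cohort, comorbidities, "sex", reference_level="male",
        seed=config.seed + 2, n_resamples=config.n_bootstrap,
        gate=config.auroc_gate)
    outputs["cutpoints_by_race.csv"] = subgroup_table(
        cohort, comorbidities, "race_ethnicity", reference_level="White-NH",
        seed=config.seed + 3, n_resamples=config.n_bootstrap,
        gate=config.auroc_gate)
    outputs["incidence_vs_prevalence.csv"] = incidence_vs_prevalence_table(
        cohort, comorbidities, seed=config.seed + 4,
        n_resamples=config.n_bootstrap, gate=config.auroc_gate)
    log.info("cut points done (%.1fs)", time.time() - t0)

    # rates above/below + baseline comparisons for defined cut points only
    rate_rows = []
    for name in comorbidities:
        r = cohort_cutpoint(cohort, name, gate=config.auroc_gate)
        if not r.defined:
            continue
        below, above = rates_above_below(cohort, name, r.cutpoint)
        rate_rows.append((name, r.cutpoint, below.rate, above.rate))
        outputs[f"baseline_comparison_{name}.csv"] = \
            baseline_comparison_table(cohort, name, comorbidities)
        if config.make_plots:
            plot_incidence_vs_bmi(
                cohort, name, r.cutpoint,
                os.path.join(config.output_dir, f"incidence_{name}.png"))
    outputs["rates_above_below.csv"] = pd.DataFrame(
        rate_rows, columns=["comorbidity", "cutpoint", "rate_below",
                            "rate_above"])

    manifest = {"seed": config.seed, "files": {}}
    for fname, df in outputs.items():
        path = os.path.join(config.output_dir, fname)
        _write_csv(df, path)
        manifest["files"][fname] = {"rows": int(len(df)),
                                    "sha256": _sha256(path)}
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %d files (%.1fs)",
             len(manifest["files"]), time.time() - t0)
    return manifest
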
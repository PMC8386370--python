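"""Generator determinism, calibration against its own truth, corruption
accounting, and configuration validation."""

import numpy as np
import pandas as pd
import pytest

from bmicut import (ComorbidityModel, ConfigurationError, ErrorSpec,
                    GeneratorConfig, generate_population,
                    simulate_screening_sample, true_cutpoint)
from bmicut.anthro_cleaning import (HEIGHT_MAX, HEIGHT_MIN, WEIGHT_MAX,
                                    WEIGHT_MIN)


def _step_model(theta=30.0, delta=3.0, base=0.03, **kw):
    return ComorbidityModel(name="disease", codes=("E11",),
                            prevalence_intercept=-9.0,
                            prevalence_bmi_slope=0.0,
                            incidence_base_rate=base,
                            incidence_threshold=theta,
                            incidence_effect=delta, **kw)


def test_empty_population():
    pop = generate_population(GeneratorConfig(n_patients=0), seed=3)
    assert len(pop.visits) == 0 and len(pop.diagnoses) == 0
    assert len(pop.truth.onsets) == 0 and pop.registry_ids == []


def test_determinism_and_seed_sensitivity():
    config = GeneratorConfig(n_patients=300)
    a = generate_population(config, seed=5)
    b = generate_population(config, seed=5)
    pd.testing.assert_frame_equal(a.visits, b.visits)
    pd.testing.assert_frame_equal(a.diagnoses, b.diagnoses)
    pd.testing.assert_frame_equal(a.demographics, b.demographics)
    c = generate_population(config, seed=6)
    assert not a.visits.equals(c.visits)


def test_no_corruption_means_plausible_tables():
    config = GeneratorConfig(n_patients=400, errors=ErrorSpec.none())
    pop = generate_population(config, seed=2)
    h = pop.visits["height_in"]
    w = pop.visits["weight_lb"]
    assert h.notna().all()
    assert ((h >= HEIGHT_MIN) & (h <= HEIGHT_MAX)).all()
    assert ((w >= WEIGHT_MIN) & (w <= WEIGHT_MAX)).all()
    assert pop.corruption_counts == {"missing_height": 0, "height_typo": 0,
                                     "weight_typo": 0}


def test_visit_dates_inside_window():
    config = GeneratorConfig(n_patients=200)
    pop = generate_population(config, seed=9)
    assert (pop.visits["date"] > pd.Timestamp(config.start_date)).all()
    assert (pop.visits["date"] < pd.Timestamp(config.end_date)).all()


def test_step_effect_visible_in_truth_counts():
    """With a large step at theta=30, incident onsets among at-risk
    patients with baseline BMI >= 30 outnumber (as a fraction) those
    below, counted directly from the truth object."""
    model = _step_model(theta=30.0, delta=3.0)
    config = GeneratorConfig(n_patients=2000, comorbidities=(model,))
    pop = generate_population(config, seed=7)
    truth = pop.truth
    onsets = truth.onsets[~truth.onsets["prevalent_at_start"]]
    has_onset = set(onsets["patient_id"])
    pat = truth.patients
    above = pat["bmi_intercept"] >= 30.0
    frac_above = pat.loc[above, "patient_id"].isin(has_onset).mean()
    frac_below = pat.loc[~above, "patient_id"].isin(has_onset).mean()
    assert frac_above > frac_below


def test_marginal_incidence_calibration():
    """delta=0 and flat age effect: realized 1-year incidence matches the
    base rate within 3 binomial SEs."""
    base = 0.04
    model = _step_model(delta=0.0, base=base)
    bmi, label = simulate_screening_sample(model, n=40000, seed=21)
    se = np.sqrt(base * (1 - base) / label.size)
    assert abs(label.mean() - base) < 3 * se
    # and the step raises incidence only above theta
    bmi2, label2 = simulate_screening_sample(_step_model(delta=2.0,
                                                         base=base),
                                             n=40000, seed=22)
    assert label2[bmi2 >= 30].mean() > label2[bmi2 < 30].mean() * 3


def test_corruption_accounting_matches_table_diff():
    config = GeneratorConfig(n_patients=600)
    pop = generate_population(config, seed=13)
    h0 = pop.visits_uncorrupted["height_in"].to_numpy()
    h1 = pop.visits["height_in"].to_numpy()
    w0 = pop.visits_uncorrupted["weight_lb"].to_numpy()
    w1 = pop.visits["weight_lb"].to_numpy()
    n_missing = int(np.isnan(h1).sum() - np.isnan(h0).sum())
    n_h_typo = int((~np.isnan(h1) & (h0 != h1)).sum())
    n_w_typo = int((w0 != w1).sum())
    assert pop.corruption_counts == {"missing_height": n_missing,
                                     "height_typo": n_h_typo,
                                     "weight_typo": n_w_typo}
    assert len(pop.corruption_log) == sum(pop.corruption_counts.values())


def test_true_cutpoint_accessor():
    models = (_step_model(theta=30.0),)
    assert true_cutpoint(models, "disease") == 30.0
    models = (_step_model(theta=27.5),)
    assert true_cutpoint(models, "disease") == 27.5
    with pytest.raises(KeyError, match="disease"):
        true_cutpoint(models, "unknown")


@pytest.mark.parametrize("bad, match", [
    (dict(n_patients=-1), "n_patients"),
    (dict(n_patients=10, p_female=1.5), "p_female"),
    (dict(n_patients=10, visits_per_patient=0.0), "visits_per_patient"),
])
def test_config_errors_name_the_field(bad, match):
    with pytest.raises(ConfigurationError, match=match):
        GeneratorConfig(**bad).validate()


def test_bad_error_spec_and_model_rejected():
    with pytest.raises(ConfigurationError, match="p_missing_height"):
        ErrorSpec(p_missing_height=2.0).validate()
    with pytest.raises(ConfigurationError, match="incidence_base_rate"):
        _step_model(base=0.0).validate()
    with pytest.raises(ConfigurationError, match="incidence_threshold"):
        _step_model(theta=80.0).validate()
    with pytest.raises(ConfigurationError, match="end_date"):
        from datetime import date
        GeneratorConfig(n_patients=1, start_date=date(2010, 1, 1),
                        end_date=date(2009, 1, 1)).validate()


def test_onsets_lie_inside_window(small_population):
    config, pop = small_population
    on = pop.truth.onsets["onset_date"]
    assert (on >= pd.Timestamp(config.start_date)).all()
    assert (on <= pd.Timestamp(config.end_date)).all()
    # every onset has a diagnosis code on its onset date
    merged = pop.truth.onsets.merge(
        pop.diagnoses, left_on=["patient_id", "onset_date"],
        right_on=["patient_id", "date"], how="left")
    assert merged["code"].notna().all()
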
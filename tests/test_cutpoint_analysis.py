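"""ROC/AUROC, Youden cut points, subgroups, bootstrap comparisons."""

import numpy as np
import pandas as pd
import pytest

from bmicut import (ComorbidityModel, auroc, bootstrap_compare_cutpoints,
                    find_cutpoint, prevalence_cutpoint, rates_above_below,
                    roc_curve, simulate_screening_sample, subgroup_cutpoints,
                    youden_index)
from bmicut.comorbidity_timing import FREE, INCIDENT, PREVALENT
from bmicut.cutpoint_analysis import cohort_cutpoint, cutpoint_table


def brute_force_auroc(bmi, label):
    """O(n^2) pairwise concordance with ties counted one half."""
    bmi = np.asarray(bmi, dtype=float)
    label = np.asarray(label).astype(bool)
    pos, neg = bmi[label], bmi[~label]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


def test_roc_perfect_separation():
    curve = roc_curve([40, 41, 20, 21], [1, 1, 0, 0])
    i = list(curve.thresholds).index(40.0)
    assert curve.sensitivity[i] == 1.0 and curve.specificity[i] == 1.0
    # endpoints present; monotone in the right directions
    assert curve.sensitivity[0] == 1.0 and curve.specificity[0] == 0.0
    assert curve.sensitivity[-1] == 0.0 and curve.specificity[-1] == 1.0
    assert (np.diff(curve.sensitivity) <= 0).all()
    assert (np.diff(curve.specificity) >= 0).all()


def test_degenerate_all_equal_is_chance():
    assert auroc([25, 25, 25, 25], [1, 0, 1, 0]) == pytest.approx(0.5)


def test_single_class_errors():
    with pytest.raises(ValueError, match="single class"):
        roc_curve([1, 2], [1, 1])
    with pytest.raises(ValueError, match="single class"):
        auroc([1, 2], [0, 0])


def test_roc_matches_exhaustive_enumeration():
    bmi = np.array([22.0, 25.0, 25.0, 28.0, 31.0, 35.0])
    label = np.array([0, 0, 1, 0, 1, 1])
    curve = roc_curve(bmi, label)
    pos, neg = bmi[label == 1], bmi[label == 0]
    for t, se, sp in zip(curve.thresholds, curve.sensitivity,
                         curve.specificity):
        if np.isfinite(t):
            assert se == (pos >= t).mean()
            assert sp == (neg < t).mean()


def test_auroc_equals_concordance_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(6, 60))
        bmi = np.round(rng.normal(29, 6, n), 1)  # rounding forces ties
        label = rng.random(n) < 0.4
        if label.all() or not label.any():
            continue
        assert auroc(bmi, label) == pytest.approx(
            brute_force_auroc(bmi, label), abs=1e-12)


def test_auroc_null_is_half():
    model = ComorbidityModel(name="d", codes=("X",),
                             prevalence_intercept=-9, prevalence_bmi_slope=0,
                             incidence_base_rate=0.2,
                             incidence_threshold=30, incidence_effect=0.0)
    bmi, label = simulate_screening_sample(model, 2000, seed=8)
    # null SE of AUROC is roughly sqrt(1/12 (1/n1 + 1/n0))
    n1 = label.sum()
    se = np.sqrt((1 / n1 + 1 / (2000 - n1)) / 12)
    assert abs(auroc(bmi, label) - 0.5) < 3 * se


def test_sklearn_agreement():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(3)
    bmi = np.round(rng.normal(29, 6, 500), 1)
    label = rng.random(500) < (0.1 + 0.4 * (bmi > 30))
    assert auroc(bmi, label) == pytest.approx(roc_auc_score(label, bmi),
                                              abs=1e-12)


@pytest.mark.parametrize("se, sp, j", [
    (0.72, 0.666, 0.386),
    (1.0, 1.0, 1.0),
    (0.5, 0.5, 0.0),
])
def test_youden_values(se, sp, j):
    assert youden_index(se, sp) == pytest.approx(j, abs=1e-12)


def test_youden_rejects_out_of_range():
    with pytest.raises(ValueError, match="sensitivity"):
        youden_index(1.2, 0.5)
    with pytest.raises(ValueError, match="specificity"):
        youden_index(0.5, -0.1)


def test_find_cutpoint_gate_and_tie_rule():
    # alternating classes: AUROC far below the 0.6 gate
    r = find_cutpoint([20, 21, 22, 23], [1, 0, 1, 0])
    assert not r.defined and r.cutpoint is None and r.reason == "auroc_gate"

    # J ties at thresholds 2 and 4; the smaller BMI must win
    r = find_cutpoint([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1], gate=0.51)
    assert r.defined and r.cutpoint == 2.0
    assert r.youden == pytest.approx(r.sensitivity + r.specificity - 1,
                                     abs=1e-12)


def test_cutpoint_is_global_youden_maximum():
    rng = np.random.default_rng(5)
    bmi = np.round(rng.normal(29, 6, 400), 1)
    label = rng.random(400) < (0.05 + 0.5 * (bmi >= 31))
    r = find_cutpoint(bmi, label)
    assert r.defined
    pos, neg = bmi[label], bmi[~label]
    best = max((pos >= t).mean() + (neg < t).mean() - 1
               for t in np.unique(bmi))
    assert r.youden == pytest.approx(best, abs=1e-12)
    assert r.cutpoint in bmi


def _make_cohort(theta_f=28.0, theta_m=32.0, n=6000, seed=0, delta=3.0):
    rng = np.random.default_rng(seed)
    model_f = ComorbidityModel(name="d", codes=("X",),
                               prevalence_intercept=-9,
                               prevalence_bmi_slope=0,
                               incidence_base_rate=0.03,
                               incidence_threshold=theta_f,
                               incidence_effect=delta)
    model_m = ComorbidityModel(name="d", codes=("X",),
                               prevalence_intercept=-9,
                               prevalence_bmi_slope=0,
                               incidence_base_rate=0.03,
                               incidence_threshold=theta_m,
                               incidence_effect=delta)
    bmi_f, lab_f = simulate_screening_sample(model_f, n, seed=seed + 1)
    bmi_m, lab_m = simulate_screening_sample(model_m, n, seed=seed + 2)
    return pd.DataFrame({
        "baseline_bmi": np.concatenate([bmi_f, bmi_m]),
        "sex": ["female"] * n + ["male"] * n,
        "d": np.where(np.concatenate([lab_f, lab_m]) == 1, INCIDENT, FREE)})


def test_subgroup_cutpoints_ordered_by_planted_thresholds():
    cohort = _make_cohort()
    results = {r.subset: r for r in subgroup_cutpoints(cohort, "d", "sex")}
    assert results["female"].defined and results["male"].defined
    assert results["female"].cutpoint < results["male"].cutpoint
    assert results["female"].cutpoint == pytest.approx(28.0, abs=1.5)
    assert results["male"].cutpoint == pytest.approx(32.0, abs=1.5)


def test_subgroup_degenerate_stratum_not_defined():
    cohort = _make_cohort(n=300)
    cohort.loc[cohort["sex"] == "male", "d"] = FREE  # zero incident males
    results = {r.subset: r for r in subgroup_cutpoints(cohort, "d", "sex")}
    assert not results["male"].defined
    assert results["male"].reason == "single_class"


def test_single_stratum_matches_overall():
    cohort = _make_cohort(n=2000)
    cohort["sex"] = "female"
    only = subgroup_cutpoints(cohort, "d", "sex")
    assert len(only) == 1
    overall = cohort_cutpoint(cohort, "d")
    assert only[0].cutpoint == overall.cutpoint
    assert only[0].auroc == pytest.approx(overall.auroc)


def test_bootstrap_determinism_and_null():
    cohort = _make_cohort(theta_f=30, theta_m=30, n=4000, seed=9)
    f = cohort[cohort["sex"] == "female"]
    a = (f["baseline_bmi"].to_numpy(), (f["d"] == INCIDENT).to_numpy())
    cmp1 = bootstrap_compare_cutpoints(a, a, n_resamples=150, seed=4)
    cmp2 = bootstrap_compare_cutpoints(a, a, n_resamples=150, seed=4)
    assert cmp1.p_value == cmp2.p_value
    # a set compared with itself: p should be far from significant
    assert cmp1.p_value >= 0.5
    with pytest.raises(ValueError):
        bootstrap_compare_cutpoints(a, a, n_resamples=0, seed=1)


def test_bootstrap_detects_large_separation():
    cohort = _make_cohort(theta_f=27, theta_m=33, n=8000, seed=11)
    f = cohort[cohort["sex"] == "female"]
    m = cohort[cohort["sex"] == "male"]
    cmp_ = bootstrap_compare_cutpoints(
        (f["baseline_bmi"].to_numpy(), (f["d"] == INCIDENT).to_numpy()),
        (m["baseline_bmi"].to_numpy(), (m["d"] == INCIDENT).to_numpy()),
        n_resamples=200, seed=5)
    assert cmp_.p_value < 0.05


def test_prevalence_cutpoint_and_rates(small_cohort):
    config, pop, cohort = small_cohort
    no_prev = cohort.copy()
    no_prev["type_2_diabetes"] = FREE
    with pytest.raises(ValueError):
        prevalence_cutpoint(no_prev, "type_2_diabetes")

    r = prevalence_cutpoint(cohort, "hypertension")
    assert r.subset == "prevalence" and r.auroc is not None

    with pytest.raises(ValueError):
        rates_above_below(cohort, "hypertension", None)
    below, above = rates_above_below(cohort, "hypertension", 28.5)
    assert below.n_at_risk + above.n_at_risk == \
        (cohort["hypertension"] != PREVALENT).sum()


def test_rates_above_exceed_below_under_step():
    cohort = _make_cohort(theta_f=30, theta_m=30, n=5000, seed=13)
    below, above = rates_above_below(cohort, "d", 30.0)
    assert above.rate > below.rate
    # with the step submerged, rates on both sides agree within noise
    null = _make_cohort(theta_f=30, theta_m=30, n=5000, seed=14, delta=0.0)
    b2, a2 = rates_above_below(null, "d", 30.0)
    pooled = (b2.n_incident + a2.n_incident) / (b2.n_at_risk + a2.n_at_risk)
    se = 100 * np.sqrt(pooled * (1 - pooled)
                       * (1 / b2.n_at_risk + 1 / a2.n_at_risk))
    assert abs(a2.rate - b2.rate) < 3 * se


def test_cutpoint_table_shape(small_cohort):
    config, _, cohort = small_cohort
    names = [m.name for m in config.comorbidities]
    table = cutpoint_table(cohort, names)
    assert list(table["comorbidity"]) == names
    defined = table["cutpoint"].notna()
    assert (table.loc[defined, "auroc"] > 0.6).all()
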
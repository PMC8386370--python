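"""BMI cut points: ROC curves, the AUROC gate, Youden maximization,
subgroup and prevalence analyses, and bootstrap cut-point comparisons.

BMI is treated as a screening test for one-year comorbidity incidence,
with the positive direction "BMI >= threshold". Sensitivity and
specificity are swept over every observed BMI value; a comorbidity *has*
a cut point only when the area under the ROC curve exceeds 0.6 (strict),
and the cut point is then the observed BMI value maximizing the Youden
index J = sensitivity + specificity - 1, ties broken toward the smaller
BMI (favoring earlier screening). Cut points between groups are compared
with a patient-level bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comorbidity_timing import INCIDENT, PREVALENT, incidence_rate, IncidenceResult

DEFAULT_GATE = 0.6


@dataclass(frozen=True)
class RocCurve:
    """Operating points at every threshold, positive = BMI >= threshold.

    ``thresholds`` ascend and include -inf and +inf sentinels so the
    endpoints (Se, Sp) = (1, 0) and (0, 1) are always present; sensitivity
    is non-increasing and specificity non-decreasing along the sweep.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


def roc_curve(bmi, label) -> RocCurve:
    """Threshold sweep over the unique observed BMI values."""
    bmi = np.asarray(bmi, dtype=float)
    label = np.asarray(label).astype(bool)
    _check_two_classes(label)
    pos = np.sort(bmi[label])
    neg = np.sort(bmi[~label])
    thresholds = np.concatenate([[-np.inf], np.unique(bmi), [np.inf]])
    # Se(t) = P(BMI >= t | case), Sp(t) = P(BMI < t | non-case)
    se = (pos.size - np.searchsorted(pos, thresholds, side="left")) / pos.size
    sp = np.searchsorted(neg, thresholds, side="left") / neg.size
    return RocCurve(thresholds, se, sp)


def auroc(bmi, label) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the Mann-Whitney concordance P(BMI_case > BMI_noncase) plus
    half the tie probability.
    """
    curve = roc_curve(bmi, label)
    fpr = 1.0 - curve.specificity  # descending as thresholds ascend
    return float(np.trapezoid(curve.sensitivity[::-1], fpr[::-1]))


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1 (0 at chance, 1 when perfect)."""
    for name, v in (("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {v!r} outside [0, 1]")
    return sensitivity + specificity - 1.0


@dataclass(frozen=True)
class CutpointResult:
    """One comorbidity on one subset: the gate decision and, when the gate
    passes, the Youden-optimal operating point."""

    comorbidity: str
    subset: str
    auroc: float | None
    defined: bool
    cutpoint: float | None
    youden: float | None
    sensitivity: float | None
    specificity: float | None
    n_at_risk: int
    n_incident: int
    reason: str | None = None  # why not defined: "auroc_gate"/"single_class"


def _check_two_classes(label: np.ndarray) -> None:
    if label.all() or not label.any():
        raise ValueError("both outcome classes must be present; "
                         "AUROC is undefined on a single class")


def _best_operating_point(bmi: np.ndarray, label: np.ndarray
                          ) -> tuple[float, float, float]:
    """(cutpoint, Se, Sp) maximizing J over observed BMI values; smallest
    BMI wins ties."""
    pos = np.sort(bmi[label])
    neg = np.sort(bmi[~label])
    cand = np.unique(bmi)
    se = (pos.size - np.searchsorted(pos, cand, side="left")) / pos.size
    sp = np.searchsorted(neg, cand, side="left") / neg.size
    j = se + sp - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    return float(cand[best]), float(se[best]), float(sp[best])


def find_cutpoint(bmi, label, comorbidity: str = "", subset: str = "overall",
                  gate: float = DEFAULT_GATE) -> CutpointResult:
    """AUROC gate then Youden maximization on one screening data set."""
    bmi = np.asarray(bmi, dtype=float)
    label = np.asarray(label).astype(bool)
    _check_two_classes(label)
    n, n_pos = label.size, int(label.sum())
    area = auroc(bmi, label)
    if not area > gate:
        return CutpointResult(comorbidity, subset, area, False, None, None,
                              None, None, n, n_pos, reason="auroc_gate")
    cut, se, sp = _best_operating_point(bmi, label)
    return CutpointResult(comorbidity, subset, area, True, cut,
                          youden_index(se, sp), se, sp, n, n_pos)


def _screening_arrays(cohort: pd.DataFrame, comorbidity: str
                      ) -> tuple[np.ndarray, np.ndarray]:
    """At-risk patients only: baseline BMI and incident indicator."""
    at_risk = cohort[cohort[comorbidity] != PREVALENT]
    bmi = at_risk["baseline_bmi"].to_numpy(dtype=float)
    label = (at_risk[comorbidity] == INCIDENT).to_numpy()
    return bmi, label


def cohort_cutpoint(cohort: pd.DataFrame, comorbidity: str,
                    subset: str = "overall",
                    gate: float = DEFAULT_GATE) -> CutpointResult:
    """find_cutpoint on the at-risk members of a cohort table."""
    bmi, label = _screening_arrays(cohort, comorbidity)
    if label.size == 0 or label.all() or not label.any():
        return CutpointResult(comorbidity, subset, None, False, None, None,
                              None, None, int(label.size), int(label.sum()),
                              reason="single_class")
    return find_cutpoint(bmi, label, comorbidity, subset, gate)


def subgroup_cutpoints(cohort: pd.DataFrame, comorbidity: str,
                       stratifier: str,
                       gate: float = DEFAULT_GATE) -> list[CutpointResult]:
    """Independent cut points within each level of sex or race/ethnicity.

    Degenerate strata (one outcome class) and strata failing the gate come
    back as not-defined results rather than being dropped.
    """
    if stratifier not in cohort.columns:
        raise KeyError(f"stratifier column {stratifier!r} not in cohort")
    out = []
    for level, sub in cohort.groupby(stratifier, sort=True):
        out.append(cohort_cutpoint(sub, comorbidity, subset=str(level),
                                   gate=gate))
    return out


@dataclass(frozen=True)
class BootstrapComparison:
    """Bootstrap test of cut-point equality between two screening sets."""

    label_a: str
    cutpoint_a: float
    label_b: str
    cutpoint_b: float
    n_resamples: int
    n_effective: int  # resamples where both gates passed
    p_value: float
    seed: int


def _cutpoint_only(bmi: np.ndarray, label: np.ndarray,
                   gate: float) -> float | None:
    """Fast path: gate then Youden argmax, no result object."""
    pos = np.sort(bmi[label])
    neg = np.sort(bmi[~label])
    if pos.size == 0 or neg.size == 0:
        return None
    cand = np.unique(bmi)
    se = (pos.size - np.searchsorted(pos, cand, side="left")) / pos.size
    sp = np.searchsorted(neg, cand, side="left") / neg.size
    # trapezoid over the full sweep including endpoints
    se_full = np.concatenate([[1.0], se, [0.0]])
    sp_full = np.concatenate([[0.0], sp, [1.0]])
    area = np.trapezoid(se_full[::-1], (1.0 - sp_full)[::-1])
    if not area > gate:
        return None
    j = se + sp - 1.0
    return float(cand[np.argmax(j)])


def bootstrap_compare_cutpoints(set_a, set_b, n_resamples: int = 1000,
                                seed: int = 0, gate: float = DEFAULT_GATE,
                                stratified: bool = False,
                                max_redraws: int = 10,
                                label_a: str = "a", label_b: str = "b",
                                ) -> BootstrapComparison:
    """Two-sided bootstrap p-value for a difference in cut points.

    Each of ``set_a``/``set_b`` is (bmi, label); both must pass the AUROC
    gate on the observed data. Patients are resampled with replacement
    (optionally within outcome class when ``stratified``), both cut points
    recomputed, and the difference collected; a resample where either gate
    fails is redrawn up to ``max_redraws`` times, then counted missing
    with a warning. p = 2 * min(P(D <= 0), P(D >= 0)) with the add-one
    correction (count + 1)/(n + 1), capped at 1.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    arrays = []
    for (bmi, label) in (set_a, set_b):
        bmi = np.asarray(bmi, dtype=float)
        label = np.asarray(label).astype(bool)
        _check_two_classes(label)
        arrays.append((bmi, label))
    observed = [_cutpoint_only(b, l, gate) for b, l in arrays]
    if any(c is None for c in observed):
        raise ValueError("both sets must pass the AUROC gate on the "
                         "observed data")

    rng = np.random.default_rng(seed)

    def resample(bmi, label):
        n = bmi.size
        if stratified:
            pos_idx = np.flatnonzero(label)
            neg_idx = np.flatnonzero(~label)
            take = np.concatenate([
                pos_idx[rng.integers(0, pos_idx.size, pos_idx.size)],
                neg_idx[rng.integers(0, neg_idx.size, neg_idx.size)]])
        else:
            take = rng.integers(0, n, n)
        return bmi[take], label[take]

    deltas = np.full(n_resamples, np.nan)
    for b in range(n_resamples):
        for _ in range(max_redraws + 1):
            cut_a = _cutpoint_only(*resample(*arrays[0]), gate)
            cut_b = _cutpoint_only(*resample(*arrays[1]), gate)
            if cut_a is not None and cut_b is not None:
                deltas[b] = cut_a - cut_b
                break
    missing = int(np.isnan(deltas).sum())
    if missing:
        warnings.warn(f"{missing}/{n_resamples} bootstrap resamples failed "
                      f"the AUROC gate after {max_redraws} redraws")
    deltas = deltas[~np.isnan(deltas)]
    m = deltas.size
    p_low = (np.sum(deltas <= 0) + 1) / (m + 1)
    p_high = (np.sum(deltas >= 0) + 1) / (m + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return BootstrapComparison(label_a, observed[0], label_b, observed[1],
                               n_resamples, m, float(p), seed)


def prevalence_cutpoint(cohort: pd.DataFrame, comorbidity: str,
                        gate: float = DEFAULT_GATE) -> CutpointResult:
    """Cut point with positive = prevalent at index, reference = everyone
    else, using baseline BMI (the denominator includes future incident
    cases)."""
    bmi = cohort["baseline_bmi"].to_numpy(dtype=float)
    label = (cohort[comorbidity] == PREVALENT).to_numpy()
    return find_cutpoint(bmi, label, comorbidity, subset="prevalence",
                         gate=gate)


def rates_above_below(cohort: pd.DataFrame, comorbidity: str,
                      cutpoint: float | None
                      ) -> tuple[IncidenceResult, IncidenceResult]:
    """1-year incidence per 100 person-years below vs at/above the cut point."""
    if cutpoint is None:
        raise ValueError("cut point is not defined for this comorbidity")
    below = cohort["baseline_bmi"] < cutpoint
    return (incidence_rate(cohort, comorbidity, below),
            incidence_rate(cohort, comorbidity, ~below))


# --- table builders --------------------------------------------------------

def cutpoint_table(cohort: pd.DataFrame, comorbidities,
                   gate: float = DEFAULT_GATE) -> pd.DataFrame:
    """Overall screening summary, one row per comorbidity (Table-2 shape)."""
    rows = []
    for name in comorbidities:
        r = cohort_cutpoint(cohort, name, gate=gate)
        rows.append((name, r.auroc, r.youden,
                     None if r.sensitivity is None else 100 * r.sensitivity,
                     None if r.specificity is None else 100 * r.specificity,
                     r.cutpoint, r.n_at_risk, r.n_incident))
    return pd.DataFrame(rows, columns=["comorbidity", "auroc", "youden",
                                       "sensitivity_pct", "specificity_pct",
                                       "cutpoint", "n_at_risk", "n_incident"])


def subgroup_table(cohort: pd.DataFrame, comorbidities, stratifier: str,
                   reference_level: str, seed: int,
                   n_resamples: int = 1000,
                   gate: float = DEFAULT_GATE) -> pd.DataFrame:
    """Per-stratum cut points plus bootstrap p-values vs a reference stratum.

    Comparisons are only made where both the stratum and the reference
    have defined cut points; otherwise the p-value cell stays empty.
    """
    rows = []
    for k, name in enumerate(comorbidities):
        results = {r.subset: r for r in
                   subgroup_cutpoints(cohort, name, stratifier, gate=gate)}
        ref = results.get(reference_level)
        for level, r in results.items():
            p = None
            if (level != reference_level and r.defined and ref is not None
                    and ref.defined):
                sub = cohort[cohort[stratifier] == level]
                refsub = cohort[cohort[stratifier] == reference_level]
                cmp_ = bootstrap_compare_cutpoints(
                    _screening_arrays(sub, name),
                    _screening_arrays(refsub, name),
                    n_resamples=n_resamples, seed=seed + 104729 * k,
                    gate=gate, label_a=level, label_b=reference_level)
                p = cmp_.p_value
            rows.append((name, level, r.auroc, r.cutpoint, r.youden,
                         p, r.reason))
    return pd.DataFrame(rows, columns=["comorbidity", stratifier, "auroc",
                                       "cutpoint", "youden",
                                       "p_vs_reference", "reason"])


def incidence_vs_prevalence_table(cohort: pd.DataFrame, comorbidities,
                                  seed: int, n_resamples: int = 1000,
                                  gate: float = DEFAULT_GATE) -> pd.DataFrame:
    """Incidence cut point vs prevalence cut point with a bootstrap p."""
    rows = []
    for k, name in enumerate(comorbidities):
        inc = cohort_cutpoint(cohort, name, gate=gate)
        try:
            prev = prevalence_cutpoint(cohort, name, gate=gate)
        except ValueError:  # no prevalent cases in this cohort
            rows.append((name, inc.cutpoint, None, None))
            continue
        p = None
        if inc.defined and prev.defined:
            prev_bmi = cohort["baseline_bmi"].to_numpy(dtype=float)
            prev_label = (cohort[name] == PREVALENT).to_numpy()
            cmp_ = bootstrap_compare_cutpoints(
                _screening_arrays(cohort, name), (prev_bmi, prev_label),
                n_resamples=n_resamples, seed=seed + 104729 * k, gate=gate,
                label_a="incidence", label_b="prevalence")
            p = cmp_.p_value
        rows.append((name, inc.cutpoint, prev.cutpoint, p))
    return pd.DataFrame(rows, columns=["comorbidity", "incidence_cutpoint",
                                       "prevalence_cutpoint", "p_value"])
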
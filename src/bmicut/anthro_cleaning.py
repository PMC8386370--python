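"""Longitudinal anthropometric cleaning: plausibility rules, imputation, BMI.

Heights and weights recorded across a patient's visits carry entry errors
(unit confusion, digit transpositions, blanks). Cleaning is per patient and
single pass:

* heights: remove >90 in or <44 in; then, on the survivors, if the
  patient's sample SD exceeds 2.5% of their mean, remove values more than
  1 SD from the mean;
* weights: remove >1000 lb or <55 lb; then, on the survivors, if the range
  is at least 50 lb remove values further than 70% of the range from the
  mean, and if the SD exceeds 20% of the mean remove values more than
  1 SD from the mean;
* missing heights: last valid carried forward, then next valid carried
  backward;
* BMI = 703 x weight(lb) / height(in)^2 wherever a valid weight and a
  valid-or-imputed height coexist.

All per-patient statistics use the sample SD (n-1 denominator; SD of a
singleton is 0), conditional-rule statistics are computed once on the
absolute-bound survivors, and comparisons are strict, so boundary values
are kept. Cleaning removes measurements, never patients.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

REASON_NONE = "none"
REASON_ABS_HIGH = "abs_bound_high"
REASON_ABS_LOW = "abs_bound_low"
REASON_SD = "sd_rule"
REASON_RANGE = "range_rule"

HEIGHT_MAX, HEIGHT_MIN = 90.0, 44.0
WEIGHT_MAX, WEIGHT_MIN = 1000.0, 55.0


class MalformedInputError(ValueError):
    """A non-positive height or weight: malformed, not merely implausible."""


def _sample_sd(values: np.ndarray) -> float:
    # singleton series have SD defined as 0 so conditional rules never fire
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def _check_positive(values: np.ndarray, what: str) -> None:
    present = ~np.isnan(values)
    if np.any(values[present] <= 0):
        bad = values[present][values[present] <= 0][0]
        raise MalformedInputError(f"non-positive {what} {bad!r}")


def clean_height_values(heights: Sequence[float]) -> list[str]:
    """Removal reason per height of one patient (``none`` = kept).

    NaN entries are missing, not removals; they pass through as ``none``
    and are resolved later by imputation.
    """
    h = np.asarray(heights, dtype=float)
    _check_positive(h, "height")
    reasons = np.full(h.shape, REASON_NONE, dtype=object)
    present = ~np.isnan(h)
    reasons[present & (h > HEIGHT_MAX)] = REASON_ABS_HIGH
    reasons[present & (h < HEIGHT_MIN)] = REASON_ABS_LOW

    surv = present & (reasons == REASON_NONE)
    vals = h[surv]
    if vals.size:
        mean, sd = float(vals.mean()), _sample_sd(vals)
        if sd > 0.025 * mean:
            reasons[surv & (np.abs(h - mean) > sd)] = REASON_SD
    return list(reasons)


def clean_weight_values(weights: Sequence[float]) -> list[str]:
    """Removal reason per weight of one patient (``none`` = kept)."""
    w = np.asarray(weights, dtype=float)
    _check_positive(w, "weight")
    reasons = np.full(w.shape, REASON_NONE, dtype=object)
    present = ~np.isnan(w)
    reasons[present & (w > WEIGHT_MAX)] = REASON_ABS_HIGH
    reasons[present & (w < WEIGHT_MIN)] = REASON_ABS_LOW

    surv = present & (reasons == REASON_NONE)
    vals = w[surv]
    if vals.size:
        mean = float(vals.mean())
        rng_ = float(vals.max() - vals.min())
        sd = _sample_sd(vals)
        if rng_ >= 50.0:
            reasons[surv & (np.abs(w - mean) > 0.70 * rng_)] = REASON_RANGE
        surv2 = surv & (reasons == REASON_NONE)
        if sd > 0.20 * mean:
            reasons[surv2 & (np.abs(w - mean) > sd)] = REASON_SD
    return list(reasons)


def clean_heights(records: Sequence[tuple]) -> list[tuple]:
    """(date, inches) -> (date, inches, valid, reason), order preserved."""
    reasons = clean_height_values([v for _, v in records])
    return [(d, v, r == REASON_NONE and not _isnan(v), r)
            for (d, v), r in zip(records, reasons)]


def clean_weights(records: Sequence[tuple]) -> list[tuple]:
    """(date, pounds) -> (date, pounds, valid, reason), order preserved."""
    reasons = clean_weight_values([v for _, v in records])
    return [(d, v, r == REASON_NONE and not _isnan(v), r)
            for (d, v), r in zip(records, reasons)]


def _isnan(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def impute_heights(records: Sequence[tuple]) -> list[tuple]:
    """Fill missing/invalid heights from the patient's valid ones.

    ``records`` is date-ordered (date, height, valid) per one patient.
    Returns (date, height, valid, imputed): last-valid carried forward,
    then next-valid carried backward. Patients with no valid height at all
    keep their missing values.
    """
    heights = [h if valid else np.nan for _, h, valid in records]
    filled = pd.Series(heights, dtype=float).ffill().bfill()
    out = []
    for (d, h, valid), f in zip(records, filled):
        if valid:
            out.append((d, h, True, False))
        elif not np.isnan(f):
            out.append((d, float(f), True, True))
        else:
            out.append((d, np.nan, False, False))
    return out


def compute_bmi(height_in: float, weight_lb: float) -> float:
    """BMI in kg/m^2 from inches and pounds; NaN if either is missing."""
    if _isnan(height_in) or _isnan(weight_lb):
        return float("nan")
    if height_in <= 0 or weight_lb <= 0:
        raise MalformedInputError(
            f"non-positive anthropometric ({height_in!r}, {weight_lb!r})")
    return 703.0 * weight_lb / height_in ** 2


# --- vectorized table interface --------------------------------------------

def clean_visits(visits: pd.DataFrame) -> pd.DataFrame:
    """Apply all cleaning rules to a visit table.

    Input columns: patient_id, date, height_in, weight_lb (NaN = missing).
    Output adds height_reason, weight_reason, height_valid, weight_valid,
    height_imputed, height_filled (post-imputation height) and bmi. Rows
    are returned sorted by (patient_id, date), one row per input row: no
    patient is ever dropped.
    """
    df = visits.copy()
    df = df.sort_values(["patient_id", "date"], kind="mergesort")
    df = df.reset_index(drop=True)
    h = df["height_in"].to_numpy(dtype=float)
    w = df["weight_lb"].to_numpy(dtype=float)
    _check_positive(h, "height")
    _check_positive(w, "weight")
    pid = df["patient_id"]

    h_reason = np.full(len(df), REASON_NONE, dtype=object)
    w_reason = np.full(len(df), REASON_NONE, dtype=object)
    h_present, w_present = ~np.isnan(h), ~np.isnan(w)
    h_reason[h_present & (h > HEIGHT_MAX)] = REASON_ABS_HIGH
    h_reason[h_present & (h < HEIGHT_MIN)] = REASON_ABS_LOW
    w_reason[w_present & (w > WEIGHT_MAX)] = REASON_ABS_HIGH
    w_reason[w_present & (w < WEIGHT_MIN)] = REASON_ABS_LOW

    # conditional rules on absolute-bound survivors, per patient, one pass
    hs = pd.Series(np.where(h_present & (h_reason == REASON_NONE), h, np.nan))
    g = hs.groupby(pid)
    mean, sd = g.transform("mean"), g.transform("std").fillna(0.0)
    fire = sd > 0.025 * mean
    h_reason[(fire & (np.abs(hs - mean) > sd)).to_numpy(dtype=bool)] = REASON_SD

    ws = pd.Series(np.where(w_present & (w_reason == REASON_NONE), w, np.nan))
    g = ws.groupby(pid)
    mean, sd = g.transform("mean"), g.transform("std").fillna(0.0)
    rng_ = g.transform("max") - g.transform("min")
    fire_range = rng_ >= 50.0
    range_mask = (fire_range & (np.abs(ws - mean) > 0.70 * rng_))
    w_reason[range_mask.to_numpy(dtype=bool)] = REASON_RANGE
    fire_sd = (sd > 0.20 * mean) & (w_reason == REASON_NONE)
    w_reason[(fire_sd & (np.abs(ws - mean) > sd)).to_numpy(dtype=bool)] = REASON_SD

    df["height_reason"] = h_reason
    df["weight_reason"] = w_reason
    df["height_valid"] = h_present & (h_reason == REASON_NONE)
    df["weight_valid"] = w_present & (w_reason == REASON_NONE)

    valid_h = pd.Series(np.where(df["height_valid"], h, np.nan))
    filled = valid_h.groupby(pid).transform(lambda s: s.ffill().bfill())
    df["height_filled"] = filled
    df["height_imputed"] = filled.notna() & ~df["height_valid"]

    wv = np.where(df["weight_valid"], w, np.nan)
    df["bmi"] = 703.0 * wv / filled.to_numpy(dtype=float) ** 2
    return df


def cleaning_audit(cleaned: pd.DataFrame) -> pd.DataFrame:
    """Long-form audit of removed and imputed cells, one row per action."""
    cols = ["patient_id", "date", "field", "value", "removal_reason"]
    parts = []
    hm = cleaned["height_reason"] != REASON_NONE
    parts.append(pd.DataFrame({
        "patient_id": cleaned.loc[hm, "patient_id"],
        "date": cleaned.loc[hm, "date"], "field": "height_in",
        "value": cleaned.loc[hm, "height_in"],
        "removal_reason": cleaned.loc[hm, "height_reason"]}))
    wm = cleaned["weight_reason"] != REASON_NONE
    parts.append(pd.DataFrame({
        "patient_id": cleaned.loc[wm, "patient_id"],
        "date": cleaned.loc[wm, "date"], "field": "weight_lb",
        "value": cleaned.loc[wm, "weight_lb"],
        "removal_reason": cleaned.loc[wm, "weight_reason"]}))
    im = cleaned["height_imputed"].astype(bool)
    parts.append(pd.DataFrame({
        "patient_id": cleaned.loc[im, "patient_id"],
        "date": cleaned.loc[im, "date"], "field": "height_in",
        "value": cleaned.loc[im, "height_filled"],
        "removal_reason": "imputed"}))
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=cols)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["patient_id", "date", "field"],
                           kind="mergesort").reset_index(drop=True)[cols]
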
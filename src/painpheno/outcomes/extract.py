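"""Pain-score extraction at the four assessment points.

All extractors return the mean of the scores recorded on a single
selected day, or NaN when no day qualifies:

* preoperative — latest day with observations in the 30 days before
  surgery (day 0 excluded);
* discharge — last inpatient day with observations;
* follow-up — the day closest to the target (21 or 56) within +/- 7
  days, earlier day winning ties.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

TARGET_DAYS = {"3wk": 21, "8wk": 56}
FOLLOWUP_TOLERANCE = 7


def _day_offsets(pain: pd.DataFrame, anchor) -> pd.Series:
    anchor = pd.Timestamp(anchor)
    return (pd.to_datetime(pain["date"]) - anchor).dt.days


def extract_preop_pain(pain: pd.DataFrame, surgery_date, window_days: int = 30) -> float:
    """Mean score on the latest pre-surgery day with observations."""
    if pain.empty:
        return float("nan")
    day = _day_offsets(pain, surgery_date)
    eligible = pain[(day >= -window_days) & (day <= -1)]
    if eligible.empty:
        return float("nan")
    days = day[eligible.index]
    last = days.max()
    return float(eligible.loc[days == last, "score"].astype(float).mean())


def extract_discharge_pain(pain: pd.DataFrame, surgery_date, discharge_date) -> float:
    """Mean score on the last inpatient day (surgery through discharge)."""
    if pain.empty:
        return float("nan")
    day = _day_offsets(pain, surgery_date)
    los = (pd.Timestamp(discharge_date) - pd.Timestamp(surgery_date)).days
    eligible = pain[(day >= 0) & (day <= los)]
    if eligible.empty:
        return float("nan")
    days = day[eligible.index]
    last = days.max()
    return float(eligible.loc[days == last, "score"].astype(float).mean())


def extract_followup_pain(
    pain: pd.DataFrame, surgery_date, target_day: int, tolerance: int = FOLLOWUP_TOLERANCE
) -> float:
    """Mean score on the in-window day closest to ``target_day``."""
    if target_day not in (21, 56):
        raise ValueError("target_day must be 21 or 56")
    if pain.empty:
        return float("nan")
    day = _day_offsets(pain, surgery_date)
    eligible = pain[(day >= target_day - tolerance) & (day <= target_day + tolerance)]
    if eligible.empty:
        return float("nan")
    days = day[eligible.index]
    # closest to target; earlier day wins ties
    best = min(days.unique(), key=lambda d: (abs(d - target_day), d))
    return float(eligible.loc[days == best, "score"].astype(float).mean())


def compute_delta(preop: float, postop: float) -> tuple[float, bool | None]:
    """Pain-control statistic: postop minus preop; worsened iff > 0.

    Missing operands give (NaN, None).
    """
    if preop is None or postop is None or np.isnan(preop) or np.isnan(postop):
        return float("nan"), None
    delta = postop - preop
    return delta, bool(delta > 0)


def extract_preop_pain_batch(pain: pd.DataFrame, anchors: pd.DataFrame) -> pd.DataFrame:
    """Vectorized preop extraction for many patients.

    ``anchors`` has columns patient_id and surgery_date; returns
    patient_id + preop_pain (NaN where unobserved).
    """
    out = anchors[["patient_id"]].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    if pain.empty:
        out["preop_pain"] = np.nan
        return out
    df = pain.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df = df.merge(
        anchors.assign(patient_id=anchors["patient_id"].astype(str)),
        on="patient_id",
        how="inner",
    )
    df["day"] = (pd.to_datetime(df["date"]) - pd.to_datetime(df["surgery_date"])).dt.days
    df = df[(df["day"] >= -30) & (df["day"] <= -1)]
    if df.empty:
        out["preop_pain"] = np.nan
        return out
    last = df.groupby("patient_id")["day"].transform("max")
    df = df[df["day"] == last]
    means = df.groupby("patient_id")["score"].mean().rename("preop_pain")
    return out.merge(means, on="patient_id", how="left")


def compute_outcomes(cohort: pd.DataFrame, pain: pd.DataFrame) -> pd.DataFrame:
    """Per-patient delta outcomes at the three postoperative points.

    ``cohort`` needs patient_id, surgery_date, discharge_date and
    (optionally) preop_pain; pain observations are matched by patient.
    Vectorized: one selection pass per assessment point.
    """
    base = cohort[["patient_id", "surgery_date", "discharge_date"]].copy()
    base["patient_id"] = base["patient_id"].astype(str)
    df = pain.copy()
    if df.empty:
        df = pd.DataFrame(columns=["patient_id", "date", "score"])
    df["patient_id"] = df["patient_id"].astype(str)
    df = df.merge(base, on="patient_id", how="inner")
    df["day"] = (pd.to_datetime(df["date"]) - pd.to_datetime(df["surgery_date"])).dt.days
    df["los"] = (
        pd.to_datetime(df["discharge_date"]) - pd.to_datetime(df["surgery_date"])
    ).dt.days
    df["score"] = df["score"].astype(float)

    out = base[["patient_id"]].copy()
    if "preop_pain" in cohort.columns:
        out["preop_pain"] = cohort["preop_pain"].astype(float).to_numpy()
    else:
        out = out.merge(
            extract_preop_pain_batch(pain, cohort[["patient_id", "surgery_date"]]),
            on="patient_id",
            how="left",
        )

    inpatient = df[(df["day"] >= 0) & (df["day"] <= df["los"])]
    if not inpatient.empty:
        last = inpatient.groupby("patient_id")["day"].transform("max")
        discharge = (
            inpatient[inpatient["day"] == last]
            .groupby("patient_id")["score"]
            .mean()
            .rename("postop_discharge")
        )
        out = out.merge(discharge, on="patient_id", how="left")
    else:
        out["postop_discharge"] = np.nan

    for tp, target in TARGET_DAYS.items():
        window = df[
            (df["day"] >= target - FOLLOWUP_TOLERANCE) & (df["day"] <= target + FOLLOWUP_TOLERANCE)
        ].copy()
        col = f"postop_{tp}"
        if window.empty:
            out[col] = np.nan
            continue
        window["dist"] = (window["day"] - target).abs()
        window = window.sort_values(["patient_id", "dist", "day"], kind="mergesort")
        best_day = window.drop_duplicates("patient_id", keep="first")[["patient_id", "day"]]
        window = window.merge(best_day, on=["patient_id", "day"], how="inner")
        out = out.merge(
            window.groupby("patient_id")["score"].mean().rename(col),
            on="patient_id",
            how="left",
        )

    for tp in ("discharge", "3wk", "8wk"):
        out[f"delta_{tp}"] = out[f"postop_{tp}"] - out["preop_pain"]
        delta = out[f"delta_{tp}"]
        worsened = pd.Series(pd.NA, index=out.index, dtype="boolean")
        worsened[delta.notna()] = delta[delta.notna()] > 0
        out[f"worsened_{tp}"] = worsened
    return out
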
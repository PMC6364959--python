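"""Exposure-group assignment and full cohort assembly.

Depressed = depression diagnosis code within a year of surgery, OR an
Affirmed depression note (NLP flag), OR — when enabled — an
antidepressant order plus a symptom concept match. SSRI+ = structured
SSRI order within 30 days before surgery OR a non-negated note mention.
Prodrug status comes from the discharge opioid prescription after
ingredient distillation; mixed prescriptions fall to the side with the
larger total OME (ties -> non-prodrug, misclassification-conservative).
"""

from __future__ import annotations

import datetime as dt
import logging

import pandas as pd

from .charlson import compute_charlson_category
from .medications import (
    classify_opioid,
    compute_daily_ome,
    distill_ingredients,
    flag_opioid_naive,
    load_ingredient_map,
    load_ome_table,
    therapeutic_class,
)

log = logging.getLogger(__name__)

DEPRESSION_CODE_PREFIXES = ("296.2", "296.3", "311", "F32", "F33")
ANTIDEPRESSANT_CLASSES = (
    "ssri", "snri", "tricyclic_antidepressant", "other_antidepressant",
)

HR_NORMAL_RANGE = (60.0, 100.0)
NORMAL_SYSTOLIC = 120.0
NORMAL_DIASTOLIC = 80.0
NORMAL_TEMPERATURE = 37.0


def _date(value) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.datetime):
        return value.date()
    return dt.date.fromisoformat(str(value))


def _days(later, earlier) -> int:
    return (_date(later) - _date(earlier)).days


def _classify_discharge(discharge_meds: pd.DataFrame, mapping, ome_table, mixed_policy: str):
    """Return ('prodrug'|'non_prodrug'|None, mixed_flag) for the discharge
    prescription."""
    weights = {"prodrug": 0.0, "non_prodrug": 0.0}
    present = {"prodrug": False, "non_prodrug": False}
    for row in discharge_meds.itertuples(index=False):
        route = str(getattr(row, "route", "oral")).strip().lower()
        dose = float(getattr(row, "dose_mg", 0.0) or 0.0)
        for ingredient in distill_ingredients(str(row.drug_name), mapping):
            cls = classify_opioid(ingredient)
            if cls == "not_opioid":
                continue
            present[cls] = True
            factor = ome_table.get((ingredient, route), ome_table.get((ingredient, "oral"), 0.0))
            weights[cls] += dose * factor
    if not present["prodrug"] and not present["non_prodrug"]:
        return None, False
    if present["prodrug"] != present["non_prodrug"]:
        return ("prodrug" if present["prodrug"] else "non_prodrug"), False
    if mixed_policy != "ome":
        raise ValueError(f"unknown mixed-prescription policy: {mixed_policy}")
    side = "prodrug" if weights["prodrug"] > weights["non_prodrug"] else "non_prodrug"
    log.info("mixed discharge prescription resolved to %s by OME weight", side)
    return side, True


def assign_groups(
    encounters: pd.DataFrame,
    diagnoses: pd.DataFrame,
    medications: pd.DataFrame,
    nlp_flags: pd.DataFrame,
    *,
    depression_code_prefixes=DEPRESSION_CODE_PREFIXES,
    depression_window_days: int = 365,
    ssri_window_days: int = 30,
    mixed_policy: str = "ome",
    med_symptom_arm: bool = False,
    symptom_flags: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign SSRI/prodrug groups and depression provenance.

    ``nlp_flags`` has columns patient_id, nlp_depressed, nlp_ssri.
    Non-depressed patients and patients without a discharge opioid are
    dropped and recorded in the attrition log. Returns (groups, attrition).
    """
    mapping = load_ingredient_map()
    ome_table = load_ome_table()
    flags = nlp_flags.set_index(nlp_flags["patient_id"].astype(str))
    dx_by_pid = dict(tuple(diagnoses.groupby(diagnoses["patient_id"].astype(str)))) if not diagnoses.empty else {}
    med_by_pid = dict(tuple(medications.groupby(medications["patient_id"].astype(str)))) if not medications.empty else {}
    symptom_by_pid = {}
    if symptom_flags is not None:
        symptom_by_pid = dict(
            zip(symptom_flags["patient_id"].astype(str), symptom_flags["has_symptom"])
        )

    rows, attrition = [], []
    for enc in encounters.itertuples(index=False):
        pid = str(enc.patient_id)
        surgery = _date(enc.surgery_date)
        dx = dx_by_pid.get(pid)
        meds = med_by_pid.get(pid)

        icd_dep = False
        if dx is not None:
            for row in dx.itertuples(index=False):
                if -depression_window_days <= _days(row.date, surgery) <= 0 and any(
                    str(row.code).startswith(p) for p in depression_code_prefixes
                ):
                    icd_dep = True
                    break
        nlp_dep = bool(flags["nlp_depressed"].get(pid, False))
        nlp_ssri = bool(flags["nlp_ssri"].get(pid, False))

        med_dep = False
        if med_symptom_arm and meds is not None:
            has_antidep = any(
                therapeutic_class(str(r.drug_name), mapping) in ANTIDEPRESSANT_CLASSES
                and -depression_window_days <= _days(r.date, surgery) <= 0
                for r in meds.itertuples(index=False)
            )
            med_dep = has_antidep and bool(symptom_by_pid.get(pid, False))

        source = sorted(
            s
            for s, flag in (("icd", icd_dep), ("note", nlp_dep), ("medication", med_dep))
            if flag
        )
        if not source:
            attrition.append({"patient_id": pid, "reason": "not_depressed"})
            continue

        ssri_structured = False
        if meds is not None:
            for r in meds.itertuples(index=False):
                if (
                    str(getattr(r, "order_type", "outpatient")) != "discharge"
                    and therapeutic_class(str(r.drug_name), mapping) == "ssri"
                    and -ssri_window_days <= _days(r.date, surgery) <= 0
                ):
                    ssri_structured = True
                    break
        ssri_pos = ssri_structured or nlp_ssri

        discharge_meds = (
            meds[meds["order_type"] == "discharge"]
            if meds is not None and "order_type" in meds
            else pd.DataFrame(columns=["drug_name", "dose_mg", "route"])
        )
        side, mixed = _classify_discharge(discharge_meds, mapping, ome_table, mixed_policy)
        if side is None:
            attrition.append({"patient_id": pid, "reason": "no_discharge_opioid"})
            continue
        group = f"SSRI{'+' if ssri_pos else '-'}/Pro{'+' if side == 'prodrug' else '-'}"
        rows.append(
            {
                "patient_id": pid,
                "surgery_date": surgery.isoformat(),
                "group": group,
                "depression_source": ";".join(source),
                "ssri_structured": ssri_structured,
                "ssri_note": nlp_ssri,
                "mixed_discharge": mixed,
            }
        )
    groups_df = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "surgery_date", "group", "depression_source",
            "ssri_structured", "ssri_note", "mixed_discharge",
        ],
    )
    attrition_df = pd.DataFrame(attrition, columns=["patient_id", "reason"])
    return groups_df, attrition_df


def build_cohort(
    extract_tables: dict[str, pd.DataFrame],
    nlp_flags: pd.DataFrame,
    **assign_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the full cohort table from an extract and NLP flags.

    ``extract_tables`` maps table names (patients, encounters, diagnoses,
    medications, vitals, pain) to data frames. Returns (cohort, attrition).
    """
    from painpheno.outcomes.extract import extract_preop_pain_batch
    from .surgeries import select_surgeries

    encounters = select_surgeries(extract_tables["encounters"])
    diagnoses = extract_tables["diagnoses"]
    medications = extract_tables["medications"]
    groups_df, attrition = assign_groups(encounters, diagnoses, medications, nlp_flags, **assign_kwargs)
    if groups_df.empty:
        return groups_df, attrition

    enc = encounters.copy()
    enc["patient_id"] = enc["patient_id"].astype(str)
    cohort = groups_df.merge(
        enc[
            ["patient_id", "discharge_date", "surgery_type", "age_at_surgery"]
        ],
        on="patient_id",
        how="left",
    )
    patients = extract_tables["patients"].copy()
    patients["patient_id"] = patients["patient_id"].astype(str)
    cohort = cohort.merge(
        patients[["patient_id", "gender", "race", "marital_status", "insurance", "bmi"]],
        on="patient_id",
        how="left",
    )

    med_by_pid = dict(tuple(medications.groupby(medications["patient_id"].astype(str)))) if not medications.empty else {}
    dx_by_pid = dict(tuple(diagnoses.groupby(diagnoses["patient_id"].astype(str)))) if not diagnoses.empty else {}
    omes, naives, charlsons = [], [], []
    for row in cohort.itertuples(index=False):
        pid = row.patient_id
        meds = med_by_pid.get(pid)
        los = max(_days(row.discharge_date, row.surgery_date), 1)
        if meds is not None:
            admins = meds[meds["order_type"] == "inpatient_admin"]
            outpatient = meds[meds["order_type"] == "outpatient"]
        else:
            admins = pd.DataFrame(columns=["drug_name", "dose_mg", "route"])
            outpatient = pd.DataFrame(columns=["drug_name", "date"])
        omes.append(round(compute_daily_ome(admins, los), 3))
        naives.append(flag_opioid_naive(outpatient, row.surgery_date))
        dx = dx_by_pid.get(pid)
        codes = []
        if dx is not None:
            codes = [
                (r.code, r.code_system)
                for r in dx.itertuples(index=False)
                if -365 <= _days(r.date, row.surgery_date) <= -1
            ]
        charlsons.append(compute_charlson_category(codes))
    cohort["daily_ome"] = omes
    cohort["opioid_naive"] = naives
    cohort["charlson_category"] = charlsons

    vitals = extract_tables["vitals"].copy()
    if not vitals.empty:
        vitals["patient_id"] = vitals["patient_id"].astype(str)
        vitals = vitals.drop_duplicates("patient_id", keep="last")
        cohort = cohort.merge(
            vitals[["patient_id", "systolic", "diastolic", "heart_rate", "temperature"]],
            on="patient_id",
            how="left",
        )
    else:
        for col in ("systolic", "diastolic", "heart_rate", "temperature"):
            cohort[col] = float("nan")
    cohort["systolic_dev"] = cohort["systolic"].astype(float) - NORMAL_SYSTOLIC
    cohort["diastolic_dev"] = cohort["diastolic"].astype(float) - NORMAL_DIASTOLIC
    cohort["temperature_dev"] = cohort["temperature"].astype(float) - NORMAL_TEMPERATURE
    hr = cohort["heart_rate"].astype(float)
    cohort["hr_category"] = "unknown"
    cohort.loc[hr.notna() & (hr >= HR_NORMAL_RANGE[0]) & (hr <= HR_NORMAL_RANGE[1]), "hr_category"] = "normal"
    cohort.loc[hr.notna() & ((hr < HR_NORMAL_RANGE[0]) | (hr > HR_NORMAL_RANGE[1])), "hr_category"] = "abnormal"
    cohort = cohort.drop(columns=["systolic", "diastolic", "heart_rate", "temperature"])

    preop = extract_preop_pain_batch(extract_tables["pain"], cohort[["patient_id", "surgery_date"]])
    cohort = cohort.merge(preop, on="patient_id", how="left")
    return cohort, attrition
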
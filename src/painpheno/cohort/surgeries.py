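"""Surgical-encounter eligibility."""

from __future__ import annotations

import pandas as pd

from painpheno.resources import read_table


def load_surgical_codes() -> set[str]:
    return set(read_table("surgical_codes.tsv")["code"])


def select_surgeries(
    encounters: pd.DataFrame, procedure_codes: set[str] | None = None
) -> pd.DataFrame:
    """Select one eligible surgical encounter per patient.

    Keeps adults (age >= 18 at surgery) who survived the hospitalization,
    restricted to the configured procedure-code list, taking the earliest
    surgery when a patient has several (ties broken by encounter id).
    """
    if encounters.empty:
        return encounters.copy()
    if procedure_codes is None:
        procedure_codes = load_surgical_codes()
    df = encounters.copy()
    df = df[df["procedure_code"].astype(str).isin(procedure_codes)]
    df = df[df["age_at_surgery"].astype(float) >= 18.0]
    died = df["died_in_hospital"]
    if died.dtype == object:
        died = died.astype(str).str.lower().isin(("true", "1", "yes"))
    df = df[~died.astype(bool)]
    df = df.sort_values(["patient_id", "surgery_date", "encounter_id"], kind="mergesort")
    return df.drop_duplicates(subset="patient_id", keep="first").reset_index(drop=True)
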
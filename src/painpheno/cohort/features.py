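"""The model feature matrix: 65 manifest-ordered predictors.

The manifest file is the single source of truth for feature names and
order; its length is validated at load time. Continuous features with
missing values are mean-imputed with a paired missingness indicator
(``preop_pain`` / ``preop_pain_missing``); imputation statistics are
supplied by the caller so cross-validation can use training-fold means.
"""

from __future__ import annotations

import datetime as dt
from functools import lru_cache

import numpy as np
import pandas as pd

from painpheno.resources import read_table

from .medications import load_ingredient_map, therapeutic_class

N_FEATURES = 65

_CATEGORICALS = {
    "gender": ("male", "female"),
    "race": ("white", "black", "hispanic", "asian", "other"),
    "marital_status": ("married", "single"),
    "insurance": ("private", "medicaid", "medicare", "other"),
}
_GROUP_COLUMNS = {
    "SSRI+/Pro+": "group_ssri_pos_pro_pos",
    "SSRI+/Pro-": "group_ssri_pos_pro_neg",
    "SSRI-/Pro+": "group_ssri_neg_pro_pos",
    "SSRI-/Pro-": "group_ssri_neg_pro_neg",
}


@lru_cache(maxsize=1)
def load_manifest() -> tuple[str, ...]:
    """Feature names in canonical order; validated to length 65."""
    manifest = read_table("feature_manifest.tsv")
    names = tuple(manifest["name"])
    if len(names) != N_FEATURES:
        raise ValueError(f"feature manifest must list {N_FEATURES} features, got {len(names)}")
    if len(set(names)) != len(names):
        raise ValueError("feature manifest contains duplicate names")
    return names


def _med_class_indicators(
    cohort: pd.DataFrame, medications: pd.DataFrame, window_days: int = 30
) -> pd.DataFrame:
    """Binary therapeutic-class indicators for pre-surgery orders."""
    mapping = load_ingredient_map()
    med_cols = [n for n in load_manifest() if n.startswith("med_")]
    out = pd.DataFrame(0, index=cohort["patient_id"], columns=med_cols)
    if medications.empty:
        return out
    meds = medications.copy()
    meds["patient_id"] = meds["patient_id"].astype(str)
    surgery = dict(zip(cohort["patient_id"], cohort["surgery_date"]))
    for row in meds.itertuples(index=False):
        pid = row.patient_id
        if pid not in surgery:
            continue
        if str(getattr(row, "order_type", "outpatient")) == "discharge":
            continue
        day = (
            dt.date.fromisoformat(str(row.date)) - dt.date.fromisoformat(str(surgery[pid]))
        ).days
        if not -window_days <= day <= 0:
            continue
        klass = therapeutic_class(str(row.drug_name), mapping)
        col = f"med_{klass}" if klass else None
        if col in out.columns:
            out.loc[pid, col] = 1
    return out


def build_feature_vectors(cohort: pd.DataFrame, medications: pd.DataFrame) -> pd.DataFrame:
    """Build the manifest-ordered feature matrix (one row per patient).

    ``preop_pain`` is left as NaN when missing, with
    ``preop_pain_missing`` set to 1; impute with :func:`impute_features`.
    """
    names = load_manifest()
    X = pd.DataFrame(index=cohort["patient_id"].astype(str))
    X["age"] = cohort["age_at_surgery"].astype(float).to_numpy()
    X["bmi"] = cohort["bmi"].astype(float).to_numpy()
    for field, levels in _CATEGORICALS.items():
        values = cohort[field].astype(str).str.lower().to_numpy()
        for level in levels:
            prefix = {"marital_status": "marital"}.get(field, field)
            X[f"{prefix}_{level}"] = (values == level).astype(int)
    X["charlson_3plus"] = (cohort["charlson_category"].astype(str) == "3+").astype(int).to_numpy()
    X["opioid_tolerant"] = (~cohort["opioid_naive"].astype(bool)).astype(int).to_numpy()
    X["daily_ome"] = cohort["daily_ome"].astype(float).to_numpy()
    preop = cohort["preop_pain"].astype(float).to_numpy()
    X["preop_pain"] = preop
    X["preop_pain_missing"] = np.isnan(preop).astype(int)
    for col in ("systolic_dev", "diastolic_dev", "temperature_dev"):
        X[col] = cohort[col].astype(float).to_numpy()
    hr = cohort["hr_category"].astype(str).to_numpy()
    for level in ("normal", "abnormal", "unknown"):
        X[f"hr_{level}"] = (hr == level).astype(int)
    stype = cohort["surgery_type"].astype(str).to_numpy()
    for level in ("orthopedic", "vascular", "general"):
        X[f"surgery_{level}"] = (stype == level).astype(int)
    group = cohort["group"].astype(str).to_numpy()
    for label, col in _GROUP_COLUMNS.items():
        X[col] = (group == label).astype(int)
    med = _med_class_indicators(cohort, medications)
    for col in med.columns:
        X[col] = med[col].to_numpy()
    X = X[list(names)]
    X.index.name = "patient_id"
    return X


def impute_features(
    X: pd.DataFrame, means: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Fill missing continuous entries with supplied (or column) means.

    Pass training-fold means when transforming validation data so no
    statistic leaks across the fold boundary.
    """
    filled = X.copy()
    if means is None:
        means = filled.mean(numeric_only=True)
    means = means.fillna(0.0)
    for col in filled.columns:
        if filled[col].isna().any():
            filled[col] = filled[col].fillna(means.get(col, 0.0))
    return filled, means
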
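"""Eligibility, opioid handling, Charlson, group assignment, features."""

import numpy as np
import pandas as pd
import pytest

from painpheno.cohort import (
    NON_PRODRUG_OPIOIDS,
    PRODRUG_OPIOIDS,
    build_feature_vectors,
    classify_opioid,
    compute_charlson_category,
    compute_charlson_score,
    compute_daily_ome,
    distill_ingredients,
    flag_opioid_naive,
    impute_features,
    load_manifest,
    load_ome_table,
    select_surgeries,
)
from painpheno.cohort.groups import assign_groups, build_cohort


def _enc(patient_id, surgery_date, code="47.01", age=50.0, died=False, eid="E1"):
    return {
        "encounter_id": eid,
        "patient_id": patient_id,
        "surgery_date": surgery_date,
        "admission_date": surgery_date,
        "discharge_date": surgery_date,
        "procedure_code": code,
        "code_system": "ICD-9",
        "surgery_type": "general",
        "age_at_surgery": age,
        "died_in_hospital": died,
    }


class TestSelectSurgeries:
    def test_first_surgery_kept(self):
        enc = pd.DataFrame(
            [
                _enc("p1", "2015-01-01", eid="E1"),
                _enc("p1", "2015-04-01", eid="E2"),
            ]
        )
        kept = select_surgeries(enc)
        assert len(kept) == 1
        assert kept.iloc[0]["encounter_id"] == "E1"

    def test_minor_excluded(self):
        enc = pd.DataFrame([_enc("p1", "2015-01-01", age=17.0)])
        assert select_surgeries(enc).empty

    def test_in_hospital_death_excluded(self):
        enc = pd.DataFrame([_enc("p1", "2015-01-01", died=True)])
        assert select_surgeries(enc).empty

    def test_unlisted_procedure_excluded(self):
        enc = pd.DataFrame([_enc("p1", "2015-01-01", code="99.99")])
        assert select_surgeries(enc).empty

    def test_empty_table(self):
        assert select_surgeries(pd.DataFrame()).empty


class TestOpioidClassification:
    @pytest.mark.parametrize("name,expected", [
        ("hydrocodone", "prodrug"),
        ("codeine", "prodrug"),
        ("tramadol", "prodrug"),
        ("morphine", "non_prodrug"),
        ("fentanyl", "non_prodrug"),
        ("hydromorphone", "non_prodrug"),
        ("oxycodone", "non_prodrug"),
        ("methadone", "non_prodrug"),
        ("acetaminophen", "not_opioid"),
        ("sertraline", "not_opioid"),
    ])
    def test_fixed_lists(self, name, expected):
        assert classify_opioid(name) == expected

    def test_lists_are_disjoint(self):
        assert not PRODRUG_OPIOIDS & NON_PRODRUG_OPIOIDS


class TestDistillIngredients:
    def test_combination_trade_name(self):
        assert distill_ingredients("Vicodin") == ["hydrocodone", "acetaminophen"]

    def test_salt_form(self):
        assert distill_ingredients("morphine sulfate") == ["morphine"]

    def test_unknown_passthrough(self, caplog):
        with caplog.at_level("WARNING"):
            out = distill_ingredients("zzz-unknown-drug")
        assert out == ["zzz-unknown-drug"]
        assert "unknown drug" in caplog.text

    @pytest.mark.parametrize("trade,generic", [
        ("vicodin", "hydrocodone"), ("norco", "hydrocodone"),
        ("lortab", "hydrocodone"), ("percocet", "oxycodone"),
        ("oxycontin", "oxycodone"), ("ultram", "tramadol"),
    ])
    def test_trade_generic_same_opioid_class(self, trade, generic):
        trade_classes = {classify_opioid(i) for i in distill_ingredients(trade)}
        trade_classes.discard("not_opioid")
        assert trade_classes == {classify_opioid(generic)}


class TestDailyOME:
    def _admins(self, rows):
        return pd.DataFrame(rows, columns=["drug_name", "dose_mg", "route"])

    def test_oral_morphine_factor_one(self):
        admins = self._admins([("morphine", 30.0, "oral")])
        assert compute_daily_ome(admins, 1) == 30.0

    def test_oxycodone_factor(self):
        table = load_ome_table()
        assert table[("oxycodone", "oral")] == 1.5
        admins = self._admins([("oxycodone", 20.0, "oral")])
        assert compute_daily_ome(admins, 1) == 30.0

    def test_no_administrations(self):
        assert compute_daily_ome(self._admins([]), 3) == 0.0

    def test_averaged_over_stay(self):
        admins = self._admins([("morphine", 30.0, "oral"), ("morphine", 30.0, "oral")])
        assert compute_daily_ome(admins, 2) == 30.0

    def test_missing_factor_skipped(self, caplog):
        admins = self._admins([("methadone", 10.0, "rectal"), ("morphine", 10.0, "oral")])
        with caplog.at_level("WARNING"):
            assert compute_daily_ome(admins, 1) == 10.0
        assert "conversion factor" in caplog.text

    def test_zero_day_stay_rejected(self):
        with pytest.raises(ValueError):
            compute_daily_ome(self._admins([]), 0)


class TestOpioidNaive:
    ADMISSION = "2015-06-01"

    def _orders(self, rows):
        return pd.DataFrame(rows, columns=["drug_name", "date"])

    def test_recent_opioid_not_naive(self):
        orders = self._orders([("oxycodone", "2015-02-21")])  # day -100
        assert flag_opioid_naive(orders, self.ADMISSION) is False

    def test_only_nsaids_naive(self):
        orders = self._orders([("ibuprofen", "2015-05-01")])
        assert flag_opioid_naive(orders, self.ADMISSION) is True

    def test_old_opioid_outside_window_naive(self):
        orders = self._orders([("oxycodone", "2014-04-27")])  # day -400
        assert flag_opioid_naive(orders, self.ADMISSION) is True

    def test_trade_name_counts(self):
        orders = self._orders([("vicodin", "2015-05-01")])
        assert flag_opioid_naive(orders, self.ADMISSION) is False


class TestCharlson:
    def test_no_codes(self):
        assert compute_charlson_category([]) == "0-2"

    def test_metastatic_cancer_weight_six(self):
        assert compute_charlson_score([("C78.0", "ICD-10")]) == 6
        assert compute_charlson_category([("C78.0", "ICD-10")]) == "3+"

    def test_condition_counted_once(self):
        codes = [("I50.1", "ICD-10"), ("I50.9", "ICD-10")]
        assert compute_charlson_score(codes) == 1

    def test_weights_sum_across_conditions(self):
        codes = [("I50.9", "ICD-10"), ("N18.4", "ICD-10")]
        assert compute_charlson_score(codes) == 3

    def test_monotone_adding_codes(self, rng):
        pool = [("I21.0", "ICD-10"), ("N18.5", "ICD-10"), ("C78.1", "ICD-10"),
                ("J44.9", "ICD-10"), ("G81.0", "ICD-10")]
        order = {"0-2": 0, "3+": 1}
        for _ in range(20):
            k = int(rng.integers(0, len(pool)))
            subset = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
            extra = subset + [pool[int(rng.integers(0, len(pool)))]]
            assert (
                order[compute_charlson_category(extra)]
                >= order[compute_charlson_category(subset)]
            )


class TestAssignGroups:
    def _flags(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "nlp_depressed", "nlp_ssri"])

    def _meds(self, rows):
        return pd.DataFrame(
            rows, columns=["patient_id", "drug_name", "date", "dose_mg", "route", "order_type"]
        )

    def test_icd_only_with_ssri_and_prodrug(self):
        enc = pd.DataFrame([_enc("p1", "2015-06-01")])
        dx = pd.DataFrame(
            [{"patient_id": "p1", "date": "2015-01-01", "code": "F32.9", "code_system": "ICD-10"}]
        )
        meds = self._meds([
            ("p1", "sertraline", "2015-05-20", 50.0, "oral", "outpatient"),
            ("p1", "hydrocodone", "2015-06-01", 5.0, "oral", "discharge"),
        ])
        groups, attrition = assign_groups(enc, dx, meds, self._flags([("p1", False, False)]))
        assert groups.iloc[0]["group"] == "SSRI+/Pro+"
        assert groups.iloc[0]["depression_source"] == "icd"
        assert attrition.empty

    def test_nlp_only_no_ssri_nonprodrug(self):
        enc = pd.DataFrame([_enc("p1", "2015-06-01")])
        meds = self._meds([("p1", "oxycodone", "2015-06-01", 5.0, "oral", "discharge")])
        groups, _ = assign_groups(
            enc, pd.DataFrame(columns=["patient_id", "date", "code", "code_system"]),
            meds, self._flags([("p1", True, False)]),
        )
        assert groups.iloc[0]["group"] == "SSRI-/Pro-"
        assert groups.iloc[0]["depression_source"] == "note"

    def test_not_depressed_dropped(self):
        enc = pd.DataFrame([_enc("p1", "2015-06-01")])
        meds = self._meds([("p1", "oxycodone", "2015-06-01", 5.0, "oral", "discharge")])
        groups, attrition = assign_groups(
            enc, pd.DataFrame(columns=["patient_id", "date", "code", "code_system"]),
            meds, self._flags([("p1", False, False)]),
        )
        assert groups.empty
        assert attrition.iloc[0]["reason"] == "not_depressed"

    def test_no_discharge_opioid_logged(self):
        enc = pd.DataFrame([_enc("p1", "2015-06-01")])
        meds = self._meds([("p1", "acetaminophen", "2015-06-01", 500.0, "oral", "discharge")])
        groups, attrition = assign_groups(
            enc, pd.DataFrame(columns=["patient_id", "date", "code", "code_system"]),
            meds, self._flags([("p1", True, False)]),
        )
        assert groups.empty
        assert attrition.iloc[0]["reason"] == "no_discharge_opioid"

    def test_mixed_prescription_resolved_by_ome(self):
        enc = pd.DataFrame([_enc("p1", "2015-06-01"), _enc("p2", "2015-06-01", eid="E2")])
        meds = self._meds([
            # p1: hydrocodone 30mg (OME 30) vs oxycodone 5mg (OME 7.5) -> prodrug
            ("p1", "hydrocodone", "2015-06-01", 30.0, "oral", "discharge"),
            ("p1", "oxycodone", "2015-06-01", 5.0, "oral", "discharge"),
            # p2: equal OME -> tie -> non_prodrug
            ("p2", "hydrocodone", "2015-06-01", 15.0, "oral", "discharge"),
            ("p2", "oxycodone", "2015-06-01", 10.0, "oral", "discharge"),
        ])
        flags = self._flags([("p1", True, False), ("p2", True, False)])
        groups, _ = assign_groups(
            enc, pd.DataFrame(columns=["patient_id", "date", "code", "code_system"]), meds, flags
        )
        by_pid = groups.set_index("patient_id")
        assert by_pid.loc["p1", "group"] == "SSRI-/Pro+"
        assert by_pid.loc["p2", "group"] == "SSRI-/Pro-"
        assert by_pid["mixed_discharge"].all()

    def test_synthetic_recovery_100_percent(self, pipeline_small, extract_small):
        cohort = pipeline_small["cohort"]
        gold = extract_small.gold["patients"]
        assert len(cohort) == sum(1 for g in gold.values() if g["eligible"])
        for row in cohort.itertuples(index=False):
            assert row.group == gold[row.patient_id]["group"], row.patient_id

    def test_partition_disjoint_and_exhaustive(self, pipeline_small):
        cohort = pipeline_small["cohort"]
        counts = cohort["group"].value_counts()
        assert counts.sum() == len(cohort)
        assert set(counts.index) <= {"SSRI+/Pro+", "SSRI+/Pro-", "SSRI-/Pro+", "SSRI-/Pro-"}


class TestFeatures:
    def test_manifest_has_65_features(self):
        assert len(load_manifest()) == 65

    def test_feature_matrix_shape_and_order(self, pipeline_small):
        features = pipeline_small["features"]
        assert list(features.columns) == list(load_manifest())
        assert len(features) == len(pipeline_small["cohort"])

    def test_one_hot_blocks_sum_to_one(self, pipeline_small):
        X = pipeline_small["features"]
        for block in (
            ["gender_male", "gender_female"],
            ["race_white", "race_black", "race_hispanic", "race_asian", "race_other"],
            ["hr_normal", "hr_abnormal", "hr_unknown"],
            ["group_ssri_pos_pro_pos", "group_ssri_pos_pro_neg",
             "group_ssri_neg_pro_pos", "group_ssri_neg_pro_neg"],
        ):
            assert (X[block].sum(axis=1) == 1).all(), block

    def test_missing_preop_flagged_and_imputed(self, pipeline_small):
        X = pipeline_small["features"]
        missing = X["preop_pain"].isna()
        assert (X.loc[missing, "preop_pain_missing"] == 1).all()
        assert (X.loc[~missing, "preop_pain_missing"] == 0).all()
        filled, means = impute_features(X)
        assert not filled.isna().any().any()
        observed_mean = X["preop_pain"].dropna().mean()
        assert filled.loc[missing, "preop_pain"].iloc[0] == pytest.approx(observed_mean)

    def test_impute_with_training_means(self, pipeline_small):
        X = pipeline_small["features"]
        means = pd.Series({c: 0.0 for c in X.columns})
        filled, _ = impute_features(X, means)
        assert (filled.loc[X["preop_pain"].isna(), "preop_pain"] == 0.0).all()

    def test_systolic_deviation_arithmetic(self, pipeline_small, extract_small):
        cohort = pipeline_small["cohort"].set_index("patient_id")
        vitals = extract_small.vitals.set_index("patient_id")
        pid = cohort.index[0]
        assert cohort.loc[pid, "systolic_dev"] == pytest.approx(
            float(vitals.loc[pid, "systolic"]) - 120.0
        )

    def test_ssri_med_class_indicator(self, pipeline_small, extract_small):
        X = pipeline_small["features"]
        gold = extract_small.gold["patients"]
        for pid, g in gold.items():
            if g["eligible"] and g["ssri_structured"]:
                assert X.loc[pid, "med_ssri"] == 1, pid


def test_build_cohort_attrition_accounts_for_everyone(pipeline_small, extract_small):
    cohort = pipeline_small["cohort"]
    attrition = pipeline_small["attrition"]
    eligible = sum(1 for g in extract_small.gold["patients"].values() if g["eligible"])
    assert len(cohort) + len(attrition) == eligible
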
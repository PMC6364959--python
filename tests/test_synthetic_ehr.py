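"""Generator determinism, allocation, gold consistency and marginal
recovery."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from painpheno.synthetic_ehr import (
    GROUPS,
    GeneratorConfig,
    allocate_counts,
    expected_observed_delta,
    generate_cohort,
    generate_pain_trajectories,
)
from painpheno.synthetic_ehr.config import ConfigurationError
from painpheno.synthetic_ehr.templates import ALL_TEMPLATES


class TestConfig:
    def test_non_summing_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(group_proportions=(0.3, 0.3, 0.3, 0.3))

    def test_zero_sd_rejected(self):
        cfg = {"SSRI+/Pro+": {"discharge": 0.0, "3wk": 1.0, "8wk": 1.0}}
        base = GeneratorConfig()
        bad = {g: dict(v) for g, v in base.delta_sds.items()}
        bad["SSRI+/Pro+"]["discharge"] = 0.0
        with pytest.raises(ConfigurationError):
            GeneratorConfig(delta_sds=bad)

    def test_retention_range(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(followup_retention={"preop": 1.0, "discharge": 0.0, "3wk": 1.0, "8wk": 1.0})

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig.from_dict({"n_patient": 10})


class TestAllocation:
    def test_reference_group_counts(self):
        # printed four-group proportions at the printed cohort size
        counts = allocate_counts(4306, (0.1407, 0.2984, 0.1863, 0.3746))
        assert counts == [606, 1285, 802, 1613]
        assert sum(counts) == 4306

    def test_sums_to_n(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            raw = rng.random(4) + 0.01
            props = raw / raw.sum()
            n = int(rng.integers(1, 5000))
            assert sum(allocate_counts(n, props)) == n

    def test_provenance_triple_exact(self):
        cfg = GeneratorConfig(n_patients=5978, icd_note_overlap=(1912, 2315, 1751))
        assert cfg.provenance_counts() == [1912, 2315, 1751]


class TestGenerateCohort:
    def test_empty_extract(self):
        extract = generate_cohort(GeneratorConfig(n_patients=0))
        assert len(extract.patients) == 0
        assert extract.notes == []

    def test_determinism_byte_identical(self, tmp_path):
        def digest(seed_dir: Path) -> dict[str, str]:
            out = {}
            for path in sorted(seed_dir.rglob("*")):
                if path.is_file():
                    out[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
            return out

        a, b = tmp_path / "a", tmp_path / "b"
        generate_cohort(GeneratorConfig(n_patients=60, seed=9)).write(a)
        generate_cohort(GeneratorConfig(n_patients=60, seed=9)).write(b)
        assert digest(a) == digest(b)

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig(n_patients=60, seed=1))
        b = generate_cohort(GeneratorConfig(n_patients=60, seed=2))
        assert not a.pain.equals(b.pain)

    def test_one_encounter_per_patient(self, extract_small):
        enc = extract_small.encounters
        assert enc["patient_id"].is_unique

    def test_group_medication_consistency(self, extract_small):
        from painpheno.cohort import classify_opioid, distill_ingredients

        meds = extract_small.medications
        discharge = meds[meds["order_type"] == "discharge"]
        for pid, gold in extract_small.gold["patients"].items():
            if not gold["eligible"]:
                continue
            drugs = discharge.loc[discharge["patient_id"] == pid, "drug_name"]
            classes = {
                classify_opioid(i)
                for d in drugs
                for i in distill_ingredients(d)
                if classify_opioid(i) != "not_opioid"
            }
            want = {"prodrug"} if gold["group"].endswith("Pro+") else {"non_prodrug"}
            assert classes == want, pid

    def test_ssri_orders_within_30_days(self, extract_small):
        meds = extract_small.medications
        enc = extract_small.encounters.set_index("patient_id")
        ssri_names = {"sertraline", "fluoxetine", "paroxetine", "citalopram",
                      "escitalopram", "fluvoxamine", "zoloft", "prozac", "paxil",
                      "celexa", "lexapro", "luvox"}
        for pid, gold in extract_small.gold["patients"].items():
            if not gold["eligible"]:
                continue
            rows = meds[(meds["patient_id"] == pid) & meds["drug_name"].isin(ssri_names)]
            if gold["ssri_structured"]:
                surgery = pd.Timestamp(enc.loc[pid, "surgery_date"])
                days = (pd.to_datetime(rows["date"]) - surgery).dt.days
                assert ((days >= -30) & (days <= 0)).any(), pid
            if not gold["group"].startswith("SSRI+"):
                assert rows.empty, pid

    def test_combination_products_present(self, extract_small):
        discharge = extract_small.medications.query("order_type == 'discharge'")
        combos = discharge["drug_name"].isin(
            ["vicodin", "norco", "lortab", "tylenol with codeine", "percocet"]
        )
        assert combos.mean() >= 0.10

    def test_gold_consistency_every_depressed_has_a_source(self, extract_small):
        for pid, gold in extract_small.gold["patients"].items():
            if gold["depressed"]:
                assert gold["provenance"], pid

    def test_note_depressed_have_affirmed_note_in_window(self, extract_small):
        gold = extract_small.gold
        notes_by_pid: dict[str, list] = {}
        for note in extract_small.notes:
            notes_by_pid.setdefault(note["patient_id"], []).append(note)
        enc = extract_small.encounters.set_index("patient_id")
        for pid, g in gold["patients"].items():
            if "note" not in g.get("provenance", []):
                continue
            surgery = pd.Timestamp(enc.loc[pid, "surgery_date"])
            affirmed_days = [
                (pd.Timestamp(n["date"]) - surgery).days
                for n in notes_by_pid[pid]
                if gold["note_labels"][n["note_id"]] == "Affirmed"
            ]
            assert any(-365 <= d <= 0 for d in affirmed_days), pid

    def test_noise_free_notes_are_verbatim_templates(self):
        extract = generate_cohort(GeneratorConfig(n_patients=40, seed=11, note_noise=0.0))
        for note in extract.notes:
            for sentence in note["text"].rstrip(".").split(". "):
                assert sentence in ALL_TEMPLATES, sentence

    def test_provenance_counts_reproduced_exactly(self):
        extract = generate_cohort(
            GeneratorConfig(n_patients=598, seed=3, icd_note_overlap=(1912, 2315, 1751))
        )
        counts = {"note_only": 0, "icd_only": 0, "both": 0}
        for g in extract.gold["patients"].values():
            prov = set(g["provenance"])
            if prov == {"note"}:
                counts["note_only"] += 1
            elif prov == {"icd"}:
                counts["icd_only"] += 1
            elif prov == {"icd", "note"}:
                counts["both"] += 1
        assert counts == extract.gold["provenance_counts"]
        assert sum(counts.values()) == 598


class TestPainTrajectories:
    def _patients(self, n, group="SSRI+/Pro+"):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "group": group,
                "surgery_day": 50,
                "los": 3,
            }
        )

    def test_null_effect(self):
        cfg = GeneratorConfig()
        means = {g: {t: 0.0 for t in v} for g, v in cfg.delta_means.items()}
        sds = {g: {t: 1e-9 for t in v} for g, v in cfg.delta_sds.items()}
        cfg = GeneratorConfig(
            delta_means=means, delta_sds=sds,
            followup_retention={"preop": 1.0, "discharge": 1.0, "3wk": 1.0, "8wk": 1.0},
        )
        rng = np.random.default_rng(0)
        _, truth = generate_pain_trajectories(self._patients(50), cfg, rng)
        for rec in truth.values():
            for tp in ("discharge", "3wk", "8wk"):
                assert rec["postop"][tp] == pytest.approx(rec["preop"], abs=0.02)

    def test_default_config_uses_reference_discharge_deltas(self):
        cfg = GeneratorConfig()
        assert cfg.delta_means["SSRI+/Pro+"]["discharge"] == 0.720
        assert cfg.delta_means["SSRI+/Pro-"]["discharge"] == 0.161
        assert cfg.delta_sds["SSRI+/Pro+"]["discharge"] == 3.15
        assert cfg.delta_sds["SSRI+/Pro-"]["discharge"] == 3.29

    def test_retention_binomial(self):
        n = 2000
        cfg = GeneratorConfig(
            followup_retention={"preop": 1.0, "discharge": 1.0, "3wk": 1.0, "8wk": 0.62}
        )
        rng = np.random.default_rng(4)
        _, truth = generate_pain_trajectories(self._patients(n), cfg, rng)
        observed = sum(rec["observed"]["8wk"] for rec in truth.values())
        lo, hi = stats.binom.interval(0.999, n, 0.62)
        assert lo <= observed <= hi

    def test_marginal_recovery_with_clamp_adjustment(self):
        """Empirical delta means match the clamp-adjusted expectation
        within 3 SE at n = 2000."""
        n = 2000
        cfg = GeneratorConfig(
            followup_retention={"preop": 1.0, "discharge": 1.0, "3wk": 1.0, "8wk": 1.0}
        )
        rng = np.random.default_rng(12)
        for group in GROUPS[:2]:
            _, truth = generate_pain_trajectories(self._patients(n, group), cfg, rng)
            preop = np.array([rec["preop"] for rec in truth.values()])
            for tp in ("discharge", "8wk"):
                deltas = np.array(
                    [rec["postop"][tp] - rec["preop"] for rec in truth.values()]
                )
                expected = expected_observed_delta(
                    preop, cfg.delta_means[group][tp], cfg.delta_sds[group][tp]
                )
                se = cfg.delta_sds[group][tp] / np.sqrt(n)
                assert abs(deltas.mean() - expected) < 3 * se, (group, tp)
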
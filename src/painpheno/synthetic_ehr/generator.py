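"""Synthetic EHR extract generator.

Produces structured tables (patients, encounters, diagnoses,
medications, vitals, pain observations), template-built clinical notes
and a gold-label sidecar with the true group assignments, depression
provenance and pain trajectories. Deterministic given the config seed.

Pain model: a recorded preoperative score ``p`` is drawn per patient
from the group's preop distribution and clamped to [0, 10]; the
postoperative score at time point ``t`` is ``clamp(p + mu[g][t] +
eps)`` with Gaussian noise. Clamping truncates the noise, so observed
group delta means are biased towards the interior of the scale;
:func:`expected_observed_delta` computes the clamp-adjusted expectation
recovery tests should compare against.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import GROUPS, TIME_POINTS, GeneratorConfig
from . import templates as T

BASE_DATE = dt.date(2015, 1, 15)

_DEPRESSION_CODES = (
    ("296.20", "ICD-9"),
    ("296.30", "ICD-9"),
    ("311", "ICD-9"),
    ("F32.9", "ICD-10"),
    ("F33.1", "ICD-10"),
)
_OTHER_CODES = (("I10", "ICD-10"), ("E78.5", "ICD-10"), ("401.9", "ICD-9"))
_CHARLSON_LOW = (("428.0", "ICD-9"), ("I50.9", "ICD-10"), ("J44.9", "ICD-10"))
_CHARLSON_HIGH = (("C78.0", "ICD-10"), ("196.9", "ICD-9"), ("K72.10", "ICD-10"))

_PRODRUG_SINGLE = ("hydrocodone", "codeine", "tramadol")
_PRODRUG_COMBO = ("vicodin", "norco", "lortab", "tylenol with codeine")
_NONPRODRUG_SINGLE = ("oxycodone", "morphine", "hydromorphone", "methadone")
_NONPRODRUG_COMBO = ("percocet",)
_DISCHARGE_DOSE = {
    "hydrocodone": 5.0, "codeine": 30.0, "tramadol": 50.0,
    "vicodin": 5.0, "norco": 5.0, "lortab": 5.0, "tylenol with codeine": 30.0,
    "oxycodone": 5.0, "morphine": 15.0, "hydromorphone": 2.0,
    "methadone": 5.0, "percocet": 5.0,
}
_SSRI_DRUGS = (
    "sertraline", "fluoxetine", "paroxetine", "citalopram", "escitalopram",
    "zoloft", "prozac", "lexapro",
)
_OTHER_MED_POOL = (
    "lisinopril", "metoprolol", "atorvastatin", "ibuprofen", "gabapentin",
    "omeprazole", "levothyroxine", "metformin", "amlodipine", "furosemide",
    "albuterol", "warfarin", "aspirin", "prednisone", "ondansetron",
    "lorazepam", "amitriptyline", "bupropion", "cetirizine", "amoxicillin",
)

SURGERY_TYPES = ("orthopedic", "vascular", "general")
_SURGERY_CODES = {
    "orthopedic": ("81.51", "81.54"),
    "vascular": ("38.12", "39.25"),
    "general": ("47.01", "51.23"),
}


@dataclass
class EHRExtract:
    """In-memory synthetic extract: structured tables + notes + gold."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    diagnoses: pd.DataFrame
    medications: pd.DataFrame
    vitals: pd.DataFrame
    pain: pd.DataFrame
    notes: list[dict] = field(default_factory=list)
    gold: dict = field(default_factory=dict)

    _CSV_TABLES = ("patients", "encounters", "diagnoses", "medications", "vitals", "pain")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._CSV_TABLES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        with open(out / "notes.jsonl", "w", encoding="utf-8") as fh:
            for note in self.notes:
                fh.write(json.dumps(note, sort_keys=True) + "\n")
        with open(out / "gold.json", "w", encoding="utf-8") as fh:
            json.dump(self.gold, fh, indent=1, sort_keys=True)


def read_extract(in_dir: str | Path) -> EHRExtract:
    src = Path(in_dir)
    tables = {
        name: pd.read_csv(src / f"{name}.csv", dtype={"patient_id": str})
        for name in EHRExtract._CSV_TABLES
    }
    notes = []
    notes_path = src / "notes.jsonl"
    if notes_path.exists():
        with open(notes_path, encoding="utf-8") as fh:
            notes = [json.loads(line) for line in fh if line.strip()]
    gold = {}
    gold_path = src / "gold.json"
    if gold_path.exists():
        gold = json.loads(gold_path.read_text(encoding="utf-8"))
    return EHRExtract(notes=notes, gold=gold, **tables)


def _clamp(x, lo=0.0, hi=10.0):
    return np.minimum(hi, np.maximum(lo, x))


def _iso(day_offset: int | np.integer, origin: dt.date) -> str:
    return (origin + dt.timedelta(days=int(day_offset))).isoformat()


def expected_observed_delta(
    preop: np.ndarray, delta_mean: float, delta_sd: float, lo: float = 0.0, hi: float = 10.0
) -> float:
    """Mean of E[clamp(p + mu + eps) - p] over recorded preop scores.

    This is the clamp-adjusted configured delta; recovery tests compare
    empirical delta means against it rather than against ``delta_mean``.
    """
    p = np.asarray(preop, dtype=float)
    mu = p + delta_mean
    a = (lo - mu) / delta_sd
    b = (hi - mu) / delta_sd
    expected = (
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        + delta_sd * (norm.pdf(a) - norm.pdf(b))
    )
    return float(np.mean(expected - p))


def generate_pain_trajectories(
    patients: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Draw pain trajectories and emit the pain-observation table.

    ``patients`` needs columns patient_id, group, surgery_day, los.
    Returns the observation rows plus per-patient truth (recorded preop,
    true postop scores, observation flags).
    """
    rows: list[tuple[str, str, float]] = []
    truth: dict[str, dict] = {}
    retention = config.followup_retention
    for rec in patients.itertuples(index=False):
        pid, group = rec.patient_id, rec.group
        sday, los = int(rec.surgery_day), int(rec.los)
        surgery = BASE_DATE + dt.timedelta(days=sday)
        preop = float(_clamp(rng.normal(config.preop_pain_means[group], config.preop_pain_sds[group])))
        preop = round(preop, 2)
        postop = {}
        for tp in TIME_POINTS:
            raw = preop + config.delta_means[group][tp] + rng.normal(0.0, config.delta_sds[group][tp])
            postop[tp] = round(float(_clamp(raw) if config.clamp else raw), 2)
        observed = {tp: bool(rng.random() < retention[tp]) for tp in ("preop",) + TIME_POINTS}
        if observed["preop"]:
            rows.append((pid, _iso(-int(rng.integers(1, 31)), surgery), preop))
        if observed["discharge"]:
            # inpatient course: interim days noisy, last inpatient day exact
            for day in range(los):
                interim = round(float(_clamp(postop["discharge"] + rng.normal(0.0, 0.5))), 2)
                rows.append((pid, _iso(day, surgery), interim))
            rows.append((pid, _iso(los, surgery), postop["discharge"]))
        if observed["3wk"]:
            rows.append((pid, _iso(21 + int(rng.integers(-4, 5)), surgery), postop["3wk"]))
        if observed["8wk"]:
            rows.append((pid, _iso(56 + int(rng.integers(-4, 5)), surgery), postop["8wk"]))
        if rng.random() < 0.1:  # stray observation outside every window
            rows.append((pid, _iso(35, surgery), round(float(rng.uniform(0, 10)), 2)))
        truth[pid] = {"preop": preop, "postop": postop, "observed": observed}
    pain = pd.DataFrame(rows, columns=["patient_id", "date", "score"])
    return pain, truth


def _build_note(
    sentences: list[tuple[str, str]], rng: np.random.Generator
) -> tuple[str, list[str], str]:
    """Shuffle sentences, join to note text; return (text, gold sentence
    labels, gold note label)."""
    order = rng.permutation(len(sentences))
    shuffled = [sentences[i] for i in order]
    text = ". ".join(s for s, _ in shuffled) + "."
    labels = [lab for _, lab in shuffled]
    n_aff = labels.count("Affirmed")
    n_neg = labels.count("Negated")
    if n_aff == 0 and n_neg == 0:
        note_label = "NoMention"
    elif n_aff >= n_neg:
        note_label = "Affirmed"
    else:
        note_label = "Negated"
    return text, labels, note_label


def generate_notes(
    patients: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[dict], dict, dict]:
    """Generate clinical notes with gold sentence/note labels.

    ``patients`` needs columns patient_id, surgery_day, note_depressed,
    ssri_note. Patients depressed by note get at least one note whose
    gold label is Affirmed, dated within a year before surgery.
    """
    lo, hi = config.notes_per_patient
    slo, shi = config.sentences_per_note
    notes: list[dict] = []
    note_labels: dict[str, str] = {}
    sentence_labels: dict[str, list[str]] = {}
    counter = 0
    for rec in patients.itertuples(index=False):
        pid = rec.patient_id
        surgery = BASE_DATE + dt.timedelta(days=int(rec.surgery_day))
        n_notes = int(rng.integers(lo, hi + 1))
        for k in range(max(n_notes, 1 if rec.note_depressed else n_notes)):
            counter += 1
            note_id = f"N{counter:06d}"
            n_sent = int(rng.integers(slo, shi + 1))
            sentences: list[tuple[str, str]] = []
            if k == 0 and rec.note_depressed:
                n_aff = 1 + int(rng.integers(0, 2))
                n_neg = int(rng.integers(0, n_aff + 1))  # ties still vote Affirmed
                for _ in range(n_aff):
                    t = str(rng.choice(T.AFFIRMED_TEMPLATES))
                    sentences.append((t, "Affirmed"))
                for _ in range(n_neg):
                    t = str(rng.choice(T.NEGATED_TEMPLATES))
                    sentences.append((t, "Negated"))
            elif rng.random() < 0.3:
                t = str(rng.choice(T.NEGATED_TEMPLATES))
                sentences.append((t, "Negated"))
            if k == 0 and rec.ssri_note:
                t = str(rng.choice(T.SSRI_MENTION_TEMPLATES))
                sentences.append((t, "NoMention"))
            while len(sentences) < n_sent:
                if rng.random() < config.note_noise:
                    t = str(rng.choice(T.DECOY_TEMPLATES))
                else:
                    t = str(rng.choice(T.NEUTRAL_TEMPLATES))
                sentences.append((t, "NoMention"))
            text, labels, note_label = _build_note(sentences, rng)
            day = -int(rng.integers(1, 366))
            notes.append(
                {
                    "note_id": note_id,
                    "patient_id": pid,
                    "date": _iso(day, surgery),
                    "type": str(rng.choice(T.NOTE_TYPES)),
                    "text": text,
                }
            )
            note_labels[note_id] = note_label
            sentence_labels[note_id] = labels
    return notes, note_labels, sentence_labels


def generate_cohort(config: GeneratorConfig) -> EHRExtract:
    """Generate the full synthetic extract with gold labels.

    One surgical encounter per eligible patient; medication orders are
    consistent with the assigned SSRI/prodrug group; pain observations
    follow the configured trajectories thinned by retention.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        empty = EHRExtract(
            patients=pd.DataFrame(columns=["patient_id", "birth_date", "gender", "race", "marital_status", "insurance", "bmi"]),
            encounters=pd.DataFrame(columns=["encounter_id", "patient_id", "surgery_date", "admission_date", "discharge_date", "procedure_code", "code_system", "surgery_type", "age_at_surgery", "died_in_hospital"]),
            diagnoses=pd.DataFrame(columns=["patient_id", "date", "code", "code_system"]),
            medications=pd.DataFrame(columns=["patient_id", "drug_name", "date", "dose_mg", "route", "order_type"]),
            vitals=pd.DataFrame(columns=["patient_id", "date", "systolic", "diastolic", "heart_rate", "temperature"]),
            pain=pd.DataFrame(columns=["patient_id", "date", "score"]),
            notes=[],
            gold={"patients": {}, "note_labels": {}, "sentence_labels": {}},
        )
        return empty

    group_counts = config.group_counts()
    groups = np.repeat(GROUPS, group_counts)
    rng.shuffle(groups)
    prov_counts = config.provenance_counts()
    provenance = np.repeat(["note", "icd", "both"], prov_counts)
    rng.shuffle(provenance)

    pids = [f"P{i + 1:05d}" for i in range(n)]
    gender = rng.choice(["female", "male"], size=n, p=[0.73, 0.27])
    race = rng.choice(
        ["white", "hispanic", "other", "asian", "black"],
        size=n,
        p=[0.695, 0.132, 0.083, 0.059, 0.031],
    )
    marital = rng.choice(["married", "single"], size=n, p=[0.562, 0.438])
    insurance = rng.choice(
        ["medicare", "private", "medicaid", "other"],
        size=n,
        p=[0.4777, 0.3186, 0.1166, 0.0871],
    )
    age = np.clip(np.round(rng.normal(58.34, 14.88, size=n), 1), 18.0, 95.0)
    bmi = np.clip(np.round(rng.normal(28.47, 7.39, size=n), 1), 15.0, 60.0)
    surgery_day = rng.integers(0, 300, size=n)
    los = rng.integers(1, 8, size=n)
    surgery_type = rng.choice(SURGERY_TYPES, size=n, p=[0.45, 0.2, 0.35])

    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "birth_date": [
                _iso(-int(round(a * 365.25)), BASE_DATE + dt.timedelta(days=int(d)))
                for a, d in zip(age, surgery_day)
            ],
            "gender": gender,
            "race": race,
            "marital_status": marital,
            "insurance": insurance,
            "bmi": bmi,
        }
    )

    enc_rows, dx_rows, med_rows, vit_rows = [], [], [], []
    gold_patients: dict[str, dict] = {}
    ssri_note_only = rng.random(n) < config.ssri_note_only_fraction
    tolerant = rng.random(n) < 0.574

    for i, pid in enumerate(pids):
        surgery = BASE_DATE + dt.timedelta(days=int(surgery_day[i]))
        group = str(groups[i])
        prov = str(provenance[i])
        ssri_pos = group.startswith("SSRI+")
        pro_pos = group.endswith("Pro+")
        code = _SURGERY_CODES[surgery_type[i]][int(rng.integers(0, 2))]
        enc_rows.append(
            {
                "encounter_id": f"E{i + 1:05d}",
                "patient_id": pid,
                "surgery_date": surgery.isoformat(),
                "admission_date": surgery.isoformat(),
                "discharge_date": _iso(int(los[i]), surgery),
                "procedure_code": code,
                "code_system": "ICD-9",
                "surgery_type": surgery_type[i],
                "age_at_surgery": float(age[i]),
                "died_in_hospital": False,
            }
        )
        # depression diagnosis codes for icd / both provenance
        if prov in ("icd", "both"):
            dx_code, dx_system = _DEPRESSION_CODES[int(rng.integers(0, len(_DEPRESSION_CODES)))]
            dx_rows.append(
                {
                    "patient_id": pid,
                    "date": _iso(-int(rng.integers(1, 366)), surgery),
                    "code": dx_code,
                    "code_system": dx_system,
                }
            )
        # comorbidity burden
        u = rng.random()
        if u < 0.09:
            cx, csys = _CHARLSON_HIGH[int(rng.integers(0, len(_CHARLSON_HIGH)))]
            dx_rows.append({"patient_id": pid, "date": _iso(-int(rng.integers(1, 366)), surgery), "code": cx, "code_system": csys})
        elif u < 0.35:
            cx, csys = _CHARLSON_LOW[int(rng.integers(0, len(_CHARLSON_LOW)))]
            dx_rows.append({"patient_id": pid, "date": _iso(-int(rng.integers(1, 366)), surgery), "code": cx, "code_system": csys})
        if rng.random() < 0.4:
            cx, csys = _OTHER_CODES[int(rng.integers(0, len(_OTHER_CODES)))]
            dx_rows.append({"patient_id": pid, "date": _iso(-int(rng.integers(1, 366)), surgery), "code": cx, "code_system": csys})

        # SSRI exposure: structured order within 30 days pre-surgery,
        # except for the note-mention-only subset
        ssri_by_note = bool(ssri_pos and ssri_note_only[i])
        if ssri_pos and not ssri_by_note:
            drug = str(rng.choice(_SSRI_DRUGS))
            med_rows.append(
                {
                    "patient_id": pid,
                    "drug_name": drug,
                    "date": _iso(-int(rng.integers(1, 31)), surgery),
                    "dose_mg": 50.0,
                    "route": "oral",
                    "order_type": "outpatient",
                }
            )
        # discharge opioid consistent with the prodrug arm
        combo = rng.random() < max(config.combo_order_fraction, 0.10)
        if pro_pos:
            pool = _PRODRUG_COMBO if combo else _PRODRUG_SINGLE
        else:
            pool = _NONPRODRUG_COMBO if combo else _NONPRODRUG_SINGLE
        drug = str(rng.choice(pool))
        med_rows.append(
            {
                "patient_id": pid,
                "drug_name": drug,
                "date": _iso(int(los[i]), surgery),
                "dose_mg": _DISCHARGE_DOSE[drug],
                "route": "oral",
                "order_type": "discharge",
            }
        )
        # inpatient opioid administrations (drive daily OME)
        for day in range(int(los[i]) + 1):
            dose = float(rng.choice([15.0, 30.0, 45.0]))
            med_rows.append(
                {
                    "patient_id": pid,
                    "drug_name": "morphine",
                    "date": _iso(day, surgery),
                    "dose_mg": dose,
                    "route": "oral",
                    "order_type": "inpatient_admin",
                }
            )
            if rng.random() < 0.5:
                med_rows.append(
                    {
                        "patient_id": pid,
                        "drug_name": "oxycodone",
                        "date": _iso(day, surgery),
                        "dose_mg": 10.0,
                        "route": "oral",
                        "order_type": "inpatient_admin",
                    }
                )
        # outpatient opioid history (tolerance)
        if tolerant[i]:
            drug = str(rng.choice(_PRODRUG_SINGLE + _NONPRODRUG_SINGLE))
            med_rows.append(
                {
                    "patient_id": pid,
                    "drug_name": drug,
                    "date": _iso(-int(rng.integers(1, 366)), surgery),
                    "dose_mg": 10.0,
                    "route": "oral",
                    "order_type": "outpatient",
                }
            )
        # other therapeutic classes
        for _ in range(int(rng.poisson(2.0))):
            drug = str(rng.choice(_OTHER_MED_POOL))
            med_rows.append(
                {
                    "patient_id": pid,
                    "drug_name": drug,
                    "date": _iso(-int(rng.integers(1, 31)), surgery),
                    "dose_mg": 10.0,
                    "route": "oral",
                    "order_type": "outpatient",
                }
            )
        # one preoperative vitals panel; heart rate occasionally missing
        hr = float(np.round(rng.normal(78, 12), 0)) if rng.random() > 0.05 else np.nan
        vit_rows.append(
            {
                "patient_id": pid,
                "date": _iso(-int(rng.integers(0, 31)), surgery),
                "systolic": float(np.round(rng.normal(128, 15), 0)),
                "diastolic": float(np.round(rng.normal(78, 10), 0)),
                "heart_rate": hr,
                "temperature": float(np.round(rng.normal(36.8, 0.4), 1)),
            }
        )
        gold_patients[pid] = {
            "group": group,
            "depressed": True,
            "provenance": sorted(
                {"note": ["note"], "icd": ["icd"], "both": ["icd", "note"]}[prov]
            ),
            "ssri_structured": bool(ssri_pos and not ssri_by_note),
            "ssri_note": ssri_by_note,
            "opioid_tolerant": bool(tolerant[i]),
            "eligible": True,
        }

    traj_input = pd.DataFrame(
        {"patient_id": pids, "group": groups, "surgery_day": surgery_day, "los": los}
    )
    pain, truth = generate_pain_trajectories(traj_input, config, rng)
    for pid, rec in truth.items():
        gold_patients[pid]["true_preop"] = rec["preop"]
        gold_patients[pid]["true_postop"] = rec["postop"]
        gold_patients[pid]["observed"] = rec["observed"]

    notes_input = pd.DataFrame(
        {
            "patient_id": pids,
            "surgery_day": surgery_day,
            "note_depressed": [p in ("note", "both") for p in provenance],
            "ssri_note": ssri_note_only & np.array([g.startswith("SSRI+") for g in groups]),
        }
    )
    notes, note_labels, sentence_labels = generate_notes(notes_input, config, rng)

    # optional ineligible padding to exercise eligibility filters
    for j in range(config.include_ineligible):
        pid = f"X{j + 1:05d}"
        kind = j % 2
        surgery = BASE_DATE + dt.timedelta(days=int(rng.integers(0, 300)))
        patients.loc[len(patients)] = [
            pid, _iso(-6000 if kind == 0 else -20000, surgery), "female", "white",
            "single", "private", 25.0,
        ]
        enc_rows.append(
            {
                "encounter_id": f"EX{j + 1:04d}",
                "patient_id": pid,
                "surgery_date": surgery.isoformat(),
                "admission_date": surgery.isoformat(),
                "discharge_date": _iso(2, surgery),
                "procedure_code": "47.01",
                "code_system": "ICD-9",
                "surgery_type": "general",
                "age_at_surgery": 16.4 if kind == 0 else 55.0,
                "died_in_hospital": kind == 1,
            }
        )
        gold_patients[pid] = {"group": None, "depressed": False, "provenance": [],
                              "eligible": False}

    extract = EHRExtract(
        patients=patients,
        encounters=pd.DataFrame(enc_rows),
        diagnoses=pd.DataFrame(dx_rows, columns=["patient_id", "date", "code", "code_system"]),
        medications=pd.DataFrame(
            med_rows, columns=["patient_id", "drug_name", "date", "dose_mg", "route", "order_type"]
        ),
        vitals=pd.DataFrame(vit_rows),
        pain=pain,
        notes=notes,
        gold={
            "patients": gold_patients,
            "note_labels": note_labels,
            "sentence_labels": sentence_labels,
            "group_counts": dict(zip(GROUPS, (int(c) for c in group_counts))),
            "provenance_counts": {
                "note_only": int(prov_counts[0]),
                "icd_only": int(prov_counts[1]),
                "both": int(prov_counts[2]),
            },
        },
    )
    return extract
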
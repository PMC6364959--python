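"""Batch phenotyping over a note corpus."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from painpheno.resources import load_stopwords

from .lexicon import Lexicon, default_depression_lexicon, default_ssri_lexicon
from .negex import AFFIRMED
from .note import classify_note, detect_ssri_mentions, phenotype_patient


def read_notes_jsonl(path: str | Path) -> list[dict]:
    notes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                notes.append(json.loads(line))
    return notes


def run_phenotype(
    notes: Iterable[Mapping],
    surgery_dates: Mapping[str, object],
    lexicon: Lexicon | None = None,
    ssri_lexicon: Lexicon | None = None,
    window: int | None = None,
    note_window_days: int = 365,
    note_window_mode: str = "before_only",
) -> dict[str, pd.DataFrame]:
    """Classify all notes and derive per-patient depression/SSRI flags.

    ``notes`` holds records with keys note_id/patient_id/date/text.
    Returns ``sentence_annotations``, ``note_labels`` and
    ``patient_flags`` data frames.
    """
    lexicon = lexicon or default_depression_lexicon()
    ssri_lexicon = ssri_lexicon or default_ssri_lexicon()
    stopwords = load_stopwords()

    sent_rows, note_rows = [], []
    notes_by_patient: dict[str, list[Mapping]] = {}
    for note in notes:
        pid = str(note["patient_id"])
        notes_by_patient.setdefault(pid, []).append(note)
        note_label, annotations = classify_note(
            note["text"], lexicon, stopwords, window=window, note_id=str(note["note_id"])
        )
        note_rows.append(
            {
                "note_id": str(note["note_id"]),
                "patient_id": pid,
                "date": note["date"],
                "n_affirmed": note_label.n_affirmed,
                "n_negated": note_label.n_negated,
                "label": note_label.label,
            }
        )
        for idx, ann in enumerate(annotations):
            sent_rows.append(
                {
                    "note_id": str(note["note_id"]),
                    "sentence_index": idx,
                    "sentence_text": ann.sentence_text,
                    "matched_concepts": ";".join(t for t, _ in ann.matched_concepts),
                    "label": ann.label,
                    "filtered": ann.filtered,
                }
            )

    note_df = pd.DataFrame(
        note_rows, columns=["note_id", "patient_id", "date", "n_affirmed", "n_negated", "label"]
    )
    flag_rows = []
    for pid, surgery_date in surgery_dates.items():
        pid = str(pid)
        patient_notes = notes_by_patient.get(pid, [])
        labeled = note_df[note_df["patient_id"] == pid] if patient_notes else note_df.iloc[:0]
        depressed = phenotype_patient(
            list(zip(labeled["date"], labeled["label"])),
            surgery_date,
            window_days=note_window_days,
            mode=note_window_mode,
        )
        ssri = detect_ssri_mentions(
            [(n["date"], n["text"]) for n in patient_notes],
            ssri_lexicon,
            surgery_date,
            window_days=note_window_days,
            mode=note_window_mode,
            stopwords=stopwords,
        )
        flag_rows.append(
            {"patient_id": pid, "nlp_depressed": depressed, "nlp_ssri": ssri}
        )
    return {
        "sentence_annotations": pd.DataFrame(
            sent_rows,
            columns=[
                "note_id",
                "sentence_index",
                "sentence_text",
                "matched_concepts",
                "label",
                "filtered",
            ],
        ),
        "note_labels": note_df,
        "patient_flags": pd.DataFrame(
            flag_rows, columns=["patient_id", "nlp_depressed", "nlp_ssri"]
        ),
    }


def write_phenotype_outputs(outputs: dict[str, pd.DataFrame], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs["sentence_annotations"].to_json(
        out / "sentence_annotations.jsonl", orient="records", lines=True
    )
    outputs["note_labels"].to_csv(out / "note_labels.csv", index=False)
    outputs["patient_flags"].to_csv(out / "patient_flags.csv", index=False)
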
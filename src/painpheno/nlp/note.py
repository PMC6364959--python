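"""Note-level aggregation and patient-level phenotype flags."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

from .lexicon import Lexicon
from .negex import AFFIRMED, NEGATED, NO_MENTION, SentenceAnnotation, classify_sentence
from .preprocess import preprocess


@dataclass(frozen=True)
class NoteLabel:
    note_id: str
    n_affirmed: int
    n_negated: int
    label: str


def vote_note(annotations: Sequence[SentenceAnnotation | str], note_id: str = "") -> NoteLabel:
    """Majority vote over sentence labels, ignoring NoMention sentences.

    Affirmed wins ties. A note with no voting sentences is NoMention.
    Accepts annotations or bare label strings.
    """
    labels = [a if isinstance(a, str) else a.label for a in annotations]
    n_aff = sum(1 for l in labels if l == AFFIRMED)
    n_neg = sum(1 for l in labels if l == NEGATED)
    if n_aff == 0 and n_neg == 0:
        label = NO_MENTION
    elif n_aff >= n_neg:
        label = AFFIRMED
    else:
        label = NEGATED
    return NoteLabel(note_id=note_id, n_affirmed=n_aff, n_negated=n_neg, label=label)


def classify_note(
    text: str,
    lexicon: Lexicon,
    stopwords=None,
    window: int | None = None,
    note_id: str = "",
) -> tuple[NoteLabel, list[SentenceAnnotation]]:
    """Classify every sentence of a note and aggregate to a note label."""
    kwargs = {} if window is None else {"window": window}
    annotations = [
        classify_sentence(s, lexicon, stopwords, **kwargs) for s in preprocess(text)
    ]
    return vote_note(annotations, note_id=note_id), annotations


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def _in_window(note_date, surgery_date, window_days: int, mode: str) -> bool:
    d = (_as_date(note_date) - _as_date(surgery_date)).days
    if mode == "before_only":
        return -window_days <= d <= 0
    if mode == "any":
        return -window_days <= d <= window_days
    raise ValueError(f"unknown note window mode: {mode}")


def phenotype_patient(
    note_labels: Iterable[tuple[object, str]],
    surgery_date,
    window_days: int = 365,
    mode: str = "before_only",
) -> bool:
    """True iff at least one Affirmed note falls inside the lookback window.

    ``note_labels`` is an iterable of (note_date, label) pairs.
    """
    return any(
        label == AFFIRMED and _in_window(date, surgery_date, window_days, mode)
        for date, label in note_labels
    )


def detect_ssri_mentions(
    notes: Iterable[tuple[object, str]],
    ssri_lexicon: Lexicon,
    surgery_date,
    window_days: int = 365,
    mode: str = "before_only",
    stopwords=None,
) -> bool:
    """True iff any in-window note contains a non-negated, unfiltered
    SSRI mention. Reuses the negation engine with SSRI terms as the
    concept list; ``notes`` is an iterable of (note_date, text) pairs.
    """
    for date, text in notes:
        if not _in_window(date, surgery_date, window_days, mode):
            continue
        for sentence in preprocess(text):
            ann = classify_sentence(sentence, ssri_lexicon, stopwords)
            if ann.label == AFFIRMED:
                return True
    return False
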
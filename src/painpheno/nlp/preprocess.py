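"""Note text normalization, sentence splitting and tokenization.

Two token views are produced from each sentence:

* the *raw* view keeps every token (words and punctuation) — negation
  trigger and termination matching runs on this view, because standard
  stop-word lists contain negation cues ("no", "not");
* the *concept* view drops stop words, punctuation and words of two or
  fewer letters — concept phrase matching runs on this view, with each
  surviving token remembering its raw index.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+|\n+")
_TOKEN = re.compile(r"[a-z0-9']+|[^\w\s]")
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class Sentence:
    """One sentence: normalized text plus its raw token list."""

    text: str
    tokens: tuple[str, ...] = field(default_factory=tuple)


def _normalize(raw_text: str | bytes) -> str:
    if isinstance(raw_text, bytes):
        try:
            raw_text = raw_text.decode("utf-8")
        except UnicodeDecodeError:
            log.warning("undecodable bytes in note text; replacing with U+FFFD")
            raw_text = raw_text.decode("utf-8", errors="replace")
    return _WS.sub(" ", raw_text.lower()).strip()


def preprocess(raw_text: str | bytes) -> list[Sentence]:
    """Normalize, split into sentences and tokenize.

    Returns an empty list for empty/whitespace-only input. Tokens are
    lower-case; punctuation marks are kept as single-character tokens.
    """
    if isinstance(raw_text, bytes):
        raw_text = _normalize(raw_text)
    sentences: list[Sentence] = []
    for chunk in _SENT_BOUNDARY.split(str(raw_text)):
        text = _normalize(chunk)
        if not text:
            continue
        tokens = tuple(_TOKEN.findall(text))
        if tokens:
            sentences.append(Sentence(text=text, tokens=tokens))
    return sentences


def concept_view(
    tokens: tuple[str, ...] | list[str], stopwords: frozenset[str] | set[str]
) -> list[tuple[int, str]]:
    """Filtered token view for concept matching.

    Drops stop words, punctuation and words of <= 2 letters; keeps the
    raw index of every surviving token so matches can be mapped back.
    """
    view = []
    for i, tok in enumerate(tokens):
        if tok in stopwords:
            continue
        if not any(ch.isalnum() for ch in tok):
            continue
        if len(tok) <= 2:
            continue
        view.append((i, tok))
    return view
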
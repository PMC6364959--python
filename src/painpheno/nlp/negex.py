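"""Concept matching and negation classification for single sentences.

The negation rule follows the classic trigger/scope scheme: a concept
is negated when a pre-negation trigger ends within ``window`` tokens
before it, or a post-negation trigger starts within ``window`` tokens
after it, with the scope cut at sentence boundaries and at termination
terms ("but", "however", ...). Concept matching runs on the filtered
concept view; triggers, terminations and sense-exclusion patterns are
matched on the raw token sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from painpheno.resources import load_stopwords

from .lexicon import Lexicon
from .preprocess import Sentence, concept_view, preprocess

AFFIRMED = "Affirmed"
NEGATED = "Negated"
NO_MENTION = "NoMention"

#: scope size, in raw tokens, on the scoped side of a trigger. Six is
#: required for trigger phrases separated from the concept by up to five
#: intervening words ("no preinjury mental health issues or depression").
DEFAULT_WINDOW = 6

Span = tuple[int, int]


@dataclass(frozen=True)
class SentenceAnnotation:
    """Per-sentence concept matches and assertion label."""

    sentence_text: str
    tokens: tuple[str, ...]
    matched_concepts: tuple[tuple[str, Span], ...]
    label: str
    filtered: bool = False


def _phrase_tokens(phrases: tuple[str, ...]) -> list[tuple[str, tuple[str, ...]]]:
    split = [(p, tuple(p.split())) for p in phrases]
    return sorted(split, key=lambda item: -len(item[1]))


def find_phrases(
    tokens: list[str] | tuple[str, ...], phrases: tuple[str, ...]
) -> list[tuple[str, Span]]:
    """Locate non-overlapping, longest-first phrase occurrences."""
    by_len = _phrase_tokens(phrases)
    hits: list[tuple[str, Span]] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for phrase, ptoks in by_len:
            k = len(ptoks)
            if k and tuple(tokens[i : i + k]) == ptoks:
                hits.append((phrase, (i, i + k)))
                i += k
                matched = True
                break
        if not matched:
            i += 1
    return hits


def _overlaps(a: Span, b: Span) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def match_concepts(
    sentence: Sentence,
    lexicon: Lexicon,
    stopwords: frozenset[str] | None = None,
) -> tuple[tuple[tuple[str, Span], ...], bool]:
    """Match concept phrases; flag the sentence if an exclusion pattern
    overlaps any matched concept.

    Concept spans are reported in raw-token coordinates even though the
    match runs on the filtered view.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    view = concept_view(sentence.tokens, stopwords)
    view_tokens = [tok for _, tok in view]
    concept_hits = []
    for term, (vs, ve) in find_phrases(view_tokens, lexicon.concept_terms):
        raw_span = (view[vs][0], view[ve - 1][0] + 1)
        concept_hits.append((term, raw_span))
    exclusion_hits = find_phrases(list(sentence.tokens), lexicon.exclusion_patterns)
    filtered = any(
        _overlaps(cspan, espan)
        for _, cspan in concept_hits
        for _, espan in exclusion_hits
    )
    return tuple(concept_hits), filtered


def _trigger_occurrences(
    tokens: tuple[str, ...],
    phrases: tuple[str, ...],
    concept_spans: list[Span],
) -> list[Span]:
    """Occurrences of trigger/termination phrases outside concept spans."""
    spans = []
    for _, span in find_phrases(list(tokens), phrases):
        if not any(_overlaps(span, c) for c in concept_spans):
            spans.append(span)
    return spans


def classify_sentence(
    sentence: Sentence | str,
    lexicon: Lexicon,
    stopwords: frozenset[str] | None = None,
    window: int = DEFAULT_WINDOW,
) -> SentenceAnnotation:
    """Assign Affirmed / Negated / NoMention to one sentence.

    The sentence is Negated iff every matched concept is negated,
    Affirmed if at least one concept survives un-negated, NoMention if
    no concept matches or the sentence is filtered by an exclusion
    pattern.
    """
    if isinstance(sentence, str):
        parts = preprocess(sentence)
        tokens = tuple(t for s in parts for t in s.tokens)
        sentence = Sentence(text=" ".join(s.text for s in parts), tokens=tokens)
    concepts, filtered = match_concepts(sentence, lexicon, stopwords)
    if filtered or not concepts:
        return SentenceAnnotation(
            sentence_text=sentence.text,
            tokens=sentence.tokens,
            matched_concepts=concepts,
            label=NO_MENTION,
            filtered=filtered,
        )
    concept_spans = [span for _, span in concepts]
    pre = _trigger_occurrences(sentence.tokens, lexicon.pre_negation_triggers, concept_spans)
    post = _trigger_occurrences(sentence.tokens, lexicon.post_negation_triggers, concept_spans)
    term = _trigger_occurrences(sentence.tokens, lexicon.termination_terms, concept_spans)
    term_starts = [s for s, _ in term]

    def negated(cspan: Span) -> bool:
        cs, ce = cspan
        for ts, te in pre:
            if te <= cs and cs - te < window:
                if not any(te <= x < cs for x in term_starts):
                    return True
        for ts, te in post:
            if ce <= ts and ts - ce < window:
                if not any(ce <= x < ts for x in term_starts):
                    return True
        return False

    all_negated = all(negated(span) for _, span in concepts)
    label = NEGATED if all_negated else AFFIRMED
    return SentenceAnnotation(
        sentence_text=sentence.text,
        tokens=sentence.tokens,
        matched_concepts=concepts,
        label=label,
        filtered=False,
    )
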
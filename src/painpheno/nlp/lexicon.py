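"""Lexicon model: concept terms, sense-exclusion patterns, negation triggers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

VALID_KINDS = ("concept", "exclusion", "pre_neg", "post_neg", "termination")


@dataclass(frozen=True)
class Lexicon:
    """Phrase lists driving concept matching and negation detection.

    All entries are lower-case phrases; multi-word phrases are matched
    as token subsequences. A term may not be both a concept and a
    negation trigger.
    """

    concept_terms: tuple[str, ...]
    exclusion_patterns: tuple[str, ...] = ()
    pre_negation_triggers: tuple[str, ...] = ()
    post_negation_triggers: tuple[str, ...] = ()
    termination_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for group in (
            self.concept_terms,
            self.exclusion_patterns,
            self.pre_negation_triggers,
            self.post_negation_triggers,
            self.termination_terms,
        ):
            for term in group:
                if not term or term != term.lower():
                    raise ValueError(f"lexicon entries must be non-empty lower-case: {term!r}")
        triggers = set(self.pre_negation_triggers) | set(self.post_negation_triggers)
        clash = set(self.concept_terms) & triggers
        if clash:
            raise ValueError(f"terms cannot be both concept and trigger: {sorted(clash)}")

    @property
    def phrases(self) -> dict[str, tuple[str, ...]]:
        return {
            "concept": self.concept_terms,
            "exclusion": self.exclusion_patterns,
            "pre_neg": self.pre_negation_triggers,
            "post_neg": self.post_negation_triggers,
            "termination": self.termination_terms,
        }


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a tab-delimited lexicon file with columns ``term`` and ``kind``."""
    groups: dict[str, list[str]] = {k: [] for k in VALID_KINDS}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    if header[:2] != ["term", "kind"]:
        raise ValueError(f"lexicon {path} must have columns term<TAB>kind")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            term, kind = line.split("\t")[:2]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed lexicon row") from exc
        kind = kind.strip()
        if kind not in VALID_KINDS:
            raise ValueError(f"{path}:{lineno}: unknown kind {kind!r}")
        term = term.strip().lower()
        if term not in groups[kind]:
            groups[kind].append(term)
    return Lexicon(
        concept_terms=tuple(groups["concept"]),
        exclusion_patterns=tuple(groups["exclusion"]),
        pre_negation_triggers=tuple(groups["pre_neg"]),
        post_negation_triggers=tuple(groups["post_neg"]),
        termination_terms=tuple(groups["termination"]),
    )


def default_depression_lexicon() -> Lexicon:
    from painpheno.resources import data_path

    return load_lexicon(data_path("depression_lexicon.tsv"))


def default_ssri_lexicon() -> Lexicon:
    from painpheno.resources import data_path

    return load_lexicon(data_path("ssri_lexicon.tsv"))
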
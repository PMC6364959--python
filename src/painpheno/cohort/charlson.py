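"""Weighted comorbidity scoring from diagnosis codes."""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable

from painpheno.resources import data_path


@lru_cache(maxsize=1)
def load_charlson_map(path: str | None = None) -> tuple[tuple[str, int, str, str], ...]:
    """Rows of (condition, weight, code system, code prefix)."""
    src = path or data_path("charlson_map.tsv")
    rows = []
    for line in open(src, encoding="utf-8").read().splitlines()[1:]:
        if not line.strip():
            continue
        condition, weight, system, prefix = line.split("\t")
        rows.append((condition, int(weight), system.strip(), prefix.strip()))
    return tuple(rows)


def compute_charlson_score(
    codes: Iterable[tuple[str, str]], charlson_map=None
) -> int:
    """Sum of condition weights; each condition counts once however many
    of its codes appear. ``codes`` is (code, code_system) pairs.
    """
    if charlson_map is None:
        charlson_map = load_charlson_map()
    codes = [(str(c).strip(), str(s).strip()) for c, s in codes]
    score = 0
    seen: set[str] = set()
    for condition, weight, system, prefix in charlson_map:
        if condition in seen:
            continue
        for code, code_system in codes:
            if code_system == system and code.startswith(prefix):
                score += weight
                seen.add(condition)
                break
    return score


def compute_charlson_category(codes: Iterable[tuple[str, str]], charlson_map=None) -> str:
    """Bin the weighted score into the reported categories {0-2, 3+}."""
    return "3+" if compute_charlson_score(codes, charlson_map) >= 3 else "0-2"
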
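"""Medication handling: ingredient distillation, opioid classes, OME,
opioid tolerance."""

from __future__ import annotations

import datetime as dt
import logging
from functools import lru_cache

import pandas as pd

from painpheno.resources import data_path

log = logging.getLogger(__name__)

# two fixed lists; everything else is not an opioid
PRODRUG_OPIOIDS = frozenset({"hydrocodone", "codeine", "tramadol"})
NON_PRODRUG_OPIOIDS = frozenset(
    {"morphine", "fentanyl", "hydromorphone", "oxycodone", "methadone"}
)
OPIOIDS = PRODRUG_OPIOIDS | NON_PRODRUG_OPIOIDS


def classify_opioid(ingredient_name: str) -> str:
    """Map an ingredient to {prodrug, non_prodrug, not_opioid}."""
    name = ingredient_name.strip().lower()
    if name in PRODRUG_OPIOIDS:
        return "prodrug"
    if name in NON_PRODRUG_OPIOIDS:
        return "non_prodrug"
    return "not_opioid"


@lru_cache(maxsize=1)
def load_ingredient_map(path: str | None = None) -> dict[str, tuple[tuple[str, ...], str]]:
    """drug name -> (ingredients, therapeutic class), from the static map."""
    src = path or data_path("ingredient_map.tsv")
    mapping: dict[str, tuple[tuple[str, ...], str]] = {}
    lines = open(src, encoding="utf-8").read().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        name, ingredients, klass = line.split("\t")
        mapping[name.strip().lower()] = (
            tuple(i.strip() for i in ingredients.split(";")),
            klass.strip(),
        )
    return mapping


def distill_ingredients(
    drug_name: str, mapping: dict | None = None
) -> list[str]:
    """Resolve a (possibly trade/combination) drug name to ingredients.

    Unknown names pass through unchanged with a logged warning.
    """
    if mapping is None:
        mapping = load_ingredient_map()
    name = drug_name.strip().lower()
    if name in mapping:
        return list(mapping[name][0])
    log.warning("unknown drug name %r: passing through as its own ingredient", drug_name)
    return [name]


def therapeutic_class(drug_name: str, mapping: dict | None = None) -> str | None:
    if mapping is None:
        mapping = load_ingredient_map()
    entry = mapping.get(drug_name.strip().lower())
    return entry[1] if entry else None


@lru_cache(maxsize=1)
def load_ome_table(path: str | None = None) -> dict[tuple[str, str], float]:
    """(ingredient, route) -> oral-morphine-equivalent factor."""
    src = path or data_path("ome_conversion.tsv")
    table: dict[tuple[str, str], float] = {}
    lines = open(src, encoding="utf-8").read().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        ingredient, route, factor = line.split("\t")
        table[(ingredient.strip().lower(), route.strip().lower())] = float(factor)
    return table


def compute_daily_ome(
    administrations: pd.DataFrame,
    inpatient_days: int,
    conversion_table: dict[tuple[str, str], float] | None = None,
    mapping: dict | None = None,
) -> float:
    """Average daily oral morphine equivalents over the inpatient stay.

    ``administrations`` needs columns drug_name, dose_mg, route. Each
    administration contributes dose x factor(ingredient, route); rows
    whose opioid ingredient lacks a conversion factor are skipped with a
    log message; non-opioid ingredients are ignored.
    """
    if inpatient_days < 1:
        raise ValueError("inpatient stay must be at least 1 day")
    if conversion_table is None:
        conversion_table = load_ome_table()
    total = 0.0
    for row in administrations.itertuples(index=False):
        route = str(row.route).strip().lower()
        for ingredient in distill_ingredients(str(row.drug_name), mapping):
            if classify_opioid(ingredient) == "not_opioid":
                continue
            factor = conversion_table.get((ingredient, route))
            if factor is None:
                log.warning(
                    "no OME conversion factor for (%s, %s); administration skipped",
                    ingredient,
                    route,
                )
                continue
            total += float(row.dose_mg) * factor
    return total / inpatient_days


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def flag_opioid_naive(
    outpatient_orders: pd.DataFrame,
    admission_date,
    window_days: int = 365,
    mapping: dict | None = None,
) -> bool:
    """Naive = no outpatient opioid order in the year before admission.

    ``outpatient_orders`` needs columns drug_name and date.
    """
    admission = _as_date(admission_date)
    for row in outpatient_orders.itertuples(index=False):
        day = (_as_date(row.date) - admission).days
        if not -window_days <= day <= -1:
            continue
        if any(
            classify_opioid(i) != "not_opioid"
            for i in distill_ingredients(str(row.drug_name), mapping)
        ):
            return False
    return True
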
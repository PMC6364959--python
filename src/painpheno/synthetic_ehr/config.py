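"""Generator configuration and deterministic count allocation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

GROUPS = ("SSRI+/Pro+", "SSRI+/Pro-", "SSRI-/Pro+", "SSRI-/Pro-")
TIME_POINTS = ("discharge", "3wk", "8wk")

_DEFAULT_DELTA_MEANS = {
    "SSRI+/Pro+": {"discharge": 0.720, "3wk": 2.774, "8wk": 0.861},
    "SSRI+/Pro-": {"discharge": 0.161, "3wk": 1.658, "8wk": 0.215},
    "SSRI-/Pro+": {"discharge": 0.492, "3wk": 2.138, "8wk": 0.798},
    "SSRI-/Pro-": {"discharge": 0.511, "3wk": 2.126, "8wk": 0.744},
}
_DEFAULT_DELTA_SDS = {
    "SSRI+/Pro+": {"discharge": 3.15, "3wk": 3.22, "8wk": 3.89},
    "SSRI+/Pro-": {"discharge": 3.29, "3wk": 3.38, "8wk": 3.89},
    "SSRI-/Pro+": {"discharge": 3.16, "3wk": 3.18, "8wk": 3.45},
    "SSRI-/Pro-": {"discharge": 3.20, "3wk": 3.17, "8wk": 3.44},
}
_DEFAULT_PREOP_MEANS = {
    "SSRI+/Pro+": 2.29,
    "SSRI+/Pro-": 2.93,
    "SSRI-/Pro+": 2.22,
    "SSRI-/Pro-": 2.70,
}
_DEFAULT_PREOP_SDS = {
    "SSRI+/Pro+": 2.92,
    "SSRI+/Pro-": 3.22,
    "SSRI-/Pro+": 2.88,
    "SSRI-/Pro-": 3.05,
}
_DEFAULT_RETENTION = {"preop": 0.772, "discharge": 0.973, "3wk": 0.936, "8wk": 0.623}


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def allocate_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Deterministic largest-remainder apportionment of ``n`` into groups."""
    if n < 0:
        raise ConfigurationError("n must be non-negative")
    raw = [p * n for p in proportions]
    counts = [int(x) for x in raw]
    remainders = [x - c for x, c in zip(raw, counts)]
    short = n - sum(counts)
    # ties broken by group order for reproducibility
    order = sorted(range(len(proportions)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        counts[i] += 1
    return counts


@dataclass
class GeneratorConfig:
    """Knobs controlling the synthetic EHR extract.

    Per-group pain parameters default to the stratified change-in-pain
    summary statistics of the reference cohort; the depression
    provenance triple defaults to its notes-only / codes-only / both
    split. ``icd_note_overlap`` may be given as counts (rescaled to
    ``n_patients``) or as fractions summing to one.
    """

    n_patients: int = 500
    group_proportions: tuple[float, float, float, float] = (0.1407, 0.2984, 0.1863, 0.3746)
    delta_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in _DEFAULT_DELTA_MEANS.items()}
    )
    delta_sds: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in _DEFAULT_DELTA_SDS.items()}
    )
    preop_pain_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREOP_MEANS)
    )
    preop_pain_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREOP_SDS)
    )
    followup_retention: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RETENTION)
    )
    note_noise: float = 0.2
    icd_note_overlap: tuple[float, float, float] = (1912, 2315, 1751)
    seed: int = 0
    notes_per_patient: tuple[int, int] = (1, 3)
    sentences_per_note: tuple[int, int] = (4, 10)
    combo_order_fraction: float = 0.15
    ssri_note_only_fraction: float = 0.15
    clamp: bool = True
    include_ineligible: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"group_proportions must sum to 1, got {sum(self.group_proportions)!r}"
            )
        if any(p < 0 for p in self.group_proportions):
            raise ConfigurationError("group_proportions must be non-negative")
        for g in GROUPS:
            for t in TIME_POINTS:
                if self.delta_sds[g][t] <= 0:
                    raise ConfigurationError(f"delta_sds[{g}][{t}] must be > 0")
            if self.preop_pain_sds[g] <= 0:
                raise ConfigurationError(f"preop_pain_sds[{g}] must be > 0")
            if not 0 <= self.preop_pain_means[g] <= 10:
                raise ConfigurationError("preop pain means must lie in [0, 10]")
        for t, r in self.followup_retention.items():
            if not 0 < r <= 1:
                raise ConfigurationError(f"retention[{t}] must be in (0, 1]")
        if not 0 <= self.note_noise <= 1:
            raise ConfigurationError("note_noise must be in [0, 1]")
        if len(self.icd_note_overlap) != 3 or any(x < 0 for x in self.icd_note_overlap):
            raise ConfigurationError("icd_note_overlap must be 3 non-negative numbers")

    def provenance_counts(self) -> list[int]:
        """(notes-only, icd-only, both) counts summing to n_patients."""
        total = sum(self.icd_note_overlap)
        if total == 0:
            raise ConfigurationError("icd_note_overlap must not sum to 0")
        fractions = [x / total for x in self.icd_note_overlap]
        return allocate_counts(self.n_patients, fractions)

    def group_counts(self) -> list[int]:
        return allocate_counts(self.n_patients, self.group_proportions)

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown generator config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("group_proportions", "icd_note_overlap", "notes_per_patient", "sentences_per_note"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
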
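"""Stratified group comparisons of the delta outcomes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupComparison:
    """Prodrug+ vs Prodrug- contrast within one SSRI stratum."""

    stratum: str
    time_point: str
    n: dict
    mean: dict
    sd: dict
    min: dict
    max: dict
    statistic: float
    p_value: float

    def as_row(self) -> dict:
        row = {"stratum": self.stratum, "time_point": self.time_point}
        for arm in ("Pro+", "Pro-"):
            row.update(
                {
                    f"n_{arm}": self.n[arm],
                    f"mean_{arm}": self.mean[arm],
                    f"sd_{arm}": self.sd[arm],
                    f"min_{arm}": self.min[arm],
                    f"max_{arm}": self.max[arm],
                }
            )
        row["statistic"] = self.statistic
        row["p_value"] = self.p_value
        return row


def compare_groups(
    outcomes: pd.DataFrame,
    cohort: pd.DataFrame,
    stratum: str,
    time_point: str,
    equal_var: bool = False,
) -> GroupComparison:
    """Welch (default) two-sample comparison of delta means by prodrug arm.

    ``stratum`` is "SSRI+" or "SSRI-"; patients with a missing delta at
    this time point are excluded, never imputed.
    """
    if stratum not in ("SSRI+", "SSRI-"):
        raise ValueError("stratum must be 'SSRI+' or 'SSRI-'")
    merged = outcomes.merge(
        cohort[["patient_id", "group"]].assign(
            patient_id=cohort["patient_id"].astype(str)
        ),
        on="patient_id",
    )
    col = f"delta_{time_point}"
    arms = {}
    for arm in ("Pro+", "Pro-"):
        values = merged.loc[merged["group"] == f"{stratum}/{arm}", col].dropna().astype(float)
        if len(values) < 2:
            raise ValueError(
                f"insufficient data in arm {stratum}/{arm} at {time_point}: n={len(values)}"
            )
        arms[arm] = values.to_numpy()
    stat, p = stats.ttest_ind(arms["Pro+"], arms["Pro-"], equal_var=equal_var)
    return GroupComparison(
        stratum=stratum,
        time_point=time_point,
        n={a: int(len(v)) for a, v in arms.items()},
        mean={a: float(np.mean(v)) for a, v in arms.items()},
        sd={a: float(np.std(v, ddof=1)) for a, v in arms.items()},
        min={a: float(np.min(v)) for a, v in arms.items()},
        max={a: float(np.max(v)) for a, v in arms.items()},
        statistic=float(stat),
        p_value=float(p),
    )


def table4_report(outcomes: pd.DataFrame, cohort: pd.DataFrame, equal_var: bool = False) -> pd.DataFrame:
    """Change-in-pain summary per stratum and time point (Prodrug contrast)."""
    rows = []
    for tp in ("discharge", "3wk", "8wk"):
        for stratum in ("SSRI+", "SSRI-"):
            try:
                rows.append(compare_groups(outcomes, cohort, stratum, tp, equal_var).as_row())
            except ValueError:
                continue
    return pd.DataFrame(rows)


def table3_report(outcomes: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Observed pain levels per group and assessment point, with each
    point reporting its own n (missingness varies by point)."""
    merged = outcomes.merge(
        cohort[["patient_id", "group"]].assign(patient_id=cohort["patient_id"].astype(str)),
        on="patient_id",
    )
    rows = []
    points = [("preop", "preop_pain")] + [
        (tp, f"postop_{tp}") for tp in ("discharge", "3wk", "8wk")
    ]
    for label, col in points:
        for group, sub in merged.groupby("group"):
            values = sub[col].dropna().astype(float)
            rows.append(
                {
                    "point": label,
                    "group": group,
                    "n": int(len(values)),
                    "mean": float(values.mean()) if len(values) else float("nan"),
                    "sd": float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)
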
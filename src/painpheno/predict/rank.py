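"""Coefficient ranking for feature importance reporting."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cv import CVResult


def rank_coefficients(result: CVResult, zero_tol: float = 0.0) -> pd.DataFrame:
    """Non-zero mean coefficients sorted by absolute magnitude.

    Signed values are retained; exactly-zero (or |coef| <= zero_tol)
    features are omitted. Returns columns (rank, feature, coefficient).
    """
    coef = np.asarray(result.mean_coef, dtype=float)
    names = (
        list(result.feature_names)
        if result.feature_names
        else [f"x{i}" for i in range(len(coef))]
    )
    keep = np.abs(coef) > zero_tol
    if not keep.any():
        warnings.warn("all coefficients are zero; returning an empty ranking")
        return pd.DataFrame(columns=["rank", "feature", "coefficient"])
    order = np.argsort(-np.abs(coef[keep]), kind="mergesort")
    kept_names = [n for n, k in zip(names, keep) if k]
    kept_coef = coef[keep]
    return pd.DataFrame(
        {
            "rank": np.arange(1, keep.sum() + 1),
            "feature": [kept_names[i] for i in order],
            "coefficient": kept_coef[order],
        }
    )
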
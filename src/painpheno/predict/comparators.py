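"""Off-the-shelf comparator models evaluated on the same outer folds.

Only the elastic net is bespoke; the support-vector and forest baselines
are pluggable backends. A backend that fails to import is reported as
unavailable rather than failing the run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cv import _Scaler, binarize_response, nested_cv, outer_folds
from .metrics import compute_auc

MODEL_ORDER = (
    "support_vector_classifier",
    "random_forest_classifier",
    "random_forest_regressor",
    "elastic_net",
)


def _make_backend(name: str, seed: int):
    if name == "support_vector_classifier":
        from sklearn.svm import SVC

        return SVC(kernel="rbf", random_state=seed), "decision_function", "labels"
    if name == "random_forest_classifier":
        from sklearn.ensemble import RandomForestClassifier

        return (
            RandomForestClassifier(n_estimators=200, random_state=seed),
            "predict_proba",
            "labels",
        )
    if name == "random_forest_regressor":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(n_estimators=200, random_state=seed), "predict", "delta"
    raise KeyError(name)


def run_comparators(
    X: np.ndarray,
    delta: np.ndarray,
    *,
    k_outer: int = 10,
    seed: int = 0,
    elastic_grid=((0.3, 0.05),),
    models=MODEL_ORDER,
) -> pd.DataFrame:
    """Mean (SD) fold AUC per model for one time point.

    Classifiers train on the binary label, the forest regressor and the
    elastic net on the continuous delta; all are scored as rankings of
    the binary label on identical outer folds.
    """
    X = np.asarray(X, dtype=float)
    delta = np.asarray(delta, dtype=float)
    labels = binarize_response(delta)
    folds = outer_folds(labels, k_outer, seed)
    rows = []
    for name in models:
        if name == "elastic_net":
            result = nested_cv(X, delta, grid=elastic_grid, k_outer=k_outer, seed=seed)
            rows.append(
                {"model": name, "mean_auc": result.mean_auc, "sd_auc": result.mean_auc_sd,
                 "n_folds": len(result.fold_aucs), "available": True}
            )
            continue
        try:
            estimator, score_method, target = _make_backend(name, seed)
        except Exception:  # missing backend is a reported row, not a failure
            rows.append(
                {"model": name, "mean_auc": float("nan"), "sd_auc": float("nan"),
                 "n_folds": 0, "available": False}
            )
            continue
        aucs = []
        for tr, te in folds:
            if labels[te].min() == labels[te].max():
                warnings.warn(f"{name}: outer fold has a single class; skipped")
                continue
            scaler = _Scaler().fit(X[tr])
            Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
            y_tr = labels[tr] if target == "labels" else delta[tr]
            estimator.fit(Xtr, y_tr)
            raw = getattr(estimator, score_method)(Xte)
            scores = raw[:, 1] if score_method == "predict_proba" else raw
            auc, _ = compute_auc(scores, labels[te])
            aucs.append(auc)
        rows.append(
            {
                "model": name,
                "mean_auc": float(np.mean(aucs)) if aucs else float("nan"),
                "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                "n_folds": len(aucs),
                "available": True,
            }
        )
    return pd.DataFrame(rows)


def table5_report(
    X: np.ndarray,
    deltas: dict[str, np.ndarray],
    masks: dict[str, np.ndarray] | None = None,
    *,
    k_outer: int = 10,
    seed: int = 0,
    elastic_grid=((0.3, 0.05),),
) -> pd.DataFrame:
    """Model-by-time-point AUC table (4 models x 3 time points).

    ``deltas`` maps time point -> continuous delta; ``masks`` optionally
    restricts rows (e.g. to patients observed at that point).
    """
    frames = []
    for tp, delta in deltas.items():
        mask = masks[tp] if masks else ~np.isnan(delta)
        report = run_comparators(
            np.asarray(X, dtype=float)[mask],
            np.asarray(delta, dtype=float)[mask],
            k_outer=k_outer,
            seed=seed,
            elastic_grid=elastic_grid,
        )
        report.insert(0, "time_point", tp)
        frames.append(report)
    return pd.concat(frames, ignore_index=True)
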
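"""Nested cross-validated evaluation of the penalized regression.

The model regresses the continuous pain change and is scored as a
ranking of the binary worsened/improved label: outer folds (default 10,
stratified by the binary label) estimate generalization; a 5-fold grid
search on each outer-train set picks (alpha, lam) by inner AUC.
Imputation means and standardization statistics are always computed on
the training side of whatever split is in scope — never on held-out
rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .elasticnet import ModelCoefficients, ModelHyperparams, fit_elasticnet
from .metrics import compute_auc, mean_roc

DEFAULT_GRID = tuple(
    (round(a, 1), lam)
    for a in np.arange(0.0, 1.01, 0.1)
    for lam in (0.001, 0.005, 0.01, 0.05, 0.1, 0.5)
)


def binarize_response(delta) -> np.ndarray:
    """Worsened (positive class) iff delta > 0; ties are non-worsened."""
    delta = np.asarray(delta, dtype=float)
    if np.isnan(delta).any():
        raise ValueError("delta contains missing values; drop them first")
    labels = (delta > 0).astype(int)
    if labels.min() == labels.max():
        warnings.warn("degenerate labels: all patients fall in one class")
    return labels


@dataclass
class _Scaler:
    """Train-side imputation + standardization statistics."""

    means: np.ndarray = field(default=None)
    centers: np.ndarray = field(default=None)
    scales: np.ndarray = field(default=None)

    def fit(self, X: np.ndarray) -> "_Scaler":
        X = np.asarray(X, dtype=float)
        self.means = np.nanmean(X, axis=0)
        self.means = np.where(np.isfinite(self.means), self.means, 0.0)
        filled = np.where(np.isnan(X), self.means, X)
        self.centers = filled.mean(axis=0)
        sd = filled.std(axis=0)
        self.scales = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        filled = np.where(np.isnan(X), self.means, X)
        return (filled - self.centers) / self.scales


@dataclass
class CVResult:
    time_point: str
    fold_aucs: list[float]
    mean_auc: float
    mean_auc_sd: float
    fold_rocs: list[np.ndarray]
    mean_roc_points: np.ndarray
    mean_coef: np.ndarray
    intercepts: list[float]
    chosen_hyperparams: list[tuple[float, float]]
    feature_names: tuple[str, ...] | None = None

    def as_dict(self) -> dict:
        return {
            "time_point": self.time_point,
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": float(self.mean_auc),
            "mean_auc_sd": float(self.mean_auc_sd),
            "chosen_hyperparams": [list(map(float, h)) for h in self.chosen_hyperparams],
            "mean_coef": [float(b) for b in self.mean_coef],
            "feature_names": list(self.feature_names) if self.feature_names else None,
        }


def outer_folds(labels: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified outer folds (shared with comparators)."""
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros_like(labels), labels))


def _inner_select(
    X: np.ndarray,
    delta: np.ndarray,
    labels: np.ndarray,
    grid,
    k_inner: int,
    seed: int,
) -> tuple[float, float]:
    """Grid search maximizing mean inner-fold AUC; first-in-grid ties win."""
    if len(grid) == 1:
        return grid[0]
    splitter = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    folds = list(splitter.split(X, labels))
    best, best_auc = grid[0], -np.inf
    for alpha, lam in grid:
        hp = ModelHyperparams(alpha=alpha, lam=lam)
        aucs = []
        for tr, va in folds:
            if labels[va].min() == labels[va].max() or labels[tr].min() == labels[tr].max():
                continue
            scaler = _Scaler().fit(X[tr])
            model = fit_elasticnet(scaler.transform(X[tr]), delta[tr], hp)
            auc, _ = compute_auc(model.predict(scaler.transform(X[va])), labels[va])
            aucs.append(auc)
        mean_auc = float(np.mean(aucs)) if aucs else -np.inf
        if mean_auc > best_auc:
            best, best_auc = (alpha, lam), mean_auc
    return best


def nested_cv(
    X: np.ndarray,
    delta: np.ndarray,
    *,
    grid=DEFAULT_GRID,
    k_outer: int = 10,
    k_inner: int = 5,
    seed: int = 0,
    time_point: str = "",
    feature_names: tuple[str, ...] | None = None,
    roc_grid_points: int = 101,
) -> CVResult:
    """Nested cross-validation of the elastic net as a ranking score.

    For each outer fold the inner grid search picks (alpha, lam), the
    model is refit on the full outer-train set and its continuous
    predictions score the held-out fold against the binary label.
    Deterministic given ``seed``. Folds containing a single class are
    skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if len(X) < k_outer:
        raise ValueError(f"need at least k_outer={k_outer} samples, got {len(X)}")
    labels = binarize_response(delta)
    fold_aucs, fold_rocs, coefs, intercepts, chosen = [], [], [], [], []
    for tr, te in outer_folds(labels, k_outer, seed):
        if labels[te].min() == labels[te].max():
            warnings.warn("outer fold has a single class; fold skipped")
            continue
        alpha, lam = _inner_select(X[tr], delta[tr], labels[tr], grid, k_inner, seed)
        scaler = _Scaler().fit(X[tr])
        model = fit_elasticnet(
            scaler.transform(X[tr]),
            delta[tr],
            ModelHyperparams(alpha=alpha, lam=lam),
            feature_names=feature_names,
        )
        scores = model.predict(scaler.transform(X[te]))
        auc, roc = compute_auc(scores, labels[te])
        fold_aucs.append(auc)
        fold_rocs.append(roc)
        coefs.append(model.coef / scaler.scales)  # back on the raw scale
        intercepts.append(model.intercept)
        chosen.append((alpha, lam))
    if not fold_aucs:
        raise ValueError("no usable outer folds (all single-class)")
    return CVResult(
        time_point=time_point,
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        mean_auc_sd=float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
        fold_rocs=fold_rocs,
        mean_roc_points=mean_roc(fold_rocs, roc_grid_points),
        mean_coef=np.mean(coefs, axis=0),
        intercepts=intercepts,
        chosen_hyperparams=chosen,
        feature_names=feature_names,
    )
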
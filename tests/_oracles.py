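"""Independent brute-force oracles used to cross-check the package.

These deliberately re-derive results by exhaustive enumeration or by a
different optimization algorithm; they must never call the code paths
they check.
"""

from __future__ import annotations

import numpy as np


def _all_matches(tokens: list[str], phrases) -> list[tuple[str, int, int]]:
    """Every (phrase, start, end) occurrence, overlapping included."""
    hits = []
    for phrase in phrases:
        p = phrase.split()
        for i in range(len(tokens) - len(p) + 1):
            if tokens[i : i + len(p)] == p:
                hits.append((phrase, i, i + len(p)))
    return hits


def _overlap(a: int, b: int, c: int, d: int) -> bool:
    return a < d and c < b


def oracle_classify(tokens, lexicon, stopwords, window: int = 6) -> str:
    """Label a tokenized sentence by enumerating every
    (trigger, concept, terminator) position combination."""
    tokens = list(tokens)
    view = [
        (i, t)
        for i, t in enumerate(tokens)
        if t not in stopwords and len(t) > 2 and any(ch.isalnum() for ch in t)
    ]
    vt = [t for _, t in view]
    concept_occurrences = _all_matches(vt, lexicon.concept_terms)
    chosen = []
    i = 0
    while i < len(vt):
        at_i = [h for h in concept_occurrences if h[1] == i]
        if at_i:
            best = max(at_i, key=lambda h: h[2] - h[1])
            chosen.append(best)
            i = best[2]
        else:
            i += 1
    concept_spans = [(view[s][0], view[e - 1][0] + 1) for _, s, e in chosen]

    exclusions = _all_matches(tokens, lexicon.exclusion_patterns)
    if any(
        _overlap(cs, ce, s, e) for cs, ce in concept_spans for _, s, e in exclusions
    ):
        return "NoMention"
    if not concept_spans:
        return "NoMention"

    def outside_concepts(hits):
        return [
            (s, e)
            for _, s, e in hits
            if not any(_overlap(s, e, cs, ce) for cs, ce in concept_spans)
        ]

    pre = outside_concepts(_all_matches(tokens, lexicon.pre_negation_triggers))
    post = outside_concepts(_all_matches(tokens, lexicon.post_negation_triggers))
    terminations = [
        s for s, _ in outside_concepts(_all_matches(tokens, lexicon.termination_terms))
    ]

    def negated(cs: int, ce: int) -> bool:
        for _, te in [(s, e) for s, e in pre]:
            if te <= cs and cs - te < window and not any(te <= x < cs for x in terminations):
                return True
        for ts, _ in post:
            if ce <= ts and ts - ce < window and not any(ce <= x < ts for x in terminations):
                return True
        return False

    if all(negated(cs, ce) for cs, ce in concept_spans):
        return "Negated"
    return "Affirmed"


def proximal_gradient_elasticnet(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    max_iter: int = 500_000,
    tol: float = 1e-13,
) -> tuple[float, np.ndarray]:
    """ISTA on ||y - b0 - Xb||^2 + alpha*lam*||b||_2^2 + (lam/2)(1-alpha)||b||_1.

    The intercept rides along as an unpenalized first column. Returns
    (intercept, coef).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    H = Xa.T @ Xa
    lipschitz = 2.0 * (np.linalg.eigvalsh(H)[-1] + alpha * lam)
    step = 1.0 / lipschitz
    shrink = step * lam * (1.0 - alpha) / 2.0
    w = np.zeros(p + 1)
    Xty = Xa.T @ y
    for _ in range(max_iter):
        grad = 2.0 * (H @ w - Xty)
        grad[1:] += 2.0 * alpha * lam * w[1:]
        w_new = w - step * grad
        w_new[1:] = np.sign(w_new[1:]) * np.maximum(np.abs(w_new[1:]) - shrink, 0.0)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    return float(w[0]), w[1:]


def pairwise_auc(scores, labels) -> float:
    """All-pairs Mann-Whitney AUC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
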
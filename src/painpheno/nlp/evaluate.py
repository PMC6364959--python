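"""Precision/recall/F1 evaluation of note labels against gold."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def evaluate(
    predicted: Mapping[str, str],
    gold: Mapping[str, str],
    positive_class: str = "Affirmed",
) -> EvalMetrics:
    """Confusion counts and P/R/F1 treating ``positive_class`` as positive.

    Raises on note-id mismatch; degenerate denominators yield 0 with a
    warning rather than NaN.
    """
    missing_pred = sorted(set(gold) - set(predicted))
    missing_gold = sorted(set(predicted) - set(gold))
    if missing_pred or missing_gold:
        raise ValueError(
            "note-id mismatch between predictions and gold: "
            f"missing from predictions {missing_pred[:10]}, "
            f"missing from gold {missing_gold[:10]}"
        )
    tp = fp = fn = tn = 0
    for note_id, gold_label in gold.items():
        pred_pos = predicted[note_id] == positive_class
        gold_pos = gold_label == positive_class
        if pred_pos and gold_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif gold_pos:
            fn += 1
        else:
            tn += 1
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision undefined, reporting 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive gold labels; recall undefined, reporting 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    if tp + fp + fn == 0:
        warnings.warn("F1 undefined (tp+fp+fn = 0), reporting 0")
        f1 = 0.0
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalMetrics(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision, recall=recall, f1=f1)
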
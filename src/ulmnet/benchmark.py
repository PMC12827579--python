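"""Confusion-matrix evaluation of doublet calls against ground truth.

The positive class is "doublet".  Predicted "unassigned" barcodes count as
singlet predictions (conservative).  When true compositions are supplied, a
composition-exact mode additionally requires the predicted composition
label to match the true one for a barcode to count as a true positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from ._errors import ValidationError
from .classify import BarcodeClassification

__all__ = ["BenchmarkResult", "evaluate_doublet_calls"]


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    tn: int
    fn: int
    per_composition: dict[str, "BenchmarkResult"] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def _ratio(self, num: int, den: int) -> float | None:
        return num / den if den else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def precision(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.n)

    @property
    def f1(self) -> float | None:
        s, p = self.sensitivity, self.precision
        if s is None or p is None or (s + p) == 0:
            return None
        return 2 * s * p / (s + p)

    def metrics(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
        }

    def to_json(self, path) -> None:
        payload = self.metrics()
        payload["per_composition"] = {
            k: v.metrics() for k, v in self.per_composition.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _is_pred_doublet(c: BarcodeClassification) -> bool:
    # multiplets count as doublet-positive calls; unassigned as singlet
    return c.category in ("doublet", "multiplet")


def evaluate_doublet_calls(
    pred: list[BarcodeClassification],
    truth: pd.Series,
    true_composition: pd.Series | None = None,
    composition_exact: bool = False,
) -> BenchmarkResult:
    """Doublet-detection confusion matrix with optional composition matching.

    ``truth`` maps barcode -> {"singlet", "doublet"} (any label other than
    "singlet" counts as the positive class).  With ``composition_exact`` a
    predicted doublet is a true positive only when its composition label
    equals the canonical true composition.
    """
    pred_by_bc = {c.barcode: c for c in pred}
    pred_set, truth_set = set(pred_by_bc), set(truth.index)
    if pred_set != truth_set:
        only_pred = sorted(pred_set - truth_set)[:5]
        only_truth = sorted(truth_set - pred_set)[:5]
        raise ValidationError(
            f"barcode sets differ: only in predictions {only_pred}, "
            f"only in truth {only_truth}"
        )
    if composition_exact and true_composition is None:
        raise ValidationError("composition_exact requires true_composition")

    def canonical(label: str) -> str:
        return "_".join(sorted(str(label).split("_")))

    tp = fp = tn = fn = 0
    comp_counts: dict[str, list[int]] = {}
    for bc, true_label in truth.items():
        c = pred_by_bc[bc]
        truly_doublet = str(true_label) != "singlet"
        called = _is_pred_doublet(c)
        if called and truly_doublet and composition_exact:
            called = c.composition == canonical(true_composition.loc[bc])
        if truly_doublet:
            if called:
                tp += 1
            else:
                fn += 1
        else:
            if called:
                fp += 1
            else:
                tn += 1
        if true_composition is not None and truly_doublet:
            key = canonical(true_composition.loc[bc])
            comp_counts.setdefault(key, [0, 0])  # [tp, fn] within this composition
            if called:
                comp_counts[key][0] += 1
            else:
                comp_counts[key][1] += 1

    per_comp = {
        k: BenchmarkResult(tp=v[0], fp=0, tn=0, fn=v[1])
        for k, v in sorted(comp_counts.items())
    }
    return BenchmarkResult(tp=tp, fp=fp, tn=tn, fn=fn, per_composition=per_comp)
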
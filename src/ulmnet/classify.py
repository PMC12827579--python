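"""Barcode classification from activity scores.

A signature is *active* in a barcode iff its t-value strictly exceeds
``t_min`` (default 1) and its p-value is strictly below ``p_max`` (default
0.05).  Barcodes are then partitioned by the number of active signatures:
0 -> unassigned, 1 -> singlet, 2 -> doublet, >=3 -> multiplet, with the
composition label the sorted active types joined by ``_``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .scoring import ActivityScoreMatrix

__all__ = [
    "BarcodeClassification",
    "active_signatures",
    "classify_barcodes",
    "classification_frame",
    "write_classification",
]

CATEGORIES = ("unassigned", "singlet", "doublet", "multiplet")


@dataclass(frozen=True)
class BarcodeClassification:
    barcode: str
    active_signatures: frozenset[str]
    category: str
    composition: str

    def __post_init__(self):
        n = len(self.active_signatures)
        expected = (
            "unassigned" if n == 0 else
            "singlet" if n == 1 else
            "doublet" if n == 2 else
            "multiplet"
        )
        if self.category != expected:
            raise ValidationError(
                f"category {self.category!r} inconsistent with {n} active signatures"
            )
        if self.composition != composition_label(self.active_signatures):
            raise ValidationError("composition label inconsistent with active set")


def composition_label(active) -> str:
    return "_".join(sorted(active))


def active_signatures(
    scores: ActivityScoreMatrix,
    t_min: float = 1.0,
    p_max: float = 0.05,
    bonferroni_across_signatures: bool = False,
) -> dict[str, frozenset[str]]:
    """Per-barcode set of active signatures under strict thresholds.

    ``t > t_min`` and ``p < p_max``, both strict.  Optionally the p threshold
    is Bonferroni-divided by the number of signatures (off by default).
    """
    p_cut = p_max / len(scores.signatures) if bonferroni_across_signatures else p_max
    active_mask = (scores.t_value > t_min) & (scores.p_value < p_cut)
    sig = np.asarray(scores.signatures)
    return {
        b: frozenset(sig[active_mask[i]])
        for i, b in enumerate(scores.barcodes)
    }


def classify_barcodes(active: dict[str, frozenset[str]]) -> list[BarcodeClassification]:
    """Total partition of barcodes into unassigned/singlet/doublet/multiplet."""
    out = []
    for barcode, sigs in active.items():
        n = len(sigs)
        category = (
            "unassigned" if n == 0 else
            "singlet" if n == 1 else
            "doublet" if n == 2 else
            "multiplet"
        )
        out.append(BarcodeClassification(
            barcode=barcode,
            active_signatures=frozenset(sigs),
            category=category,
            composition=composition_label(sigs),
        ))
    return out


def classification_frame(cls: list[BarcodeClassification]) -> pd.DataFrame:
    return pd.DataFrame({
        "barcode": [c.barcode for c in cls],
        "category": [c.category for c in cls],
        "composition": [c.composition for c in cls],
        "n_active": [len(c.active_signatures) for c in cls],
    })


def write_classification(cls: list[BarcodeClassification], tsv_path,
                         summary_path=None) -> None:
    """TSV of per-barcode calls plus an optional JSON category summary."""
    df = classification_frame(cls)
    df.to_csv(tsv_path, sep="\t", index=False)
    if summary_path is not None:
        counts = df["category"].value_counts().to_dict()
        summary = {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}
        summary["total"] = len(cls)
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
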
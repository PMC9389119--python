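"""Dichotomization and AND-fusion decision rules with performance metrics.

PET/CT call: positive iff SUVmax > cutoff OR TLG > cutoff.
Elastography call: positive iff mean hue > cutoff OR grading score > cutoff.
Combined call: positive iff BOTH component calls are positive (AND-fusion),
which can only raise specificity and lower sensitivity relative to either
component.  All comparisons are strict (a value exactly at the cutoff is a
negative call) and malignant is the positive class throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MALIGNANT = "malignant"
BENIGN = "benign"

__all__ = [
    "RuleCutoffs",
    "Prediction",
    "ConfusionMatrix",
    "DiagnosticReport",
    "petct_rule",
    "elasto_rule",
    "combined_rule",
    "predict",
    "predict_frame",
    "confusion",
    "diagnostic_metrics",
    "evaluate_frame",
]


@dataclass(frozen=True)
class RuleCutoffs:
    """Decision thresholds; defaults are the published model-group cutoffs."""

    suvmax_cut: float = 7.02
    tlg_cut: float = 12.53
    hue_cut: float = 132.73
    grade_cut: int = 3

    def __post_init__(self) -> None:
        for name in ("suvmax_cut", "tlg_cut", "hue_cut"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if int(self.grade_cut) != self.grade_cut or not 1 <= self.grade_cut <= 4:
            raise ValueError("grade_cut must be an integer in [1,4]")


@dataclass(frozen=True)
class Prediction:
    petct_call: bool
    elasto_call: bool

    @property
    def combined_call(self) -> bool:
        return self.petct_call and self.elasto_call


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticReport:
    """The seven performance metrics, each as a percentage."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    fpr: float
    fnr: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "fpr": self.fpr,
            "fnr": self.fnr,
        }

    def formatted(self) -> dict[str, str]:
        """Two-decimal percent strings, e.g. 47/53 -> '88.68%'."""
        return {k: f"{v:.2f}%" for k, v in self.as_dict().items()}


def _require(value: float, name: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"missing feature {name!r}")
    return float(value)


def petct_rule(suv_max: float, tlg: float, cutoffs: RuleCutoffs = RuleCutoffs()) -> bool:
    """PET/CT positive iff SUVmax or TLG strictly exceeds its cutoff."""
    return (
        _require(suv_max, "suv_max") > cutoffs.suvmax_cut
        or _require(tlg, "tlg") > cutoffs.tlg_cut
    )


def elasto_rule(mean_hue: float, grade: int, cutoffs: RuleCutoffs = RuleCutoffs()) -> bool:
    """Elastography positive iff mean hue or grading score strictly exceeds its cutoff."""
    return (
        _require(mean_hue, "mean_hue") > cutoffs.hue_cut
        or int(_require(grade, "grade")) > cutoffs.grade_cut
    )


def combined_rule(petct_call: bool, elasto_call: bool) -> bool:
    """AND-fusion: positive only when both component calls are positive."""
    return bool(petct_call) and bool(elasto_call)


def predict(
    suv_max: float, tlg: float, mean_hue: float, grade: int,
    cutoffs: RuleCutoffs = RuleCutoffs(),
) -> Prediction:
    return Prediction(
        petct_call=petct_rule(suv_max, tlg, cutoffs),
        elasto_call=elasto_rule(mean_hue, grade, cutoffs),
    )


def predict_frame(features: pd.DataFrame, cutoffs: RuleCutoffs = RuleCutoffs()) -> pd.DataFrame:
    """Vectorized calls for a features table.

    Requires columns suv_max, tlg, mean_hue, grade; returns a copy with
    petct_call, elasto_call and combined_call boolean columns appended.
    """
    for col in ("suv_max", "tlg", "mean_hue", "grade"):
        if col not in features.columns:
            raise ValueError(f"features table lacks column {col!r}")
        if features[col].isna().any():
            raise ValueError(f"missing values in feature column {col!r}")
    out = features.copy()
    out["petct_call"] = (features["suv_max"] > cutoffs.suvmax_cut) | (
        features["tlg"] > cutoffs.tlg_cut
    )
    out["elasto_call"] = (features["mean_hue"] > cutoffs.hue_cut) | (
        features["grade"] > cutoffs.grade_cut
    )
    out["combined_call"] = out["petct_call"] & out["elasto_call"]
    return out


def confusion(calls: Iterable[bool], truth: Iterable[str]) -> ConfusionMatrix:
    """2×2 tally with malignant as the positive class."""
    calls = [bool(c) for c in calls]
    truth = list(truth)
    if len(calls) != len(truth):
        raise ValueError("calls and truth must have equal length")
    bad = set(truth) - {MALIGNANT, BENIGN}
    if bad:
        raise ValueError(f"unknown truth labels: {sorted(bad)}")
    t = np.asarray([lab == MALIGNANT for lab in truth])
    c = np.asarray(calls)
    return ConfusionMatrix(
        tp=int(np.count_nonzero(c & t)),
        fp=int(np.count_nonzero(c & ~t)),
        fn=int(np.count_nonzero(~c & t)),
        tn=int(np.count_nonzero(~c & ~t)),
    )


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticReport:
    """Sensitivity/specificity/PPV/NPV/accuracy/FPR/FNR as percentages.

    PPV (NPV) is NaN when there are no positive (negative) calls.
    """
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("both truth classes must be present")
    sens = 100.0 * cm.tp / (cm.tp + cm.fn)
    spec = 100.0 * cm.tn / (cm.tn + cm.fp)
    ppv = 100.0 * cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else float("nan")
    npv = 100.0 * cm.tn / (cm.tn + cm.fn) if cm.tn + cm.fn else float("nan")
    return DiagnosticReport(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=100.0 * (cm.tp + cm.tn) / cm.total,
        fpr=100.0 - spec,
        fnr=100.0 - sens,
    )


def evaluate_frame(
    features: pd.DataFrame,
    cutoffs: RuleCutoffs = RuleCutoffs(),
    truth_col: str = "true_class",
) -> dict[str, Mapping[str, object]]:
    """Per-method confusion counts and metrics for a labelled features table."""
    preds = predict_frame(features, cutoffs)
    truth: Sequence[str] = features[truth_col].tolist()
    report: dict[str, Mapping[str, object]] = {}
    for method, col in (
        ("petct", "petct_call"),
        ("elastography", "elasto_call"),
        ("combined", "combined_call"),
    ):
        cm = confusion(preds[col].tolist(), truth)
        report[method] = {
            "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "metrics": diagnostic_metrics(cm).as_dict(),
        }
    return report
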
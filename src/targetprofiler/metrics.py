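"""Efficiency and validity metrics for two-class conformal predictors.

Given a test set with observed labels and per-class p-values, this
module computes:

* **observed fuzziness (OF)** — the mean of the wrong-class p-values,
  ``OF = (sum_{y=A} p_N + sum_{y=N} p_A) / (m_A + m_N)``; lower is a
  sharper predictor;
* **class-averaged observed fuzziness (CAOF)** — the same sums averaged
  within each class before adding,
  ``CAOF = sum_{y=A} p_N / m_A + sum_{y=N} p_A / m_N``, so a dominant
  class cannot mask the minority class (``CAOF = 2 * OF`` when classes
  are balanced);
* **M criterion (MC)** — the fraction of multi-label ("Both")
  prediction sets at a significance level; smaller is better;
* **calibration curves** — empirical accuracy (fraction of prediction
  sets containing the true label) on a confidence grid, the standard
  validity diagnostic;
* **label-set confusion tables** — counts of observed label versus
  predicted set in {{A}, {N}, Both, Null} at a confidence level.

Prediction-set membership uses the strict rule ``p > significance``
throughout, consistent with p-values living in (0, 1].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvaluatedPredictions",
    "EfficiencyReport",
    "DEFAULT_CONFIDENCE_GRID",
    "observed_fuzziness",
    "class_averaged_of",
    "m_criterion",
    "calibration_curve",
    "label_set_confusion",
    "efficiency_report",
]

DEFAULT_CONFIDENCE_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(0.05, 0.951, 0.05), 2)
)

PREDICTED_SET_NAMES = ("{A}", "{N}", "Both", "Null")


@dataclass
class EvaluatedPredictions:
    """Observed labels with their two-class p-values, column-wise."""

    y: np.ndarray  # array of "A"/"N"
    p_A: np.ndarray
    p_N: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=object)
        self.p_A = np.asarray(self.p_A, dtype=float)
        self.p_N = np.asarray(self.p_N, dtype=float)
        if not (len(self.y) == len(self.p_A) == len(self.p_N)):
            raise ValueError("y, p_A, p_N must have equal length")
        if len(self.y) == 0:
            raise ValueError("no predictions to evaluate")
        bad = set(np.unique(self.y.astype(str))) - {"A", "N"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def is_A(self) -> np.ndarray:
        return self.y.astype(str) == "A"

    def in_set(self, significance: float) -> np.ndarray:
        """Boolean: prediction set at ``significance`` contains the true label."""
        a = self.is_A
        return np.where(a, self.p_A, self.p_N) > significance


def observed_fuzziness(preds: EvaluatedPredictions) -> float:
    """Average wrong-class p-value over all test examples."""
    a = preds.is_A
    return float((preds.p_N[a].sum() + preds.p_A[~a].sum()) / len(preds))


def class_averaged_of(preds: EvaluatedPredictions) -> float:
    """Per-class averages of the wrong-class p-values, summed."""
    a = preds.is_A
    m_a, m_n = int(a.sum()), int((~a).sum())
    if m_a == 0 or m_n == 0:
        raise ValueError(
            "class-averaged observed fuzziness needs both classes present "
            f"(got {m_a} A and {m_n} N)"
        )
    return float(preds.p_N[a].sum() / m_a + preds.p_A[~a].sum() / m_n)


def m_criterion(preds: EvaluatedPredictions, significance: float) -> float:
    """Fraction of multi-label prediction sets at the given significance."""
    if not (0.0 < significance < 1.0):
        raise ValueError("significance must be in (0, 1)")
    both = (preds.p_A > significance) & (preds.p_N > significance)
    return float(both.mean())


def calibration_curve(
    preds: EvaluatedPredictions,
    grid: Sequence[float] = DEFAULT_CONFIDENCE_GRID,
) -> list[tuple[float, float]]:
    """(confidence, accuracy) pairs; accuracy = fraction of sets containing the truth."""
    return [(float(c), float(preds.in_set(1.0 - c).mean())) for c in grid]


def label_set_confusion(preds: EvaluatedPredictions, confidence: float) -> pd.DataFrame:
    """2x4 table of observed label x predicted set at the given confidence.

    Rows "A"/"N" sum to the class counts; columns are "{A}", "{N}",
    "Both" (both labels predicted) and "Null" (empty set).
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    eps = 1.0 - confidence
    in_a = preds.p_A > eps
    in_n = preds.p_N > eps
    set_name = np.select(
        [in_a & in_n, in_a & ~in_n, ~in_a & in_n],
        ["Both", "{A}", "{N}"],
        default="Null",
    )
    table = pd.DataFrame(
        0, index=["A", "N"], columns=list(PREDICTED_SET_NAMES), dtype=int
    )
    for obs in ("A", "N"):
        mask = preds.y.astype(str) == obs
        for name in PREDICTED_SET_NAMES:
            table.loc[obs, name] = int((set_name[mask] == name).sum())
    return table


@dataclass
class EfficiencyReport:
    """Summary of one evaluation run over a test set."""

    m_A: int
    m_N: int
    OF: float
    CAOF: float
    MC: dict[float, float]
    calibration: list[tuple[float, float]]
    confusion: dict[float, pd.DataFrame] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.m_A + self.m_N

    def to_row(self) -> dict:
        row = {"m_A": self.m_A, "m_N": self.m_N, "OF": self.OF, "CAOF": self.CAOF}
        for eps, mc in sorted(self.MC.items()):
            row[f"MC@conf{1 - eps:.1f}"] = mc
        return row


def efficiency_report(
    preds: EvaluatedPredictions,
    significances: Sequence[float] = (0.2, 0.1),
    confidences: Sequence[float] = (0.8, 0.9),
    grid: Sequence[float] = DEFAULT_CONFIDENCE_GRID,
) -> EfficiencyReport:
    a = preds.is_A
    return EfficiencyReport(
        m_A=int(a.sum()),
        m_N=int((~a).sum()),
        OF=observed_fuzziness(preds),
        CAOF=class_averaged_of(preds),
        MC={float(e): m_criterion(preds, e) for e in significances},
        calibration=calibration_curve(preds, grid),
        confusion={float(c): label_set_confusion(preds, c) for c in confidences},
    )


def write_calibration_csv(preds: EvaluatedPredictions, path, grid=DEFAULT_CONFIDENCE_GRID) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["confidence", "accuracy", "n"])
        for conf, acc in calibration_curve(preds, grid):
            w.writerow([f"{conf:.2f}", f"{acc:.6f}", len(preds)])


def write_confusion_csv(
    tables: dict[str, pd.DataFrame], path
) -> None:
    """Long-format per-target confusion export: target, observed, predicted set, count."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["target", "observed", "predicted_set", "count"])
        for target, table in sorted(tables.items()):
            for obs in table.index:
                for name in table.columns:
                    w.writerow([target, obs, name, int(table.loc[obs, name])])
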
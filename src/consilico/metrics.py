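"""Confusion matrices and the benchmark metric battery.

Sensitivity, specificity and accuracy are reported as percentages
(``TP/(TP+FN) x 100`` etc.); the Matthews correlation coefficient (MCC)

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

is the headline ranking statistic because it stays informative under the
heavy pathogenic/benign class imbalance of curated variant panels.  An
MCC above 0.5 is conventionally read as acceptable performance.
Zero-denominator conventions: rate metrics return NaN (rendered "NA" in
reports); MCC with any zero marginal returns 0.0 with a degeneracy flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .panel import BENIGN, DAMAGING, PATHOGENIC, TOLERATED

#: undefined-metric sentinel; use math.isnan to test, "NA" to render
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts for one (combination, stratum) evaluation.

    Positives are pathogenic variants called damaging; negatives are
    benign variants called tolerated.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_pathogenic(self) -> int:
        return self.tp + self.fn

    @property
    def n_benign(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp, fp=self.fp + other.fp,
            tn=self.tn + other.tn, fn=self.fn + other.fn,
        )


def confusion(
    calls: Sequence[str | None],
    truths: Sequence[str],
    mask: Sequence[bool] | None = None,
) -> ConfusionMatrix:
    """Tally consensus calls against truth labels over the masked variants."""
    if len(calls) != len(truths):
        raise ValueError(
            f"calls ({len(calls)}) and truths ({len(truths)}) differ in length"
        )
    if mask is None:
        mask = [c is not None for c in calls]
    elif len(mask) != len(calls):
        raise ValueError("mask length must match calls")
    tp = fp = tn = fn = 0
    for call, truth, keep in zip(calls, truths, mask):
        if not keep:
            continue
        if call == DAMAGING:
            if truth == PATHOGENIC:
                tp += 1
            elif truth == BENIGN:
                fp += 1
            else:
                raise ValueError(f"invalid truth label {truth!r}")
        elif call == TOLERATED:
            if truth == PATHOGENIC:
                fn += 1
            elif truth == BENIGN:
                tn += 1
            else:
                raise ValueError(f"invalid truth label {truth!r}")
        else:
            raise ValueError(f"invalid call {call!r} at unmasked position")
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(cm: ConfusionMatrix) -> float:
    """True-positive rate as a percentage; NaN when no pathogenic variants."""
    denom = cm.tp + cm.fn
    return UNDEFINED if denom == 0 else 100.0 * cm.tp / denom


def specificity(cm: ConfusionMatrix) -> float:
    """True-negative rate as a percentage; NaN when no benign variants."""
    denom = cm.tn + cm.fp
    return UNDEFINED if denom == 0 else 100.0 * cm.tn / denom


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall fraction correct as a percentage; NaN on an empty matrix."""
    return UNDEFINED if cm.total == 0 else 100.0 * (cm.tp + cm.tn) / cm.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1].

    Equals the Pearson correlation of the binary prediction and truth
    vectors.  When any of the four marginal sums is zero the correlation
    is undefined; by convention 0.0 is returned (see :func:`mcc_degenerate`).
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


def mcc_degenerate(cm: ConfusionMatrix) -> bool:
    """True when a zero marginal forced the 0.0 convention in :func:`mcc`."""
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    return (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn) == 0


@dataclass(frozen=True)
class MetricSet:
    """The four benchmark metrics for one evaluation."""

    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    mcc_degenerate: bool = False

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "MetricSet":
        return cls(
            accuracy=accuracy(cm),
            sensitivity=sensitivity(cm),
            specificity=specificity(cm),
            mcc=mcc(cm),
            mcc_degenerate=mcc_degenerate(cm),
        )


def format_percent(value: float, decimals: int = 1) -> str:
    """Report rendering: one-decimal percent, NaN as 'NA'."""
    return "NA" if math.isnan(value) else f"{value:.{decimals}f}"


def format_mcc(value: float, decimals: int = 2) -> str:
    return "NA" if math.isnan(value) else f"{value:.{decimals}f}"


def reconstruct_confusion(
    n_pathogenic: int,
    n_benign: int,
    sensitivity_pct: float,
    specificity_pct: float,
    decimals: int = 1,
) -> ConfusionMatrix:
    """Recover integer TP/FP/TN/FN from class sizes and rounded printed rates.

    Scans all TP in 0..n_pathogenic and TN in 0..n_benign and keeps the
    counts whose exact rates round (half-up, as benchmark tables print) to
    the given percentages.  Raises if no matrix or more than one matrix is
    consistent — the reconstruction is only meaningful when unique.
    """
    def rounds_to(numer: int, denom: int, target: float) -> bool:
        exact = 100.0 * numer / denom
        scale = 10 ** decimals
        return math.floor(exact * scale + 0.5) / scale == round(target, decimals)

    tps = [tp for tp in range(n_pathogenic + 1)
           if rounds_to(tp, n_pathogenic, sensitivity_pct)]
    tns = [tn for tn in range(n_benign + 1)
           if rounds_to(tn, n_benign, specificity_pct)]
    if len(tps) != 1 or len(tns) != 1:
        raise ValueError(
            f"reconstruction not unique: {len(tps)} TP and {len(tns)} TN "
            f"candidates for n={n_pathogenic}/{n_benign}, "
            f"rates {sensitivity_pct}/{specificity_pct}"
        )
    tp, tn = tps[0], tns[0]
    return ConfusionMatrix(tp=tp, fp=n_benign - tn, tn=tn, fn=n_pathogenic - tp)
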
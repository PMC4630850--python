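"""ROC curves, AUC and DeLong confidence intervals from continuous scores.

Threshold-free evaluation of each predictor's continuous output: the ROC
curve plots sensitivity against 1-specificity over all decision
thresholds, and its area (AUC) equals the probability that a random
pathogenic variant outranks a random benign one (ties counting one half)
— the tie-corrected Mann-Whitney statistic.  Confidence intervals use
DeLong's nonparametric placement-value variance estimator with a normal
approximation, the same construction R's pROC defaults to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .panel import BENIGN, HIGH_IS_DAMAGING, LOW_IS_DAMAGING, PATHOGENIC


@dataclass(frozen=True)
class ROCResult:
    """Operating points plus AUC for one predictor on one stratum.

    ``thresholds`` are on the *oriented* score scale (high = damaging); a
    variant is called damaging when its oriented score is >= the
    threshold, so curves are bit-reproducible.  ``operating_points`` are
    (threshold, sensitivity, 1-specificity) triples from (0, 0) to (1, 1).
    """

    operating_points: tuple[tuple[float, float, float], ...]
    auc: float
    ci_low: float
    ci_high: float
    direction: str
    n_pos: int
    n_neg: int
    se: float = float("nan")
    degenerate: bool = False

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "direction": self.direction,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "degenerate": self.degenerate,
        }


def orient_scores(
    scores: np.ndarray, polarity: str, truths: np.ndarray | None = None
) -> tuple[np.ndarray, str]:
    """Put scores on the high-means-damaging scale.

    ``polarity`` is ``high_is_damaging`` (identity), ``low_is_damaging``
    (negate) or ``auto``: pick whichever orientation gives AUC >= 0.5
    against the supplied truths, and report the choice.
    """
    scores = np.asarray(scores, dtype=float)
    if polarity == HIGH_IS_DAMAGING:
        return scores, HIGH_IS_DAMAGING
    if polarity == LOW_IS_DAMAGING:
        return -scores, LOW_IS_DAMAGING
    if polarity == "auto":
        if truths is None:
            raise ValueError("auto orientation needs truth labels")
        auc_high = _mann_whitney_auc(scores, np.asarray(truths))
        if auc_high >= 0.5:
            return scores, HIGH_IS_DAMAGING
        return -scores, LOW_IS_DAMAGING
    raise ValueError(f"unknown polarity {polarity!r}")


def _split(scores: np.ndarray, truths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = scores[truths == PATHOGENIC]
    neg = scores[truths == BENIGN]
    return pos, neg


def _mann_whitney_auc(scores: np.ndarray, truths: np.ndarray) -> float:
    """Tie-corrected rank AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    pos, neg = _split(scores, truths)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs at least one pathogenic and one benign score")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return u / (len(pos) * len(neg))


def roc_curve(scores, truths, direction: str = "auto") -> ROCResult:
    """Build the full ROC curve and AUC for one predictor.

    Missing (NaN) scores are excluded pairwise.  Thresholds run over all
    distinct oriented score values plus a +inf endpoint; the trapezoidal
    area over the resulting polygon equals the tie-corrected Mann-Whitney
    AUC.  Raises on single-class input, naming the class counts.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=object)
    keep = ~np.isnan(scores)
    scores, truths = scores[keep], truths[keep]
    n_pos = int(np.sum(truths == PATHOGENIC))
    n_neg = int(np.sum(truths == BENIGN))
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"ROC needs both classes with scores; got {n_pos} pathogenic "
            f"and {n_neg} benign"
        )

    oriented, chosen = orient_scores(scores, direction, truths)
    pos, neg = _split(oriented, truths)

    thresholds = np.concatenate([[np.inf], np.unique(oriented)[::-1]])
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # count of scores >= thr via sorted-array position
    sens_arr = (n_pos - np.searchsorted(pos_sorted, thresholds, side="left")) / n_pos
    fpr_arr = (n_neg - np.searchsorted(neg_sorted, thresholds, side="left")) / n_neg
    points = [
        (float(t), float(s), float(f))
        for t, s, f in zip(thresholds, sens_arr, fpr_arr)
    ]

    # trapezoid over (fpr, sens); identical to the rank AUC
    fprs = np.array([p[2] for p in points])
    senss = np.array([p[1] for p in points])
    auc_trap = float(np.trapezoid(senss, fprs))
    return ROCResult(
        operating_points=tuple(points),
        auc=auc_trap,
        ci_low=float("nan"),
        ci_high=float("nan"),
        direction=chosen,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong structural-components variance of the AUC estimate."""
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa, with ties at 1/2
    cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_ci(roc: ROCResult, scores, truths, level: float = 0.95) -> ROCResult:
    """Attach a DeLong normal-approximation AUC confidence interval.

    Interval is ``auc +/- z * se`` clipped to [0, 1].  Perfect separation
    gives zero variance; the result is then a zero-width interval with
    the ``degenerate`` flag set.
    """
    if roc.n_pos < 2 or roc.n_neg < 2:
        raise ValueError("DeLong interval needs at least 2 scores per class")
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=object)
    keep = ~np.isnan(scores)
    scores, truths = scores[keep], truths[keep]
    oriented, _ = orient_scores(scores, roc.direction)
    pos, neg = _split(oriented, truths)
    var = _delong_variance(pos, neg)
    se = math.sqrt(var)
    degenerate = var == 0.0
    z = norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, roc.auc - z * se)
    hi = min(1.0, roc.auc + z * se)
    return ROCResult(
        operating_points=roc.operating_points,
        auc=roc.auc,
        ci_low=lo,
        ci_high=hi,
        direction=roc.direction,
        n_pos=roc.n_pos,
        n_neg=roc.n_neg,
        se=se,
        degenerate=degenerate,
    )


def analyze_scores(scores, truths, direction: str = "auto",
                   level: float = 0.95) -> ROCResult:
    """Convenience: ROC curve plus DeLong interval in one call."""
    roc = roc_curve(scores, truths, direction=direction)
    return delong_ci(roc, scores, truths, level=level)
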
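"""Inter-tool association and group comparison statistics.

Two supporting analyses around the consensus benchmark: (i) the phi
coefficient between each pair of predictors' binary calls, to check that
committee members are not redundant copies of one another; (ii) the
Kruskal-Wallis rank test comparing accuracy across tools/combinations.
Both statistics are computed from first principles here (closed forms)
and validated against scipy in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata, spearmanr

from .panel import DAMAGING, MISSING, PredictionPanel


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    groups: tuple[tuple[str, int], ...]  # (label, size) pairs


def phi_association(calls_a: Sequence[str], calls_b: Sequence[str]) -> float:
    """Phi coefficient of two binary call vectors.

    Pairs where either call is missing are excluded.  Equals the Pearson
    correlation of the 0/1 encodings, computed from the 2x2 table as
    (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).  A constant vector makes the
    correlation undefined: returns NaN.
    """
    if len(calls_a) != len(calls_b):
        raise ValueError("call vectors must be the same length")
    a = b = c = d = 0  # a: both damaging, b: A only, c: B only, d: neither
    for x, y in zip(calls_a, calls_b):
        if x == MISSING or y == MISSING or x is None or y is None:
            continue
        if x == DAMAGING:
            if y == DAMAGING:
                a += 1
            else:
                b += 1
        else:
            if y == DAMAGING:
                c += 1
            else:
                d += 1
    denom_sq = (a + b) * (c + d) * (a + c) * (b + d)
    if denom_sq == 0:
        return float("nan")
    return (a * d - b * c) / math.sqrt(denom_sq)


def association_matrix(panel: PredictionPanel, method: str = "phi") -> pd.DataFrame:
    """Symmetric tools x tools association grid.

    ``method='phi'`` correlates harmonized binary calls (the default: the
    question is whether the *calls* being combined are redundant);
    ``'spearman'`` rank-correlates the raw scores instead.
    """
    tools = panel.tools
    out = pd.DataFrame(np.eye(len(tools)), index=tools, columns=tools)
    if method == "phi":
        columns = {t: [c.call for c in panel.column(t)] for t in tools}
    elif method == "spearman":
        scores = panel.scores_frame()
    else:
        raise ValueError(f"unknown association method {method!r}")
    for i, ta in enumerate(tools):
        for tb in tools[i + 1:]:
            if method == "phi":
                val = phi_association(columns[ta], columns[tb])
            else:
                sa, sb = scores[ta], scores[tb]
                keep = sa.notna() & sb.notna()
                if keep.sum() < 2:
                    val = float("nan")
                else:
                    val = float(spearmanr(sa[keep], sb[keep]).statistic)
            out.loc[ta, tb] = out.loc[tb, ta] = val
    return out


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> StatTestResult:
    """Kruskal-Wallis H test across two or more groups.

    Mid-rank tie correction applied:
        H = [12 / (N(N+1)) * sum_i R_i^2 / n_i - 3(N+1)] / (1 - sum(t^3 - t)/(N^3 - N))
    p-value from the chi-squared approximation with k-1 degrees of freedom.
    If every pooled observation is identical, H = 0 and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("all groups must be non-empty")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = len(pooled)
    ranks = rankdata(pooled)
    df = len(groups) - 1
    group_info = tuple(zip(labels, sizes))

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction == 0.0:  # every observation identical
        return StatTestResult(0.0, df, 1.0, group_info)

    h = 0.0
    start = 0
    for n_i in sizes:
        r_i = ranks[start:start + n_i].sum()
        h += r_i * r_i / n_i
        start += n_i
    h = (12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)) / correction
    h = max(h, 0.0)  # guard tiny negative round-off
    p = float(chi2.sf(h, df))
    return StatTestResult(h, df, p, group_info)


def accuracy_comparison(
    correctness_by_group: dict[str, Sequence[int]],
) -> StatTestResult:
    """Compare accuracy across tools/combinations by Kruskal-Wallis.

    Observations are per-variant correctness indicators (1 = correct,
    0 = incorrect) grouped by tool or combination — the finest sampling
    unit that gives the test real sample sizes.  For a per-gene-accuracy
    alternative, pass each group's per-gene accuracy values directly to
    :func:`kruskal_wallis`.
    """
    labels = list(correctness_by_group)
    return kruskal_wallis([correctness_by_group[k] for k in labels], labels)
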
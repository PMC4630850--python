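"""Full-evaluation orchestration: strata, rankings and report files.

Runs every tool combination over every stratum (per gene, pooled across
genes, and optionally per collapsed protein region), tallies a confusion
matrix and the metric battery for each, and ranks combinations by MCC —
the statistic used to pick a best committee per gene.  Metaservers are
evaluated as single columns only; they are themselves consensus products
and are never mixed into tool committees.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .consensus import ToolCombination, apply_combination, enumerate_combinations
from .metrics import (
    ConfusionMatrix,
    MetricSet,
    confusion,
    format_mcc,
    format_percent,
)
from .panel import (
    BENIGN,
    PATHOGENIC,
    REGION_COLLAPSE,
    PredictionPanel,
    collapse_region,
)
from .roc import analyze_scores
from .stats import association_matrix


@dataclass(frozen=True)
class Stratum:
    """An evaluation slice: one gene or the pooled set, optionally one
    collapsed region group (e.g. SCN5A membrane-associated vs loop)."""

    gene: str | None = None          # None = pooled across genes
    region_group: str | None = None  # None = all regions

    @property
    def label(self) -> str:
        gene = self.gene or "all"
        return gene if self.region_group is None else f"{gene}:{self.region_group}"

    def mask(self, panel: PredictionPanel) -> np.ndarray:
        keep = np.ones(panel.n_variants, dtype=bool)
        if self.gene is not None:
            keep &= np.array([v.gene == self.gene for v in panel.variants])
        if self.region_group is not None:
            keep &= np.array(
                [collapse_region(v.region) == self.region_group
                 for v in panel.variants]
            )
        return keep


@dataclass(frozen=True)
class ComboEvaluation:
    combination: ToolCombination
    stratum: Stratum
    confusion: ConfusionMatrix
    metrics: MetricSet
    n_evaluated: int


def default_strata(
    panel: PredictionPanel, kinds: Sequence[str] = ("gene", "pooled")
) -> list[Stratum]:
    """Build the stratification: per-gene, pooled, and/or per-region slices.

    ``kinds`` is a subset of {"gene", "pooled", "region"}.  Region strata
    are emitted per gene for every collapsed region group (other than
    ``unassigned``) that gene's variants actually carry.
    """
    unknown = set(kinds) - {"gene", "pooled", "region"}
    if unknown:
        raise ValueError(f"unknown strata kinds: {sorted(unknown)}")
    genes = list(dict.fromkeys(v.gene for v in panel.variants))
    out: list[Stratum] = []
    if "gene" in kinds:
        out.extend(Stratum(gene=g) for g in genes)
    if "pooled" in kinds:
        out.append(Stratum())
    if "region" in kinds:
        for g in genes:
            groups = sorted(
                {collapse_region(v.region) for v in panel.variants
                 if v.gene == g} - {"unassigned"}
            )
            out.extend(Stratum(gene=g, region_group=grp) for grp in groups)
    return out


def standard_combinations(
    panel: PredictionPanel, sizes: Iterable[int] = (1, 2, 3, 4, 5)
) -> list[ToolCombination]:
    """Committees over the non-metaserver tools plus metaserver singletons."""
    committee = panel.committee_tools()
    usable = [s for s in set(sizes) if 1 <= s <= len(committee)]
    combos = enumerate_combinations(committee, usable)
    combos.extend(ToolCombination((m,)) for m in sorted(panel.metaservers))
    return combos


def evaluate_all(
    panel: PredictionPanel,
    combos: Sequence[ToolCombination] | None = None,
    strata: Sequence[Stratum] | None = None,
    missing_policy: str = "exclude",
) -> list[ComboEvaluation]:
    """One ComboEvaluation per (combination, stratum), deterministic order.

    A stratum with no pathogenic or no benign evaluable variants yields
    NaN rate sentinels (and a flagged MCC of 0) with a warning; the run
    continues.
    """
    if combos is None:
        combos = standard_combinations(panel)
    if strata is None:
        strata = default_strata(panel)
    truths = panel.truths()
    out: list[ComboEvaluation] = []
    warned: set[str] = set()
    for combo in combos:
        calls, call_mask = apply_combination(panel, combo, missing_policy)
        for stratum in strata:
            keep = stratum.mask(panel) & call_mask
            cm = confusion(calls, truths, keep)
            if (cm.n_pathogenic == 0 or cm.n_benign == 0) and stratum.label not in warned:
                warned.add(stratum.label)
                warnings.warn(
                    f"stratum {stratum.label!r} lacks a truth class "
                    f"({cm.n_pathogenic} pathogenic / {cm.n_benign} benign "
                    f"evaluable); rate metrics undefined",
                    stacklevel=2,
                )
            out.append(
                ComboEvaluation(
                    combination=combo,
                    stratum=stratum,
                    confusion=cm,
                    metrics=MetricSet.from_confusion(cm),
                    n_evaluated=cm.total,
                )
            )
    return out


def rank_by_mcc(
    evals: Sequence[ComboEvaluation], stratum: Stratum
) -> list[ComboEvaluation]:
    """Order one stratum's evaluations by MCC, best first.

    Ties break towards fewer tools (cheaper committee), then higher
    specificity, then lexicographic label.  Degenerate/undefined MCCs
    sort after all defined ones, keeping their input order.
    """
    rows = [e for e in evals if e.stratum == stratum]

    def key(item: tuple[int, ComboEvaluation]):
        i, e = item
        undefined = e.metrics.mcc_degenerate
        spec = e.metrics.specificity
        spec_key = -spec if not np.isnan(spec) else np.inf
        if undefined:
            return (1, 0.0, 0, 0.0, "", i)
        return (0, -e.metrics.mcc, e.combination.size, spec_key,
                e.combination.label, i)

    return [e for _, e in sorted(enumerate(rows), key=key)]


def evaluations_frame(evals: Sequence[ComboEvaluation]) -> pd.DataFrame:
    """Machine-readable table of all evaluations, full float precision."""
    rows = []
    for e in evals:
        rows.append(
            {
                "stratum": e.stratum.label,
                "combination": e.combination.label,
                "n_tools": e.combination.size,
                "n_evaluated": e.n_evaluated,
                "tp": e.confusion.tp,
                "fp": e.confusion.fp,
                "tn": e.confusion.tn,
                "fn": e.confusion.fn,
                "accuracy": e.metrics.accuracy,
                "sensitivity": e.metrics.sensitivity,
                "specificity": e.metrics.specificity,
                "mcc": e.metrics.mcc,
                "mcc_degenerate": e.metrics.mcc_degenerate,
            }
        )
    return pd.DataFrame(rows)


def human_table(evals: Sequence[ComboEvaluation]) -> pd.DataFrame:
    """Rounded presentation table: one-decimal percents, two-decimal MCC."""
    frame = evaluations_frame(evals)
    for col in ("accuracy", "sensitivity", "specificity"):
        frame[col] = frame[col].map(format_percent)
    frame["mcc"] = frame["mcc"].map(format_mcc)
    return frame.drop(columns=["mcc_degenerate"])


def roc_summary(
    panel: PredictionPanel, strata: Sequence[Stratum] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-tool AUC and DeLong CI on every stratum (single tools and
    metaservers only — committees vote on calls, not scores)."""
    if strata is None:
        strata = default_strata(panel)
    scores = panel.scores_frame()
    truths = np.array(panel.truths(), dtype=object)
    rows = []
    for stratum in strata:
        keep = stratum.mask(panel)
        for tool in panel.tools:
            s = scores[tool].to_numpy()[keep]
            t = truths[keep]
            try:
                res = analyze_scores(s, t, direction=panel.polarity(tool),
                                     level=level)
                rows.append(
                    {
                        "stratum": stratum.label,
                        "tool": tool,
                        "auc": res.auc,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "direction": res.direction,
                        "n_pos": res.n_pos,
                        "n_neg": res.n_neg,
                        "degenerate": res.degenerate,
                    }
                )
            except ValueError as exc:
                warnings.warn(
                    f"ROC skipped for {tool} on {stratum.label}: {exc}",
                    stacklevel=2,
                )
                rows.append(
                    {
                        "stratum": stratum.label, "tool": tool,
                        "auc": float("nan"), "ci_low": float("nan"),
                        "ci_high": float("nan"), "direction": "NA",
                        "n_pos": int(np.sum(t == PATHOGENIC)),
                        "n_neg": int(np.sum(t == BENIGN)),
                        "degenerate": True,
                    }
                )
    return pd.DataFrame(rows)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n",
                 float_format=lambda x: repr(float(x)))


def run_report(
    panel: PredictionPanel,
    out_dir: str | Path,
    sizes: Iterable[int] = (1, 2, 3, 4, 5),
    strata_kinds: Sequence[str] = ("gene", "pooled"),
    missing_policy: str = "exclude",
    manifest_extra: dict | None = None,
) -> dict[str, Path]:
    """Run the full evaluation and write the report files.

    Writes ``evaluations.tsv`` (all combination metrics, full precision),
    ``roc_summary.tsv`` (per-tool AUC + CI per stratum),
    ``association.tsv`` (pairwise phi grid) and ``manifest.json``.
    Re-running on the same panel yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    strata = default_strata(panel, strata_kinds)
    combos = standard_combinations(panel, sizes)

    collected: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        evals = evaluate_all(panel, combos, strata, missing_policy)
        rocs = roc_summary(panel, strata)
        assoc = association_matrix(panel)
        collected = [str(w.message) for w in caught]

    paths = {
        "evaluations": out / "evaluations.tsv",
        "roc_summary": out / "roc_summary.tsv",
        "association": out / "association.tsv",
        "manifest": out / "manifest.json",
    }
    _write_tsv(evaluations_frame(evals), paths["evaluations"])
    _write_tsv(rocs, paths["roc_summary"])
    assoc.to_csv(paths["association"], sep="\t", na_rep="NA", lineterminator="\n",
                 index_label="tool", float_format=lambda x: repr(float(x)))

    manifest = {
        "package": "consilico",
        "version": __version__,
        "n_variants": panel.n_variants,
        "tools": list(panel.tools),
        "metaservers": list(panel.metaservers),
        "sizes": sorted(set(sizes)),
        "strata": [s.label for s in strata],
        "missing_policy": missing_policy,
        "region_collapse": REGION_COLLAPSE,
        "warnings": collected,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
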
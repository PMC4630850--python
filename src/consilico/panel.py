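"""Prediction-panel data model, TSV I/O, label harmonization and inclusion filtering.

A *prediction panel* is the variants x tools grid at the heart of the
analysis: each row is one missense variant with a curated truth label
(pathogenic / benign), each column one in silico predictor, and each cell
the predictor's categorical call in its native vocabulary plus an optional
continuous score.  Tools speak different dialects ("Deleterious",
"Non-neutral", "Probably damaging", ...); harmonization collapses every
dialect onto the binary {damaging, tolerated} scale before any voting or
scoring happens.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

DAMAGING = "damaging"
TOLERATED = "tolerated"
MISSING = "missing"

PATHOGENIC = "pathogenic"
BENIGN = "benign"

#: evidence classes admissible for the truth label
EVIDENCE_CLASSES = ("functional", "cosegregation", "allele_frequency")

#: protein-region vocabulary; ``collapse_region`` maps these onto the
#: two-group stratification used for the SCN5A sub-analysis
REGIONS = ("n_term", "transmembrane", "c_term", "loop", "unassigned")

HIGH_IS_DAMAGING = "high_is_damaging"
LOW_IS_DAMAGING = "low_is_damaging"

#: benign-by-frequency variants require a population allele frequency
#: strictly above this fraction (the "greater than 1%" rule)
ALLELE_FREQUENCY_THRESHOLD = 0.01

#: native output vocabularies of the five tools and two metaservers,
#: with the Probably/Possibly-damaging collapse for PolyPhen-2
DEFAULT_VOCABULARIES: dict[str, dict[str, str]] = {
    "PolyPhen-2": {
        "probably damaging": DAMAGING,
        "possibly damaging": DAMAGING,
        "benign": TOLERATED,
    },
    "SIFT": {"damaging": DAMAGING, "tolerated": TOLERATED},
    "PROVEAN": {"deleterious": DAMAGING, "neutral": TOLERATED},
    "SNPs&GO": {"disease": DAMAGING, "neutral": TOLERATED},
    "SNAP": {"non-neutral": DAMAGING, "neutral": TOLERATED},
    "Meta-SNP": {"disease": DAMAGING, "neutral": TOLERATED},
    "PredictSNP": {"deleterious": DAMAGING, "neutral": TOLERATED},
}

#: score orientation per tool: SIFT and PROVEAN emit low-means-damaging
#: scores, the others high-means-damaging
DEFAULT_POLARITIES: dict[str, str] = {
    "PolyPhen-2": HIGH_IS_DAMAGING,
    "SIFT": LOW_IS_DAMAGING,
    "PROVEAN": LOW_IS_DAMAGING,
    "SNPs&GO": HIGH_IS_DAMAGING,
    "SNAP": HIGH_IS_DAMAGING,
    "Meta-SNP": HIGH_IS_DAMAGING,
    "PredictSNP": HIGH_IS_DAMAGING,
}

#: the two consensus metaservers, never mixed into tool committees
DEFAULT_METASERVERS = ("Meta-SNP", "PredictSNP")


class HarmonizationError(ValueError):
    """Raised when a raw label is not in the declared vocabulary of a tool."""


class PanelFormatError(ValueError):
    """Raised on malformed panel files; carries the offending line number."""


@dataclass(frozen=True)
class VariantRecord:
    """One curated missense variant.

    ``variant_id`` is an HGVS protein-change style identifier (e.g.
    ``p.Arg190Gln``); ``truth`` is the curated label backed by ``evidence``
    (in vitro functional work, family co-segregation, or population allele
    frequency for benign variants).
    """

    variant_id: str
    gene: str
    truth: str
    evidence: str = "functional"
    allele_frequency: float | None = None
    region: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError(f"variant {self.variant_id!r}: gene must be non-empty")
        if self.truth not in (PATHOGENIC, BENIGN):
            raise ValueError(
                f"variant {self.variant_id!r}: truth must be "
                f"'{PATHOGENIC}' or '{BENIGN}', got {self.truth!r}"
            )
        if self.evidence not in EVIDENCE_CLASSES:
            raise ValueError(
                f"variant {self.variant_id!r}: unknown evidence class {self.evidence!r}"
            )
        if self.region not in REGIONS:
            raise ValueError(
                f"variant {self.variant_id!r}: unknown region {self.region!r}"
            )
        if self.allele_frequency is not None and not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(
                f"variant {self.variant_id!r}: allele frequency must be in [0, 1]"
            )


@dataclass(frozen=True)
class ToolCall:
    """A single tool's output for a single variant."""

    tool: str
    raw_label: str | None
    call: str
    score: float | None = None
    polarity: str = HIGH_IS_DAMAGING

    def __post_init__(self) -> None:
        if (self.call == MISSING) != (self.raw_label is None):
            raise ValueError(
                f"tool {self.tool!r}: call is '{MISSING}' iff raw_label is absent"
            )
        if self.call not in (DAMAGING, TOLERATED, MISSING):
            raise ValueError(f"tool {self.tool!r}: invalid call {self.call!r}")
        if self.polarity not in (HIGH_IS_DAMAGING, LOW_IS_DAMAGING):
            raise ValueError(f"tool {self.tool!r}: invalid polarity {self.polarity!r}")


@dataclass(frozen=True)
class ToolSchema:
    """Column mapping, vocabulary and score polarity for one tool."""

    name: str
    vocabulary: Mapping[str, str]
    polarity: str = HIGH_IS_DAMAGING
    call_column: str | None = None   # defaults to "<name>_call"
    score_column: str | None = None  # defaults to "<name>_score"; None-able via schema

    def resolved_call_column(self) -> str:
        return self.call_column or f"{self.name}_call"

    def resolved_score_column(self) -> str | None:
        return self.score_column if self.score_column is not None else f"{self.name}_score"


@dataclass(frozen=True)
class PanelSchema:
    """Names the fixed columns and per-tool columns of a panel TSV."""

    tools: tuple[ToolSchema, ...]
    variant_id_column: str = "variant_id"
    gene_column: str = "gene"
    truth_column: str = "truth"
    evidence_column: str = "evidence"
    allele_frequency_column: str = "allele_frequency"
    region_column: str = "region"
    missing_token: str = "."

    def tool_names(self) -> list[str]:
        return [t.name for t in self.tools]


def default_schema(tools: Sequence[str] | None = None) -> PanelSchema:
    """Schema for the seven shipped predictors (or a subset of them)."""
    names = list(tools) if tools is not None else list(DEFAULT_VOCABULARIES)
    unknown = [n for n in names if n not in DEFAULT_VOCABULARIES]
    if unknown:
        raise KeyError(f"no default vocabulary for tool(s): {unknown}")
    return PanelSchema(
        tools=tuple(
            ToolSchema(
                name=n,
                vocabulary=DEFAULT_VOCABULARIES[n],
                polarity=DEFAULT_POLARITIES[n],
            )
            for n in names
        )
    )


def load_schema(path: str | Path) -> PanelSchema:
    """Read a panel schema from a YAML config file.

    Layout::

        variant_id: variant_id
        truth: truth
        missing_token: "."
        tools:
          SIFT:
            polarity: low_is_damaging
            vocabulary: {Damaging: damaging, Tolerated: tolerated}
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    tool_schemas = []
    for name, cfg in raw["tools"].items():
        cfg = cfg or {}
        vocab = cfg.get("vocabulary") or DEFAULT_VOCABULARIES.get(name)
        if vocab is None:
            raise KeyError(f"tool {name!r}: no vocabulary given and no default known")
        tool_schemas.append(
            ToolSchema(
                name=name,
                vocabulary={str(k): str(v) for k, v in vocab.items()},
                polarity=cfg.get(
                    "polarity", DEFAULT_POLARITIES.get(name, HIGH_IS_DAMAGING)
                ),
                call_column=cfg.get("call_column"),
                score_column=cfg.get("score_column"),
            )
        )
    kwargs = {}
    for key, attr in [
        ("variant_id", "variant_id_column"),
        ("gene", "gene_column"),
        ("truth", "truth_column"),
        ("evidence", "evidence_column"),
        ("allele_frequency", "allele_frequency_column"),
        ("region", "region_column"),
        ("missing_token", "missing_token"),
    ]:
        if key in raw:
            kwargs[attr] = raw[key]
    return PanelSchema(tools=tuple(tool_schemas), **kwargs)


def harmonize_label(tool: str, raw_label: str, vocabulary: Mapping[str, str]) -> str:
    """Map a tool's native label onto {damaging, tolerated}.

    Matching is case- and surrounding-whitespace-insensitive.  An unknown
    label raises :class:`HarmonizationError` naming the tool and label —
    never a silent coercion.
    """
    key = raw_label.strip().casefold()
    table = {k.strip().casefold(): v for k, v in vocabulary.items()}
    try:
        call = table[key]
    except KeyError:
        known = sorted(table)
        raise HarmonizationError(
            f"tool {tool!r}: unknown output label {raw_label!r} "
            f"(declared vocabulary: {known})"
        ) from None
    if call not in (DAMAGING, TOLERATED):
        raise HarmonizationError(
            f"tool {tool!r}: vocabulary maps {raw_label!r} to invalid call {call!r}"
        )
    return call


def apply_inclusion_filter(
    records: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Partition variants into (kept, rejected-with-reason).

    Pathogenic variants need functional or co-segregation evidence; benign
    variants need functional evidence or a population allele frequency
    strictly above 1%.  Returns a disjoint partition of the input.
    """
    kept: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, str]] = []
    for rec in records:
        if rec.truth == PATHOGENIC:
            if rec.evidence in ("functional", "cosegregation"):
                kept.append(rec)
            else:
                rejected.append(
                    (rec, "pathogenic_requires_functional_or_cosegregation_evidence")
                )
        else:  # benign
            if rec.evidence == "functional":
                kept.append(rec)
            elif rec.evidence == "allele_frequency":
                if rec.allele_frequency is None:
                    rejected.append((rec, "benign_by_frequency_missing_allele_frequency"))
                elif rec.allele_frequency > ALLELE_FREQUENCY_THRESHOLD:
                    kept.append(rec)
                else:
                    rejected.append((rec, "allele_frequency_not_above_threshold"))
            else:
                rejected.append((rec, "benign_requires_functional_or_frequency_evidence"))
    return kept, rejected


@dataclass
class PredictionPanel:
    """Rectangular variants x tools grid of harmonized calls and scores."""

    variants: list[VariantRecord]
    tools: list[str]
    calls: list[list[ToolCall]] = field(repr=False)
    metaservers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.tools)) != len(self.tools):
            raise ValueError("tool names must be unique")
        ids = [v.variant_id for v in self.variants]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate variant IDs in panel: {sorted(dupes)}")
        if len(self.calls) != len(self.variants):
            raise ValueError("calls grid must have one row per variant")
        for i, row in enumerate(self.calls):
            if len(row) != len(self.tools):
                raise ValueError(
                    f"calls row {i} has {len(row)} cells, expected {len(self.tools)}"
                )
        bad_meta = set(self.metaservers) - set(self.tools)
        if bad_meta:
            raise ValueError(f"metaservers not in tool list: {sorted(bad_meta)}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def committee_tools(self) -> list[str]:
        """Tools eligible for committees, i.e. everything but metaservers."""
        return [t for t in self.tools if t not in self.metaservers]

    def calls_frame(self) -> pd.DataFrame:
        """Harmonized calls as a DataFrame (variant_id x tool)."""
        return pd.DataFrame(
            [[c.call for c in row] for row in self.calls],
            index=[v.variant_id for v in self.variants],
            columns=self.tools,
        )

    def scores_frame(self) -> pd.DataFrame:
        """Raw (un-oriented) scores as a float DataFrame with NaN for missing."""
        return pd.DataFrame(
            [[float("nan") if c.score is None else c.score for c in row]
             for row in self.calls],
            index=[v.variant_id for v in self.variants],
            columns=self.tools,
            dtype=float,
        )

    def truths(self) -> list[str]:
        return [v.truth for v in self.variants]

    def column(self, tool: str) -> list[ToolCall]:
        j = self.tools.index(tool)
        return [row[j] for row in self.calls]

    def polarity(self, tool: str) -> str:
        col = self.column(tool)
        return col[0].polarity if col else HIGH_IS_DAMAGING

    def subset(self, keep: Sequence[bool]) -> "PredictionPanel":
        """Row-subset the panel by a boolean mask (used for stratification)."""
        if len(keep) != self.n_variants:
            raise ValueError("mask length must equal number of variants")
        return PredictionPanel(
            variants=[v for v, k in zip(self.variants, keep) if k],
            tools=list(self.tools),
            calls=[row for row, k in zip(self.calls, keep) if k],
            metaservers=self.metaservers,
        )


#: collapse map for the two-group SCN5A region stratification:
#: amino-/carboxyl-terminus plus transmembrane segments vs inter-domain loops
REGION_COLLAPSE: dict[str, str] = {
    "n_term": "n_tm_c",
    "transmembrane": "n_tm_c",
    "c_term": "n_tm_c",
    "loop": "loop",
    "unassigned": "unassigned",
}


def collapse_region(region: str, collapse: Mapping[str, str] = REGION_COLLAPSE) -> str:
    return collapse.get(region, "unassigned")


def _format_score(score: float | None, missing_token: str) -> str:
    if score is None:
        return missing_token
    return repr(score)  # repr round-trips floats exactly


def write_panel(panel: PredictionPanel, path: str | Path, schema: PanelSchema,
                delimiter: str = "\t") -> None:
    """Serialize a panel; ``read_panel`` of the result reproduces it exactly."""
    header = [
        schema.variant_id_column,
        schema.gene_column,
        schema.truth_column,
        schema.evidence_column,
        schema.allele_frequency_column,
        schema.region_column,
    ]
    tool_schemas = {t.name: t for t in schema.tools}
    for name in panel.tools:
        ts = tool_schemas[name]
        header.append(ts.resolved_call_column())
        score_col = ts.resolved_score_column()
        if score_col is not None:
            header.append(score_col)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(header)
        for variant, row in zip(panel.variants, panel.calls):
            cells = [
                variant.variant_id,
                variant.gene,
                variant.truth,
                variant.evidence,
                _format_score(variant.allele_frequency, schema.missing_token),
                variant.region,
            ]
            for name, call in zip(panel.tools, row):
                ts = tool_schemas[name]
                cells.append(
                    schema.missing_token if call.raw_label is None else call.raw_label
                )
                if ts.resolved_score_column() is not None:
                    cells.append(_format_score(call.score, schema.missing_token))
            writer.writerow(cells)


def read_panel(path: str | Path, schema: PanelSchema, delimiter: str = "\t",
               metaservers: Sequence[str] | None = None) -> PredictionPanel:
    """Parse a panel TSV/CSV against a schema.

    Ragged rows, duplicate variant IDs and schema columns absent from the
    header raise :class:`PanelFormatError` with the offending line number.
    """
    tool_schemas = {t.name: t for t in schema.tools}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise PanelFormatError(f"{path}: line 1: empty file") from None
        col = {name: i for i, name in enumerate(header)}

        required = [schema.variant_id_column, schema.gene_column, schema.truth_column]
        for ts in schema.tools:
            required.append(ts.resolved_call_column())
        missing_cols = [c for c in required if c not in col]
        if missing_cols:
            raise PanelFormatError(
                f"{path}: line 1: schema columns absent from header: {missing_cols}"
            )

        def cell(row: list[str], name: str) -> str | None:
            i = col.get(name)
            if i is None:
                return None
            value = row[i]
            return None if value == schema.missing_token or value == "" else value

        variants: list[VariantRecord] = []
        calls: list[list[ToolCall]] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise PanelFormatError(
                    f"{path}: line {lineno}: ragged row "
                    f"({len(row)} fields, header has {len(header)})"
                )
            vid = cell(row, schema.variant_id_column)
            if vid is None:
                raise PanelFormatError(f"{path}: line {lineno}: missing variant ID")
            if vid in seen:
                raise PanelFormatError(
                    f"{path}: line {lineno}: duplicate variant ID {vid!r}"
                )
            seen.add(vid)
            af = cell(row, schema.allele_frequency_column)
            try:
                variant = VariantRecord(
                    variant_id=vid,
                    gene=cell(row, schema.gene_column) or "",
                    truth=cell(row, schema.truth_column) or "",
                    evidence=cell(row, schema.evidence_column) or "functional",
                    allele_frequency=None if af is None else float(af),
                    region=cell(row, schema.region_column) or "unassigned",
                )
            except ValueError as exc:
                raise PanelFormatError(f"{path}: line {lineno}: {exc}") from None
            row_calls: list[ToolCall] = []
            for ts in schema.tools:
                raw = cell(row, ts.resolved_call_column())
                score_col = ts.resolved_score_column()
                score = cell(row, score_col) if score_col is not None else None
                if raw is None:
                    call = MISSING
                else:
                    try:
                        call = harmonize_label(ts.name, raw, ts.vocabulary)
                    except HarmonizationError as exc:
                        raise PanelFormatError(
                            f"{path}: line {lineno}: {exc}"
                        ) from None
                row_calls.append(
                    ToolCall(
                        tool=ts.name,
                        raw_label=raw,
                        call=call,
                        score=None if score is None else float(score),
                        polarity=ts.polarity,
                    )
                )
            variants.append(variant)
            calls.append(row_calls)

    meta = tuple(metaservers) if metaservers is not None else tuple(
        m for m in DEFAULT_METASERVERS if m in [t.name for t in schema.tools]
    )
    return PredictionPanel(
        variants=variants,
        tools=[t.name for t in schema.tools],
        calls=calls,
        metaservers=meta,
    )
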
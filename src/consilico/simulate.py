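"""Synthetic prediction panels with controlled error rates and dependence.

Real multi-tool benchmarks have three statistical features the pipeline
must cope with: tools are imperfect (each has its own sensitivity and
specificity), tools are positively correlated (they share training
signal, so they tend to fail on the same "hard" variants), and calls come
with continuous scores of tool-specific polarity.  The generator
reproduces all three with a Gaussian-copula latent-difficulty model:

* each variant draws a shared difficulty z ~ N(0, 1);
* tool t errs on the variant iff sqrt(rho)*z + sqrt(1-rho)*eps_t exceeds
  Phi^-1(p_t), where eps_t ~ N(0, 1) is tool-private noise and p_t is the
  tool's sensitivity (pathogenic variants) or specificity (benign ones).

The probit threshold gives exact marginal control — each tool's expected
correctness rate equals the configured p_t for every rho — while rho in
[0, 1) is a single knob for inter-tool correlation.  Scores are drawn
conditional on the emitted call, so call and score never contradict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

from .panel import (
    BENIGN,
    DAMAGING,
    DEFAULT_METASERVERS,
    DEFAULT_POLARITIES,
    DEFAULT_VOCABULARIES,
    HIGH_IS_DAMAGING,
    LOW_IS_DAMAGING,
    MISSING,
    PATHOGENIC,
    TOLERATED,
    PredictionPanel,
    ToolCall,
    VariantRecord,
)


@dataclass(frozen=True)
class ToolProfile:
    """Error-rate and score model for one simulated predictor."""

    sensitivity: float
    specificity: float
    polarity: str = HIGH_IS_DAMAGING
    separation: float = 2.0  # latent score-class separation; larger => higher AUC
    metaserver: bool = False

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.polarity not in (HIGH_IS_DAMAGING, LOW_IS_DAMAGING):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")


@dataclass(frozen=True)
class GeneComposition:
    """Class sizes and region mix for one gene's variants."""

    n_pathogenic: int
    n_benign: int
    region_probs: tuple[tuple[str, float], ...] = (("unassigned", 1.0),)

    def __post_init__(self) -> None:
        if self.n_pathogenic < 0 or self.n_benign < 0:
            raise ValueError("class sizes must be non-negative")
        total = sum(p for _, p in self.region_probs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region probabilities must sum to 1, got {total}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one synthetic panel; the seed is mandatory."""

    genes: dict[str, GeneComposition]
    tools: dict[str, ToolProfile]
    seed: int
    rho: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not self.genes:
            raise ValueError("at least one gene required")
        if not self.tools:
            raise ValueError("at least one tool required")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def total_variants(self) -> int:
        return sum(g.n_pathogenic + g.n_benign for g in self.genes.values())


def _canonical_raw_label(tool: str, call: str) -> str:
    vocab = DEFAULT_VOCABULARIES.get(tool)
    if vocab:
        for raw, harmonized in vocab.items():
            if harmonized == call:
                return raw
    return call  # synthetic tools use the harmonized names as their vocabulary


def generate_panel(config: SimulationConfig) -> PredictionPanel:
    """Draw one panel from the latent-difficulty model.

    Deterministic in the config seed: the same config yields a
    byte-identical panel.  Pathogenic variants get functional or
    co-segregation evidence; benign variants get functional evidence or a
    population allele frequency above the 1% inclusion threshold, so
    every generated record passes the inclusion filter.
    """
    rng = np.random.default_rng(config.seed)
    tool_names = list(config.tools)
    sqrt_rho = np.sqrt(config.rho)
    sqrt_bar = np.sqrt(1.0 - config.rho)

    variants: list[VariantRecord] = []
    calls: list[list[ToolCall]] = []
    for gene, comp in config.genes.items():
        truth_block = [PATHOGENIC] * comp.n_pathogenic + [BENIGN] * comp.n_benign
        regions = [r for r, _ in comp.region_probs]
        region_p = np.array([p for _, p in comp.region_probs])
        for k, truth in enumerate(truth_block):
            region = str(rng.choice(regions, p=region_p))
            if truth == PATHOGENIC:
                evidence = "functional" if rng.random() < 0.8 else "cosegregation"
                af = None
            else:
                if rng.random() < 0.5:
                    evidence, af = "functional", None
                else:
                    evidence = "allele_frequency"
                    af = float(rng.uniform(0.011, 0.05))
            variants.append(
                VariantRecord(
                    variant_id=f"{gene}:p.V{k + 1:03d}",
                    gene=gene,
                    truth=truth,
                    evidence=evidence,
                    allele_frequency=af,
                    region=region,
                )
            )

            z = rng.standard_normal()
            row: list[ToolCall] = []
            for name in tool_names:
                prof = config.tools[name]
                p_correct = prof.sensitivity if truth == PATHOGENIC else prof.specificity
                eps = rng.standard_normal()
                errs = sqrt_rho * z + sqrt_bar * eps > norm.ppf(p_correct)
                truth_call = DAMAGING if truth == PATHOGENIC else TOLERATED
                call = (
                    (TOLERATED if truth_call == DAMAGING else DAMAGING)
                    if errs else truth_call
                )
                # score on the prob-damaging scale, conditional on the call
                mu = prof.separation / 2.0 if call == DAMAGING else -prof.separation / 2.0
                p_damaging = float(norm.cdf(rng.normal(mu, 1.0)))
                score = p_damaging if prof.polarity == HIGH_IS_DAMAGING else 1.0 - p_damaging
                if rng.random() < config.missing_rate:
                    row.append(ToolCall(tool=name, raw_label=None, call=MISSING,
                                        score=None, polarity=prof.polarity))
                else:
                    row.append(
                        ToolCall(
                            tool=name,
                            raw_label=_canonical_raw_label(name, call),
                            call=call,
                            score=score,
                            polarity=prof.polarity,
                        )
                    )
            calls.append(row)

    return PredictionPanel(
        variants=variants,
        tools=tool_names,
        calls=calls,
        metaservers=tuple(n for n, p in config.tools.items() if p.metaserver),
    )


#: region mix used for the simulated SCN5A variants: roughly even split
#: between the membrane-associated portions (termini + transmembrane
#: segments) and the large cytoplasmic inter-domain loops
_SCN5A_REGIONS = (
    ("n_term", 0.10),
    ("transmembrane", 0.35),
    ("c_term", 0.15),
    ("loop", 0.40),
)


def lqts_benchmark_config(seed: int = 20240) -> SimulationConfig:
    """Default panel emulating the curated LQTS benchmark composition.

    Three genes with the published class sizes — KCNQ1 101 pathogenic /
    8 benign, KCNH2 82/8, SCN5A 99/14, 312 variants in all — scored by
    the five predictors plus the two metaservers.  Per-tool error rates
    are plausible stand-ins in the range such tools achieve on curated
    cardiac-channel panels (sensitivities 0.85-0.93, specificities
    0.5-0.7); inter-tool correlation rho = 0.3.
    """
    tools = {
        "PolyPhen-2": ToolProfile(0.92, 0.55, HIGH_IS_DAMAGING, separation=1.8),
        "SNPs&GO": ToolProfile(0.88, 0.70, HIGH_IS_DAMAGING, separation=2.0),
        "SIFT": ToolProfile(0.90, 0.65, LOW_IS_DAMAGING, separation=1.9),
        "PROVEAN": ToolProfile(0.91, 0.70, LOW_IS_DAMAGING, separation=2.1),
        "SNAP": ToolProfile(0.85, 0.50, HIGH_IS_DAMAGING, separation=1.2),
        "Meta-SNP": ToolProfile(0.93, 0.70, HIGH_IS_DAMAGING, separation=2.3,
                                metaserver=True),
        "PredictSNP": ToolProfile(0.87, 0.60, HIGH_IS_DAMAGING, separation=1.5,
                                  metaserver=True),
    }
    genes = {
        "KCNQ1": GeneComposition(101, 8),
        "KCNH2": GeneComposition(82, 8),
        "SCN5A": GeneComposition(99, 14, region_probs=_SCN5A_REGIONS),
    }
    return SimulationConfig(genes=genes, tools=tools, seed=seed, rho=0.3,
                            missing_rate=0.0)


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "seed": int(config.seed),
        "rho": config.rho,
        "missing_rate": config.missing_rate,
        "genes": {
            g: {
                "n_pathogenic": c.n_pathogenic,
                "n_benign": c.n_benign,
                "region_probs": {r: p for r, p in c.region_probs},
            }
            for g, c in config.genes.items()
        },
        "tools": {
            t: {
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
                "polarity": p.polarity,
                "separation": p.separation,
                "metaserver": p.metaserver,
            }
            for t, p in config.tools.items()
        },
    }


def config_from_dict(raw: dict) -> SimulationConfig:
    genes = {
        g: GeneComposition(
            n_pathogenic=int(c["n_pathogenic"]),
            n_benign=int(c["n_benign"]),
            region_probs=tuple(
                (r, float(p))
                for r, p in c.get("region_probs", {"unassigned": 1.0}).items()
            ),
        )
        for g, c in raw["genes"].items()
    }
    tools = {
        t: ToolProfile(
            sensitivity=float(p["sensitivity"]),
            specificity=float(p["specificity"]),
            polarity=p.get("polarity", HIGH_IS_DAMAGING),
            separation=float(p.get("separation", 2.0)),
            metaserver=bool(p.get("metaserver", False)),
        )
        for t, p in raw["tools"].items()
    }
    return SimulationConfig(
        genes=genes,
        tools=tools,
        seed=int(raw["seed"]),
        rho=float(raw.get("rho", 0.0)),
        missing_rate=float(raw.get("missing_rate", 0.0)),
    )


def save_sim_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_sim_config(path: str | Path) -> SimulationConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))
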
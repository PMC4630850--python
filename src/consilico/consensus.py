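"""Committee voting over harmonized predictor calls.

The decision rule, for a committee of any size: the consensus is
*damaging* when at least half the committee calls damaging — i.e. strict
majority for odd committees, majority-with-ties-damaging for even ones.
Ties resolve towards pathogenicity deliberately: in a clinical screening
setting a false "damaging" is recoverable by segregation follow-up,
whereas a false "tolerated" may end the work-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Iterable, Sequence

import numpy as np

from .panel import DAMAGING, MISSING, TOLERATED, PredictionPanel


@dataclass(frozen=True)
class ToolCombination:
    """An ordered subset of panel tools acting as one voting committee."""

    tools: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tools) == 0:
            raise ValueError("a combination needs at least one tool")
        if len(set(self.tools)) != len(self.tools):
            raise ValueError(f"duplicate tools in combination: {self.tools}")

    @property
    def size(self) -> int:
        return len(self.tools)

    @property
    def label(self) -> str:
        """Report label: '+'-joined sorted tool names."""
        return "+".join(sorted(self.tools))


def consensus_call(calls: Sequence[str]) -> str:
    """Vote over a non-empty list of harmonized calls.

    Returns ``damaging`` iff damaging votes make up at least half the
    committee (``2 * n_damaging >= len(calls)``).  ``missing`` entries are
    a caller error: filter or reduce the committee first.
    """
    if len(calls) == 0:
        raise ValueError("cannot vote over an empty call list")
    n_damaging = 0
    for c in calls:
        if c == DAMAGING:
            n_damaging += 1
        elif c == MISSING:
            raise ValueError(
                "call list contains 'missing'; apply a missing policy before voting"
            )
        elif c != TOLERATED:
            raise ValueError(f"invalid call {c!r}")
    return DAMAGING if 2 * n_damaging >= len(calls) else TOLERATED


def enumerate_combinations(
    tools: Sequence[str], sizes: Iterable[int]
) -> list[ToolCombination]:
    """All tool subsets of the requested sizes, in deterministic order.

    Ordered by size, then lexicographically by tool name; exactly C(n, s)
    combinations per size s.
    """
    tool_list = list(tools)
    size_list = sorted(set(sizes))
    for s in size_list:
        if not 1 <= s <= len(tool_list):
            raise ValueError(
                f"combination size {s} out of range 1..{len(tool_list)}"
            )
    out: list[ToolCombination] = []
    for s in size_list:
        for combo in _combinations(sorted(tool_list), s):
            out.append(ToolCombination(tools=combo))
    return out


def apply_combination(
    panel: PredictionPanel,
    combo: ToolCombination,
    missing_policy: str = "exclude",
) -> tuple[list[str | None], np.ndarray]:
    """Per-variant consensus of one committee, with an evaluability mask.

    ``missing_policy='exclude'`` (default) masks out any variant for which
    a committee member has no prediction; ``'reduce'`` votes over the
    non-missing subset (at least one call) with the same tie rule.
    Returns ``(calls, mask)`` aligned with ``panel.variants``; masked
    entries carry ``None``.
    """
    if missing_policy not in ("exclude", "reduce"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    unknown = [t for t in combo.tools if t not in panel.tools]
    if unknown:
        raise KeyError(f"combination tools not in panel: {unknown}")
    idx = [panel.tools.index(t) for t in combo.tools]
    out_calls: list[str | None] = []
    mask = np.zeros(panel.n_variants, dtype=bool)
    for i, row in enumerate(panel.calls):
        votes = [row[j].call for j in idx]
        present = [v for v in votes if v != MISSING]
        if len(present) < len(votes) and missing_policy == "exclude":
            out_calls.append(None)
            continue
        if not present:  # reduce with everything missing
            out_calls.append(None)
            continue
        out_calls.append(consensus_call(present))
        mask[i] = True
    return out_calls, mask
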
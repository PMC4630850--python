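"""Committee voting rule, combination enumeration, per-variant application."""

from itertools import product

import numpy as np
import pytest

import consilico as c
from consilico import DAMAGING, TOLERATED

# The published voting conditions, transcribed row by row as
# (committee size, damaging votes) -> consensus.  "Two/three outputs are
# ..." rows are read as at-least counts, which makes the table total.
RULE_TABLE = {
    (1, 0): TOLERATED, (1, 1): DAMAGING,
    (2, 0): TOLERATED, (2, 1): DAMAGING, (2, 2): DAMAGING,
    (3, 0): TOLERATED, (3, 1): TOLERATED, (3, 2): DAMAGING, (3, 3): DAMAGING,
    (4, 0): TOLERATED, (4, 1): TOLERATED, (4, 2): DAMAGING, (4, 3): DAMAGING,
    (4, 4): DAMAGING,
    (5, 0): TOLERATED, (5, 1): TOLERATED, (5, 2): TOLERATED, (5, 3): DAMAGING,
    (5, 4): DAMAGING, (5, 5): DAMAGING,
}


def test_consensus_matches_rule_table_exhaustively():
    """Every call vector of size 1..5 reproduces the published rule rows."""
    for k in range(1, 6):
        for votes in product([DAMAGING, TOLERATED], repeat=k):
            expected = RULE_TABLE[(k, votes.count(DAMAGING))]
            assert c.consensus_call(list(votes)) == expected, votes


@pytest.mark.parametrize(
    "votes,expected",
    [
        ([DAMAGING, TOLERATED], DAMAGING),  # even tie resolves damaging
        ([DAMAGING, DAMAGING, TOLERATED, TOLERATED], DAMAGING),
        ([TOLERATED, TOLERATED, TOLERATED, DAMAGING, DAMAGING], TOLERATED),
        ([TOLERATED] * 4, TOLERATED),
    ],
)
def test_consensus_examples(votes, expected):
    assert c.consensus_call(votes) == expected


def test_consensus_monotone_and_symmetric():
    """Flipping one vote to damaging never flips the consensus to tolerated;
    the vote is order-invariant."""
    for k in range(1, 6):
        for votes in product([DAMAGING, TOLERATED], repeat=k):
            base = c.consensus_call(list(votes))
            assert c.consensus_call(list(reversed(votes))) == base
            for i, v in enumerate(votes):
                if v == TOLERATED:
                    flipped = list(votes)
                    flipped[i] = DAMAGING
                    if base == DAMAGING:
                        assert c.consensus_call(flipped) == DAMAGING


def test_consensus_rejects_empty_and_missing():
    with pytest.raises(ValueError, match="empty"):
        c.consensus_call([])
    with pytest.raises(ValueError, match="missing"):
        c.consensus_call([DAMAGING, c.MISSING])


def test_enumerate_combinations_counts_and_order():
    tools = ["SNAP", "SIFT", "PROVEAN", "SNPs&GO", "PolyPhen-2"]
    combos = c.enumerate_combinations(tools, {2, 3, 4, 5})
    assert len(combos) == 26  # 10 + 10 + 5 + 1
    assert len(c.enumerate_combinations(tools, range(1, 6))) == 31  # 2^5 - 1
    assert len(c.enumerate_combinations(tools[:2], {2})) == 1
    # deterministic: by size, then lexicographic
    sizes = [cb.size for cb in combos]
    assert sizes == sorted(sizes)
    two = [cb.tools for cb in combos if cb.size == 2]
    assert two == sorted(two)
    with pytest.raises(ValueError, match="out of range"):
        c.enumerate_combinations(tools, {6})


def test_combination_label_and_validation():
    combo = c.ToolCombination(("SIFT", "PROVEAN", "SNPs&GO"))
    assert combo.label == "PROVEAN+SIFT+SNPs&GO"
    with pytest.raises(ValueError, match="duplicate"):
        c.ToolCombination(("SIFT", "SIFT"))


def _mini_panel():
    """Three variants, three tools; variant 2 is missing tool B."""
    variants = [
        c.VariantRecord(variant_id=f"G:p.V{i}", gene="G", truth=t)
        for i, t in enumerate(["pathogenic", "pathogenic", "benign"])
    ]
    call_of = {
        "D": (DAMAGING, "damaging"),
        "T": (TOLERATED, "tolerated"),
        ".": (c.MISSING, None),
    }
    grid = [["D", "D", "T"], ["D", ".", "T"], ["T", "T", "D"]]
    calls = [
        [c.ToolCall(tool=t, raw_label=call_of[s][1], call=call_of[s][0])
         for t, s in zip("ABC", row)]
        for row in grid
    ]
    return c.PredictionPanel(variants=variants, tools=["A", "B", "C"], calls=calls)


def test_apply_combination_exclude_masks_missing():
    panel = _mini_panel()
    combo = c.ToolCombination(("A", "B", "C"))
    calls, mask = c.apply_combination(panel, combo, missing_policy="exclude")
    assert list(mask) == [True, False, True]
    assert calls[0] == DAMAGING  # 2 of 3 damaging
    assert calls[1] is None


def test_apply_combination_reduce_votes_on_present_subset():
    panel = _mini_panel()
    combo = c.ToolCombination(("A", "B", "C"))
    calls, mask = c.apply_combination(panel, combo, missing_policy="reduce")
    assert list(mask) == [True, True, True]
    # reduced committee [D, T] ties -> damaging
    assert calls[1] == DAMAGING


def test_apply_combination_unknown_tool_and_policy():
    panel = _mini_panel()
    with pytest.raises(KeyError, match="not in panel"):
        c.apply_combination(panel, c.ToolCombination(("A", "X")))
    with pytest.raises(ValueError, match="missing policy"):
        c.apply_combination(panel, c.ToolCombination(("A",)), missing_policy="drop")


def test_all_present_mask_is_all_true():
    panel = _mini_panel()
    calls, mask = c.apply_combination(panel, c.ToolCombination(("A", "C")))
    assert mask.all() and None not in calls
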
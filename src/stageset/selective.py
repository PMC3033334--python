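"""Condition-"selective" gene sets by Venn cross-intersection.

A gene is selective for a condition when it is concordance-selected and
up-regulated against every comparator condition (for the four-population
design: the same cell type at the other stage AND the other cell type at
the same stage).  Because up-regulation is antisymmetric per pair, the
selective sets of different conditions are provably disjoint; the check is
still asserted on every pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

__all__ = [
    "SelectiveSetResult",
    "pairwise_up_list",
    "build_selective",
    "check_disjoint",
]

VENN_REGION_CAP = 6  # beyond 6 comparator lists only pairwise/full counts


def pairwise_up_list(records: pd.DataFrame) -> frozenset[str]:
    """Genes selected with direction Up in one ordered comparison."""
    up = records[(records["selected"]) & (records["direction"] == "Up")]
    return frozenset(up["feature_id"].astype(str))


@dataclass(frozen=True)
class SelectiveSetResult:
    condition: str
    comparators: tuple[str, ...]
    pairwise_up: dict[str, frozenset[str]]
    selective: frozenset[str]
    venn_counts: dict[str, int]  # "+-" pattern over comparators -> count


def build_selective(
    condition: str, up_lists: dict[str, frozenset[str]]
) -> SelectiveSetResult:
    """Intersect the pairwise up-lists of one condition.

    venn_counts keys are membership patterns over the comparator lists in
    sorted-comparator order ("+" = in the list), one per non-empty region
    of the Venn diagram; their values sum to |union of the lists|.
    """
    if not up_lists:
        raise ValueError("at least one comparator up-list is required")
    comparators = tuple(sorted(up_lists))
    selective = frozenset.intersection(*(up_lists[c] for c in comparators))
    venn: dict[str, int] = {}
    if len(comparators) <= VENN_REGION_CAP:
        union = frozenset.union(*(up_lists[c] for c in comparators))
        for gene in union:
            pattern = "".join(
                "+" if gene in up_lists[c] else "-" for c in comparators
            )
            venn[pattern] = venn.get(pattern, 0) + 1
    else:
        venn["".join("+" for _ in comparators)] = len(selective)
        for a, b in combinations(comparators, 2):
            venn[f"{a}&{b}"] = len(up_lists[a] & up_lists[b])
    return SelectiveSetResult(
        condition=condition,
        comparators=comparators,
        pairwise_up=dict(up_lists),
        selective=selective,
        venn_counts=venn,
    )


def check_disjoint(results: list[SelectiveSetResult]) -> pd.DataFrame:
    """Pairwise overlaps between selective sets; an empty frame is a pass."""
    if len(results) < 2:
        raise ValueError("need at least two selective sets to compare")
    rows = []
    for a, b in combinations(results, 2):
        shared = a.selective & b.selective
        for gene in sorted(shared):
            rows.append(
                {"feature_id": gene, "set_a": a.condition, "set_b": b.condition}
            )
    return pd.DataFrame.from_records(rows, columns=["feature_id", "set_a", "set_b"])
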
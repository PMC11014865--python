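"""The tree-sorting engine: classify each single-gene tree's origin.

For a query ("seed") protein, every non-trivial bipartition of its gene tree
is scanned; the seed-containing side qualifies for a category when, after
discarding the seed and neutral seed-lineage leaves, it consists exclusively
of that category's group with at least ``min_members`` members (and one
witness-group leaf when required).  The call's score is the highest support
among qualifying edges.  When several categories qualify, the highest score
wins; equal best scores resolve to the wider category if the categories are
nested and one qualifying side contains the other, and to ``unresolved``
otherwise.  Bootstrap support of 75 is flagged as the interpretation
threshold but never suppresses a call.

The module also tallies the internal topology of the three kareniacean
genera supported by each tree, and the affiliation of the endosymbiont
signal to individual haptophyte families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxa import (
    CategoryDef,
    KARENIACEAN_GENERA,
    TaxonScheme,
    family_categories,
)
from .treeio import Bipartition, PhyloTree, enumerate_bipartitions, side_containing

__all__ = [
    "GroupBounds",
    "SortCriterion",
    "OriginCall",
    "TopologyCall",
    "SUPPORT_THRESHOLD",
    "best_supported_edge",
    "classify_origin",
    "tally_internal_topology",
    "family_affiliation",
    "summarize_calls",
    "criterion_for_category",
]

#: lower bootstrap bound generally used when *interpreting* origin calls;
#: annotates calls (``passed_threshold``) without suppressing them.
SUPPORT_THRESHOLD = 75.0

SPECIAL_CATEGORIES = ("unresolved", "dinoflagellate-specific", "lineage-specific")


@dataclass(frozen=True)
class GroupBounds:
    """Optional count/proportion bounds for one group on the evaluated side."""

    min_count: int | None = None
    max_count: int | None = None
    min_proportion: float | None = None
    max_proportion: float | None = None

    def __post_init__(self):
        if (
            self.min_count is not None
            and self.max_count is not None
            and self.min_count > self.max_count
        ):
            raise ValueError("min_count > max_count")
        for p in (self.min_proportion, self.max_proportion):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError("proportions must lie in [0, 1]")


@dataclass(frozen=True)
class SortCriterion:
    """Taxon-set constraints a seed-containing side must satisfy.

    ``group_bounds`` are per-group min/max counts and proportions;
    ``restrict_to``, when set, additionally requires every counted leaf to
    belong to that group (clade purity).  Counts and proportion denominators
    exclude the seed itself and neutral seed-lineage leaves.
    """

    group_bounds: Mapping[str, GroupBounds] = field(default_factory=dict)
    restrict_to: str | None = None


@dataclass(frozen=True)
class OriginCall:
    """Per-tree evolutionary-origin decision for one seed sequence."""

    seed: str
    category: str
    score: float | None = None
    qualifying_side: frozenset[str] | None = None

    @property
    def passed_threshold(self) -> bool:
        return self.score is not None and self.score >= SUPPORT_THRESHOLD


@dataclass(frozen=True)
class TopologyCall:
    """Which internal kareniacean genus topology a tree supports."""

    tree_id: str
    topology: str  # "KL|T", "KT|L", "LT|K" or "ambiguous"
    score: float | None = None
    kareniaceae_monophyletic: bool = False
    family_affiliation: str | None = None


# ---------------------------------------------------------------------------
# criterion evaluation

def _counted_leaves(
    side: frozenset[str], seed: str, scheme: TaxonScheme
) -> list[str]:
    return [
        leaf for leaf in side if leaf != seed and not scheme.is_neutral(leaf)
    ]


def _satisfies(
    side: frozenset[str],
    seed: str,
    criterion: SortCriterion,
    scheme: TaxonScheme,
) -> bool:
    counted = _counted_leaves(side, seed, scheme)
    n = len(counted)
    if criterion.restrict_to is not None:
        for leaf in counted:
            if criterion.restrict_to not in scheme.groups_of(leaf):
                return False
    for group, bounds in criterion.group_bounds.items():
        count = sum(1 for leaf in counted if group in scheme.groups_of(leaf))
        if bounds.min_count is not None and count < bounds.min_count:
            return False
        if bounds.max_count is not None and count > bounds.max_count:
            return False
        if bounds.min_proportion is not None or bounds.max_proportion is not None:
            prop = count / n if n else 0.0
            if bounds.min_proportion is not None and prop < bounds.min_proportion:
                return False
            if bounds.max_proportion is not None and prop > bounds.max_proportion:
                return False
    return True


def best_supported_edge(
    tree: PhyloTree,
    seed: str,
    criterion: SortCriterion,
    scheme: TaxonScheme,
    bipartitions: Sequence[Bipartition] | None = None,
) -> tuple[float, frozenset[str]] | None:
    """Highest-supported non-trivial edge whose seed side meets the criterion.

    Ties on support break toward the smaller side, then lexicographically.
    Returns ``None`` when no edge qualifies.  ``bipartitions`` may be passed
    to reuse an enumeration across categories.
    """
    if seed not in tree.leaves:
        raise KeyError(f"seed {seed!r} not among leaves of tree {tree.tree_id}")
    bad = scheme.check_leaves(tree.leaves)
    if bad:
        raise ValueError(
            f"unresolvable leaves in tree {tree.tree_id}: {sorted(bad)}"
        )
    if bipartitions is None:
        bipartitions = enumerate_bipartitions(tree)
    best: tuple[float, int, tuple[str, ...], frozenset[str]] | None = None
    for bp in bipartitions:
        side = side_containing(bp, seed)
        if not _satisfies(side, seed, criterion, scheme):
            continue
        key = (-bp.support_for_side(side), len(side), tuple(sorted(side)))
        if best is None or key < best[0:3]:
            best = key + (side,)
    if best is None:
        return None
    return (-best[0], best[3])


def criterion_for_category(
    category: CategoryDef, scheme: TaxonScheme
) -> SortCriterion:
    """Purity criterion for one category: >= min_members of the member
    group, nothing outside it (seed lineage aside), plus the witness."""
    bounds = {category.member_group: GroupBounds(min_count=category.min_members)}
    if category.required_witness_group is not None:
        bounds[category.required_witness_group] = GroupBounds(min_count=1)
    return SortCriterion(group_bounds=bounds, restrict_to=category.member_group)


def classify_origin(
    tree: PhyloTree,
    seed: str,
    categories: Sequence[CategoryDef],
    scheme: TaxonScheme,
) -> OriginCall:
    """Assign a tree's seed to the best-supported origin category.

    Highest score wins across categories; on equal best scores the wider of
    two nested categories is selected when one qualifying side contains the
    other, otherwise the call is ``unresolved``.
    """
    bipartitions = enumerate_bipartitions(tree)
    results: dict[str, tuple[float, frozenset[str]]] = {}
    by_name = {c.name: c for c in categories}
    for category in categories:
        hit = best_supported_edge(
            tree, seed, criterion_for_category(category, scheme), scheme,
            bipartitions=bipartitions,
        )
        if hit is not None:
            results[category.name] = hit
    if not results:
        return OriginCall(seed=seed, category="unresolved")
    top = max(score for score, _side in results.values())
    tied = {name: res for name, res in results.items() if res[0] == top}
    if len(tied) == 1:
        (name, (score, side)), = tied.items()
        return OriginCall(seed=seed, category=name, score=score, qualifying_side=side)
    winner = _resolve_nested_tie(tied, by_name, scheme)
    if winner is None:
        return OriginCall(seed=seed, category="unresolved", score=top)
    score, side = tied[winner]
    return OriginCall(seed=seed, category=winner, score=score, qualifying_side=side)


def _resolve_nested_tie(
    tied: Mapping[str, tuple[float, frozenset[str]]],
    by_name: Mapping[str, CategoryDef],
    scheme: TaxonScheme,
) -> str | None:
    """Pick the widest category if the tie is a fully nested chain."""
    names = list(tied)
    # candidate winner: category whose member group is an ancestor of every
    # other tied category's member group, and whose side contains the others
    for name in names:
        g = by_name[name].member_group
        side = tied[name][1]
        ok = True
        for other in names:
            if other == name:
                continue
            og = by_name[other].member_group
            oside = tied[other][1]
            if not (scheme.is_within(og, g) and oside <= side):
                ok = False
                break
        if ok:
            return name
    return None


# ---------------------------------------------------------------------------
# topology and family tallies

_TOPOLOGY_LABELS = {
    frozenset({"Karenia", "Karlodinium"}): "KL|T",
    frozenset({"Karenia", "Takayama"}): "KT|L",
    frozenset({"Karlodinium", "Takayama"}): "LT|K",
}


def tally_internal_topology(
    tree: PhyloTree,
    scheme: TaxonScheme,
    genera: Sequence[str] = KARENIACEAN_GENERA,
) -> TopologyCall:
    """Which two-genus grouping the tree supports, at what support.

    Topology XY|Z is supported by a bipartition whose one side holds every
    leaf of genera X and Y present in the tree, no leaf of Z, and no
    non-kareniacean leaf (strictest reading: the two-genus side must be
    kareniacean-pure).  The best-supported topology wins; an exact tie, a
    missing genus or a tree without internal edges is ``ambiguous``.
    """
    bad = scheme.check_leaves(tree.leaves)
    if bad:
        raise ValueError(
            f"unresolvable leaves in tree {tree.tree_id}: {sorted(bad)}"
        )
    genus_leaves = {
        g: frozenset(
            leaf for leaf in tree.leaves if g in scheme.groups_of(leaf)
        )
        for g in genera
    }
    kareniacean = frozenset(
        leaf
        for leaf in tree.leaves
        if scheme.seed_lineage in scheme.groups_of(leaf)
    )
    try:
        bipartitions = enumerate_bipartitions(tree)
    except ValueError:
        bipartitions = []

    monophyletic = any(
        side == kareniacean for bp in bipartitions for side in bp.sides()
    )
    if any(not leaves for leaves in genus_leaves.values()):
        return TopologyCall(
            tree_id=tree.tree_id,
            topology="ambiguous",
            kareniaceae_monophyletic=monophyletic,
        )

    scores: dict[str, float] = {}
    for bp in bipartitions:
        for side in bp.sides():
            if not side <= kareniacean:
                continue
            present = frozenset(
                g for g in genera if genus_leaves[g] & side
            )
            label = _TOPOLOGY_LABELS.get(present)
            if label is None:
                continue
            if all(genus_leaves[g] <= side for g in present):
                scores[label] = max(
                    scores.get(label, 0.0), bp.support_for_side(side)
                )
    if not scores:
        return TopologyCall(
            tree_id=tree.tree_id,
            topology="ambiguous",
            kareniaceae_monophyletic=monophyletic,
        )
    top = max(scores.values())
    winners = [label for label, s in scores.items() if s == top]
    if len(winners) > 1:
        return TopologyCall(
            tree_id=tree.tree_id,
            topology="ambiguous",
            score=top,
            kareniaceae_monophyletic=monophyletic,
        )
    return TopologyCall(
        tree_id=tree.tree_id,
        topology=winners[0],
        score=top,
        kareniaceae_monophyletic=monophyletic,
    )


def family_affiliation(
    tree: PhyloTree,
    seed: str,
    scheme: TaxonScheme,
    families: Sequence[str] | None = None,
) -> tuple[str | None, float | None]:
    """Haptophyte family whose pure clade the seed clusters with, if any."""
    categories = (
        family_categories()
        if families is None
        else [CategoryDef(f, f) for f in families]
    )
    call = classify_origin(tree, seed, categories, scheme)
    if call.category in SPECIAL_CATEGORIES:
        return (None, None)
    return (call.category, call.score)


# ---------------------------------------------------------------------------
# summaries

def summarize_calls(
    calls: Iterable[OriginCall | TopologyCall],
) -> pd.DataFrame:
    """Counts and proportions per category (origin calls) or topology.

    For origin calls, proportions are taken over *classified* trees (the
    unresolved / dinoflagellate-specific / lineage-specific rows are counted
    but excluded from the denominator).  Topology summaries always report
    the four rows KL|T, KT|L, LT|K, ambiguous.
    """
    calls = list(calls)
    if not calls:
        return pd.DataFrame(columns=["category", "count", "proportion"])
    if isinstance(calls[0], TopologyCall):
        order = ["KL|T", "KT|L", "LT|K", "ambiguous"]
        counts = {t: 0 for t in order}
        for call in calls:
            counts[call.topology] = counts.get(call.topology, 0) + 1
        return pd.DataFrame(
            {"category": order, "count": [counts[t] for t in order]}
        )
    counts: dict[str, int] = {}
    for call in calls:
        counts[call.category] = counts.get(call.category, 0) + 1
    classified_total = sum(
        c for name, c in counts.items() if name not in SPECIAL_CATEGORIES
    )
    rows = []
    ordered = sorted(
        counts, key=lambda name: (name in SPECIAL_CATEGORIES, name)
    )
    for name in ordered:
        count = counts[name]
        if name in SPECIAL_CATEGORIES or classified_total == 0:
            prop = float("nan")
        else:
            prop = count / classified_total
        rows.append({"category": name, "count": count, "proportion": prop})
    return pd.DataFrame(rows)
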
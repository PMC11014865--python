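"""Independent brute-force oracles for the sorter.

Deliberately naive re-derivations used only by tests: splits are collected
by a direct traversal of the tree's node structure, category rules are
checked with explicit loops, and tie resolution is re-implemented from the
written rules.  No code is shared with plastosort.sorter.
"""

from __future__ import annotations


def _records(tree):
    """(clade leafset, support) for every non-root vertex, by direct walk."""
    out = []

    def walk(node):
        if node.is_leaf:
            leafset = frozenset([node.label])
        else:
            leafset = frozenset()
            for child in node.children:
                leafset |= walk(child)
        if node is not tree.root:
            support = 0.0 if node.is_leaf else float(node.support)
            out.append((leafset, support))
        return leafset

    walk(tree.root)
    return out


def seed_side_candidates(tree, seed):
    """All (seed-containing side, support) pairs over non-trivial splits.

    When a split is recorded from both directions (rooted binary root),
    the seed side's own record wins; otherwise the complement's record
    serves both sides.
    """
    all_leaves = tree.root.leaf_labels()
    by_split = {}
    for clade, support in _records(tree):
        other = all_leaves - clade
        key = frozenset([clade, other])
        by_split.setdefault(key, {})[clade] = support
    candidates = []
    for key, recs in by_split.items():
        sides = sorted(key, key=lambda s: (len(s), tuple(sorted(s))))
        if min(len(s) for s in sides) < 2:
            continue
        seed_side = next(s for s in sides if seed in s)
        if seed_side in recs:
            support = recs[seed_side]
        else:
            support = max(recs.values())
        candidates.append((seed_side, support))
    return candidates


def _qualifies(side, seed, category, scheme):
    counted = [
        leaf for leaf in side if leaf != seed and not scheme.is_neutral(leaf)
    ]
    members = 0
    witnesses = 0
    for leaf in counted:
        groups = scheme.groups_of(leaf)
        if category.member_group not in groups:
            return False
        members += 1
        if (
            category.required_witness_group is not None
            and category.required_witness_group in groups
        ):
            witnesses += 1
    if members < category.min_members:
        return False
    if category.required_witness_group is not None and witnesses < 1:
        return False
    return True


def oracle_best_edge(tree, seed, category, scheme):
    """Best qualifying (support, side) for one category, or None."""
    best = None
    for side, support in seed_side_candidates(tree, seed):
        if not _qualifies(side, seed, category, scheme):
            continue
        key = (-support, len(side), tuple(sorted(side)))
        if best is None or key < best[0]:
            best = (key, side, support)
    if best is None:
        return None
    return (best[2], best[1])


def oracle_classify(tree, seed, categories, scheme):
    """(category name, score) by exhaustive enumeration; 'unresolved' with
    score None when nothing qualifies, the tied score on an unresolvable
    tie, and the wider category on a fully nested tie."""
    hits = {}
    for category in categories:
        res = oracle_best_edge(tree, seed, category, scheme)
        if res is not None:
            hits[category.name] = res
    if not hits:
        return ("unresolved", None)
    top = max(score for score, _ in hits.values())
    tied = {name: res for name, res in hits.items() if res[0] == top}
    if len(tied) == 1:
        name = next(iter(tied))
        return (name, top)
    by_name = {c.name: c for c in categories}
    for name in tied:
        side = tied[name][1]
        group = by_name[name].member_group
        if all(
            other == name
            or (
                tied[other][1] <= side
                and group in scheme.ancestors(by_name[other].member_group)
            )
            for other in tied
        ):
            return (name, top)
    return ("unresolved", top)
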
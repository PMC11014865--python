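"""Reading, writing and bipartition structure of support-valued gene trees.

Trees are read from Newick or Nexus documents (via dendropy) into a small
unrooted-semantics container, :class:`PhyloTree`.  Support values may be
encoded either as internal-node labels (``(A,B)95:0.1``) or as numeric
branch/node comments (``(A,B)[&support=95]:0.1``); both dialects are
auto-detected.  Supports given as proportions (every value <= 1) are scaled
to the 0-100 range.  A rooted input is stored as parsed but treated as
unrooted everywhere downstream: the two root-adjacent edges of a rooted
binary tree describe the same bipartition and are collapsed on enumeration.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy

_log = logging.getLogger(__name__)

__all__ = [
    "TreeParseError",
    "Node",
    "PhyloTree",
    "Bipartition",
    "parse_tree_file",
    "enumerate_bipartitions",
    "side_containing",
    "write_trees",
]


class TreeParseError(ValueError):
    """Raised for malformed tree documents (naming the offending tree)."""


@dataclass
class Node:
    """One vertex of the rooted representation of a tree.

    ``support`` lives on the edge subtending the node (None at the root),
    already normalized to the 0-100 scale; ``support_imputed`` marks internal
    edges whose document carried no support label (imputed as 0).
    """

    label: str | None = None
    children: list["Node"] = field(default_factory=list)
    support: float | None = None
    length: float | None = None
    support_imputed: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def leaf_labels(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        out: set[str] = set()
        for child in self.children:
            out |= child.leaf_labels()
        return frozenset(out)


@dataclass
class PhyloTree:
    """Unrooted leaf-labelled tree with support-valued internal edges."""

    tree_id: str
    root: Node

    @property
    def leaves(self) -> frozenset[str]:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def supports(self) -> list[float]:
        """Supports of all internal edges (post-normalization)."""
        out = []
        for node in self.root.iter_nodes():
            if node is not self.root and not node.is_leaf:
                out.append(node.support)
        return out

    def to_newick(self) -> str:
        return _node_to_newick(self.root) + ";"


@dataclass(frozen=True)
class Bipartition:
    """A split of the leaf set induced by removing one edge.

    ``side_a`` is the lexicographically smaller representation (fewer
    leaves, ties by sorted labels); trivial bipartitions cut off a single
    leaf.  Bipartitions are invariant under re-rooting.

    A genuinely unrooted (trifurcating-root) document labels each split
    once, so both side supports coincide.  A rooted binary document labels
    the single root split twice - once per root-adjacent clade - and the
    two labels are kept side-specifically (``support_a``/``support_b``):
    the sorter scores a qualifying side by the label attached to that
    side's own subtree, while the canonical ``support`` of the split is
    the maximum of the two.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]
    support_a: float
    support_b: float
    trivial: bool = False

    @property
    def support(self) -> float:
        return max(self.support_a, self.support_b)

    def support_for_side(self, side: frozenset[str]) -> float:
        if side == self.side_a:
            return self.support_a
        if side == self.side_b:
            return self.support_b
        raise KeyError("not a side of this bipartition")

    def sides(self) -> tuple[frozenset[str], frozenset[str]]:
        return self.side_a, self.side_b


# ---------------------------------------------------------------------------
# parsing

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_COMMENT_SUPPORT_RE = re.compile(
    r"(?:support|label|posterior|bootstrap)\s*=\s*([0-9.eE+-]+)"
)


def parse_tree_file(
    path_or_text: str | Path, format: str = "auto"
) -> list[PhyloTree]:
    """Read every tree in a Newick or Nexus document.

    Parameters
    ----------
    path_or_text
        A filesystem path, or the document text itself.
    format
        ``newick``, ``nexus`` or ``auto`` (sniffed from the leading
        ``#NEXUS`` token).

    Returns
    -------
    list of PhyloTree, one per tree statement, with supports normalized to
    the 0-100 scale (proportion-scale documents multiplied by 100) and
    missing internal supports imputed as 0.
    """
    text, source = _read_document(path_or_text)
    if not text.strip():
        raise TreeParseError(f"empty tree document: {source}")
    if format not in ("newick", "nexus", "auto"):
        raise ValueError(f"unknown format {format!r}")
    if format == "auto":
        format = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    try:
        tree_list = dendropy.TreeList.get(
            data=text,
            schema=format,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"could not parse {source}: {exc}") from exc
    if len(tree_list) == 0:
        raise TreeParseError(f"no trees found in {source}")
    out = []
    for i, dtree in enumerate(tree_list):
        label = dtree.label or f"tree{i + 1}"
        out.append(_convert(dtree, label, source))
    return out


def _read_document(path_or_text: str | Path) -> tuple[str, str]:
    if isinstance(path_or_text, Path):
        return path_or_text.read_text(), str(path_or_text)
    text = str(path_or_text)
    # Heuristic: tree statements contain '(' or ';'; short paths do not.
    looks_like_tree = "(" in text or ";" in text or "\n" in text
    if not looks_like_tree and text.strip():
        p = Path(text)
        if p.is_file():
            return p.read_text(), text
    return text, "<string>"


def _support_from_dendropy(node: "dendropy.Node") -> float | None:
    """Extract a raw support value from either dialect."""
    label = node.label
    if label is not None and _NUMERIC_RE.match(str(label).strip()):
        return float(label)
    comments = list(getattr(node, "comments", []) or [])
    if node.edge is not None:
        comments += list(getattr(node.edge, "comments", []) or [])
    for comment in comments:
        body = str(comment).strip().lstrip("&")
        if _NUMERIC_RE.match(body):
            return float(body)
        m = _COMMENT_SUPPORT_RE.search(body)
        if m:
            return float(m.group(1))
    return None


def _convert(dtree: "dendropy.Tree", tree_id: str, source: str) -> PhyloTree:
    def build(dnode: "dendropy.Node") -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or dnode.taxon.label is None:
                raise TreeParseError(f"unlabelled leaf in tree {tree_id} ({source})")
            return Node(
                label=str(dnode.taxon.label),
                length=dnode.edge.length,
            )
        node = Node(length=dnode.edge.length)
        node.support = _support_from_dendropy(dnode)
        node.children = [build(c) for c in dnode.child_nodes()]
        return node

    root = build(dtree.seed_node)
    tree = PhyloTree(tree_id=tree_id, root=root)

    labels = [n.label for n in root.iter_nodes() if n.is_leaf]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeParseError(
            f"duplicate leaf labels in tree {tree_id} ({source}): {sorted(dupes)}"
        )
    _normalize_supports(tree, source)
    return tree


def _normalize_supports(tree: PhyloTree, source: str) -> None:
    internal = [
        n
        for n in tree.root.iter_nodes()
        if n is not tree.root and not n.is_leaf
    ]
    present = [n.support for n in internal if n.support is not None]
    scale = 100.0 if present and all(s <= 1.0 for s in present) else 1.0
    for node in internal:
        if node.support is None:
            node.support = 0.0
            node.support_imputed = True
        else:
            node.support = node.support * scale
            if not (0.0 <= node.support <= 100.0):
                raise TreeParseError(
                    f"support {node.support} outside [0, 100] in tree "
                    f"{tree.tree_id} ({source})"
                )


# ---------------------------------------------------------------------------
# bipartitions

def enumerate_bipartitions(
    tree: PhyloTree, include_trivial: bool = False
) -> list[Bipartition]:
    """One Bipartition per edge of the unrooted topology.

    The two root-adjacent edges of a rooted binary input describe the same
    split and are collapsed (keeping the maximum support, with a warning
    when two explicit labels disagree).  Output order is deterministic:
    lexicographic by the smaller side.
    """
    all_leaves = tree.leaves
    if len(all_leaves) < 3:
        raise ValueError(
            f"tree {tree.tree_id} has {len(all_leaves)} leaves; need >= 3"
        )
    # key: frozenset of the two sides -> {clade side: (support, explicit)}
    seen: dict[frozenset[frozenset[str]], dict] = {}

    def visit(node: Node) -> frozenset[str]:
        if node.is_leaf:
            clade = frozenset([node.label])
        else:
            clade = frozenset().union(*(visit(c) for c in node.children))
        if node is tree.root:
            return clade
        other = all_leaves - clade
        support = 0.0 if node.is_leaf else float(node.support)
        explicit = (not node.is_leaf) and not node.support_imputed
        key = frozenset([clade, other])
        records = seen.setdefault(key, {})
        if records:
            (prev_clade, (prev_support, prev_explicit)), = records.items()
            if explicit and prev_explicit and prev_support != support:
                _log.warning(
                    "tree %s: root-adjacent edges carry different supports "
                    "(%s vs %s); the split's canonical support is the maximum",
                    tree.tree_id, prev_support, support,
                )
        records[clade] = (support, explicit)
        return clade

    visit(tree.root)
    out = []
    for key, records in seen.items():
        a, b = sorted(key, key=lambda s: (len(s), tuple(sorted(s))))
        trivial = min(len(a), len(b)) < 2
        if trivial and not include_trivial:
            continue
        fallback = max(sup for sup, _exp in records.values())
        support_a = records.get(a, (fallback, False))[0]
        support_b = records.get(b, (fallback, False))[0]
        out.append(
            Bipartition(
                side_a=a, side_b=b,
                support_a=support_a, support_b=support_b,
                trivial=trivial,
            )
        )
    out.sort(key=lambda bp: (len(bp.side_a), tuple(sorted(bp.side_a))))
    return out


def side_containing(bipartition: Bipartition, leaf: str) -> frozenset[str]:
    """The side of a bipartition that contains ``leaf``."""
    if leaf in bipartition.side_a:
        return bipartition.side_a
    if leaf in bipartition.side_b:
        return bipartition.side_b
    raise KeyError(f"leaf {leaf!r} not in bipartition")


# ---------------------------------------------------------------------------
# writing

def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _node_to_newick(node: Node) -> str:
    if node.is_leaf:
        s = node.label
    else:
        inner = ",".join(_node_to_newick(c) for c in node.children)
        label = "" if node.support is None else _format_number(node.support)
        s = f"({inner}){label}"
    if node.length is not None:
        s += f":{_format_number(node.length)}"
    return s


def write_trees(
    trees: Sequence[PhyloTree] | PhyloTree,
    path: str | Path | None = None,
    format: str = "newick",
) -> str:
    """Serialize trees (supports as internal-node labels on the 0-100 scale).

    Returns the document text; writes it to ``path`` when given.  Newick
    output holds one tree per line; Nexus output a single TREES block.
    """
    if isinstance(trees, PhyloTree):
        trees = [trees]
    if format == "newick":
        text = "\n".join(t.to_newick() for t in trees) + "\n"
    elif format == "nexus":
        buf = io.StringIO()
        buf.write("#NEXUS\nbegin trees;\n")
        for t in trees:
            buf.write(f"    tree {t.tree_id} = [&U] {t.to_newick()}\n")
        buf.write("end;\n")
        text = buf.getvalue()
    else:
        raise ValueError(f"unknown format {format!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def reroot_at(tree: PhyloTree, leaf: str) -> PhyloTree:
    """Return a copy of ``tree`` rerooted on the edge above ``leaf``.

    Supports are edge attributes and follow their edge through the
    re-rooting, so the bipartition set (sides + supports) is preserved
    exactly.  Used to exercise rooting invariance; the sorter itself never
    needs to reroot.
    """
    if leaf not in tree.leaves:
        raise KeyError(f"leaf {leaf!r} not in tree {tree.tree_id}")
    # Build an undirected adjacency keyed by vertex ids, edges carrying
    # (support, imputed, length).  Vertices are leaf labels or fresh ints.
    adjacency: dict[object, list[tuple[object, tuple]]] = {}
    counter = iter(range(10**9))

    def add_edge(u, v, attrs):
        adjacency.setdefault(u, []).append((v, attrs))
        adjacency.setdefault(v, []).append((u, attrs))

    def walk(node: Node):
        vid = node.label if node.is_leaf else next(counter)
        adjacency.setdefault(vid, [])
        for child in node.children:
            cid = walk(child)
            add_edge(vid, cid, (child.support, child.support_imputed, child.length))
        return vid

    walk(tree.root)
    # Suppress any degree-2 vertex (an old root of a rooted input) so the
    # unrooted topology is canonical before re-rooting.
    for vid in list(adjacency):
        nbrs = adjacency[vid]
        if len(nbrs) == 2 and not isinstance(vid, str):
            (u, attrs_u), (v, attrs_v) = nbrs
            merged = _merge_edge_attrs(attrs_u, attrs_v)
            adjacency[u] = [(w, a) for (w, a) in adjacency[u] if w != vid]
            adjacency[v] = [(w, a) for (w, a) in adjacency[v] if w != vid]
            add_edge(u, v, merged)
            del adjacency[vid]

    # New root: the internal vertex adjacent to ``leaf``.
    anchor = adjacency[leaf][0][0]

    def build(vid, parent, edge_attrs) -> Node:
        children = [
            build(w, vid, attrs) for (w, attrs) in adjacency[vid] if w != parent
        ]
        node = Node(label=vid if isinstance(vid, str) else None, children=children)
        if edge_attrs is not None:
            node.support, node.support_imputed, node.length = edge_attrs
        if node.is_leaf:
            node.support = None
            node.support_imputed = False
        return node

    return PhyloTree(tree_id=tree.tree_id, root=build(anchor, None, None))


def _merge_edge_attrs(a: tuple, b: tuple) -> tuple:
    """Merge the two root-adjacent edge records of a rooted input."""
    sup_a, imp_a, len_a = a
    sup_b, imp_b, len_b = b
    support = max(x for x in (sup_a, sup_b) if x is not None) if (
        sup_a is not None or sup_b is not None
    ) else None
    imputed = imp_a and imp_b
    length = None
    if len_a is not None or len_b is not None:
        length = (len_a or 0.0) + (len_b or 0.0)
    return (support, imputed, length)
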
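"""Synthetic-data generators with planted ground truth.

Every generator is deterministic under its seed and emits the exact
external formats the consuming modules read (Newick/Nexus, FASTA, hit
tables, SignalP-style tables), so the sorter, homology filters and
targeting predictor are testable end to end without any downloads.

Planted gene trees are built so recovery is exact, not probabilistic: the
seed is attached sister to a pure clade of the planted category with the
planted support on the subtending edge, and background leaves are
interleaved so that no two leaves of the same top-level group are ever
adjacent - hence no competing category criterion can qualify anywhere in
the tree, at any support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .homology import AlignmentMatrix
from .taxa import CategoryDef, TaxonScheme, default_categories, default_scheme
from .targeting import AMINO_ACIDS, PSSM, uniform_background
from .treeio import Node, PhyloTree

__all__ = [
    "PlantedTreeSpec",
    "simulate_origin_tree",
    "simulate_alignment",
    "simulate_presequences",
    "random_mixed_tree",
    "planted_nonnested_tie",
    "planted_nested_tie",
    "sharp_pssm",
    "flat_pssm",
    "DEFAULT_CONSENSUS",
    "format_signalp5",
]


@dataclass(frozen=True)
class PlantedTreeSpec:
    """Parameters of one planted-origin gene tree."""

    category: str
    support: float
    clade_size: int = 2
    n_background_leaves: int = 6
    kareniacean_inclusion: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if self.clade_size < 2:
            raise ValueError("clade_size must be >= 2")
        if not (0 <= self.support <= 100):
            raise ValueError("support must lie in [0, 100]")
        if self.n_background_leaves < 2:
            raise ValueError("need >= 2 background leaves")


# ---------------------------------------------------------------------------
# helpers

def _datasets_in_group(scheme: TaxonScheme, group: str) -> list[str]:
    return sorted(
        d
        for d in scheme.dataset_groups
        if group in scheme.groups_of_dataset(d)
    )


def _top_group(scheme: TaxonScheme, dataset: str) -> str:
    for g in scheme.dataset_groups[dataset]:
        ancestors = scheme.ancestors(g)
        for a in ancestors:
            if scheme.group_parents.get(a) is None:
                return a
    raise ValueError(f"no top-level group for dataset {dataset!r}")


def _random_binary(
    items: Sequence[Node], rng: np.random.Generator, support_fn
) -> Node:
    """Join subtrees pairwise at random into one binary tree."""
    nodes = list(items)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = Node(children=[left, right])
        left_sup, right_sup = support_fn(), support_fn()
        for child, sup in ((left, left_sup), (right, right_sup)):
            if not child.is_leaf and child.support is None:
                child.support = sup
        nodes.append(parent)
    return nodes[0]


def _leaf(label: str) -> Node:
    return Node(label=label)


def _dfs_leaves(node: Node) -> list[Node]:
    if node.is_leaf:
        return [node]
    out = []
    for child in node.children:
        out.extend(_dfs_leaves(child))
    return out


# ---------------------------------------------------------------------------
# planted origin trees

def simulate_origin_tree(
    spec: PlantedTreeSpec,
    scheme: TaxonScheme | None = None,
    categories: Sequence[CategoryDef] | None = None,
) -> tuple[PhyloTree, dict]:
    """A gene tree whose seed provably sorts into ``spec.category``.

    Layout: root is a trichotomy of (i) the planted subtree - the seed
    sister to a pure ``clade_size`` clade of the category's group, with
    ``spec.support`` on the subtending edge - and (ii)+(iii) the two halves
    of a background tree drawn from unrelated groups, interleaved so no
    competing criterion can qualify.  Reproducible under ``rng_seed``.
    """
    scheme = scheme or default_scheme()
    categories = categories or default_categories()
    by_name = {c.name: c for c in categories}
    if spec.category not in by_name:
        raise ValueError(f"unknown category {spec.category!r}")
    category = by_name[spec.category]
    rng = np.random.default_rng(spec.rng_seed)
    serial = iter(range(1, 10_000))

    def support():
        return float(rng.integers(2, 101))

    def label_for(dataset: str) -> str:
        return f"{dataset}_{next(serial):04d}"

    # clade members: exclude seed-lineage datasets (neutral, never counted)
    member_pool = [
        d
        for d in _datasets_in_group(scheme, category.member_group)
        if scheme.seed_lineage not in scheme.groups_of_dataset(d)
    ]
    witness_pool = (
        _datasets_in_group(scheme, category.required_witness_group)
        if category.required_witness_group
        else []
    )
    if not member_pool:
        raise ValueError(f"no datasets available for {category.member_group!r}")
    clade_datasets = []
    if witness_pool:
        clade_datasets.append(witness_pool[int(rng.integers(len(witness_pool)))])
    while len(clade_datasets) < spec.clade_size:
        clade_datasets.append(member_pool[int(rng.integers(len(member_pool)))])
    clade_leaves = [_leaf(label_for(d)) for d in clade_datasets]

    kar_labels = []
    if spec.kareniacean_inclusion:
        kar_pool = _datasets_in_group(scheme, scheme.seed_lineage)
        kar_dataset = kar_pool[int(rng.integers(len(kar_pool)))]
        kar_label = label_for(kar_dataset)
        kar_labels.append(kar_label)
        clade_leaves.append(_leaf(kar_label))

    clade_root = _random_binary(clade_leaves, rng, support)
    if not clade_root.is_leaf and clade_root.support is None:
        clade_root.support = support()

    seed_pool = _datasets_in_group(scheme, scheme.seed_lineage)
    seed_label = label_for(seed_pool[int(rng.integers(len(seed_pool)))])
    planted = Node(children=[_leaf(seed_label), clade_root])
    planted.support = float(spec.support)

    # background: datasets unrelated to the member group or seed lineage
    forbidden = scheme.ancestors(category.member_group)
    bg_pool = [
        d
        for d in sorted(scheme.dataset_groups)
        if not (scheme.groups_of_dataset(d) & forbidden)
        and scheme.seed_lineage not in scheme.groups_of_dataset(d)
    ]
    top_groups = sorted({_top_group(scheme, d) for d in bg_pool})
    if len(top_groups) < 2:
        raise ValueError(
            f"background needs >= 2 unrelated top-level groups for "
            f"category {category.name!r}"
        )
    # build a random topology over placeholders, then colour its leaves in
    # DFS order cycling through distinct top-level groups: every clade of
    # >= 2 background leaves then mixes groups and cannot qualify.
    placeholders = [_leaf(f"__bg{i}") for i in range(spec.n_background_leaves)]
    bg_root = _random_binary(placeholders, rng, support)
    if len(bg_root.children) != 2:  # single-leaf case excluded by spec
        raise AssertionError
    order = rng.permutation(len(top_groups))
    cycle = [top_groups[i] for i in order]
    by_top: dict[str, list[str]] = {
        g: [d for d in bg_pool if _top_group(scheme, d) == g] for g in top_groups
    }
    for i, leaf in enumerate(_dfs_leaves(bg_root)):
        group = cycle[i % len(cycle)]
        pool = by_top[group]
        leaf.label = label_for(pool[int(rng.integers(len(pool)))])

    bg_left, bg_right = bg_root.children
    root = Node(children=[planted, bg_left, bg_right])
    tree = PhyloTree(tree_id=f"planted_{spec.category}_{spec.rng_seed}", root=root)
    truth = {
        "seed": seed_label,
        "category": spec.category,
        "support": float(spec.support),
        "clade": frozenset(n.label for n in _dfs_leaves(clade_root)),
        "neutral_in_clade": tuple(kar_labels),
    }
    return tree, truth


def random_mixed_tree(
    n_leaves: int,
    rng: np.random.Generator,
    scheme: TaxonScheme | None = None,
    groups: Sequence[str] | None = None,
) -> tuple[PhyloTree, str]:
    """A random binary tree over random datasets, with one seed-lineage
    leaf designated as the query; no planted structure.  Used to compare
    the sorter against brute-force oracles."""
    if n_leaves < 4:
        raise ValueError("need >= 4 leaves")
    scheme = scheme or default_scheme()
    pool = sorted(scheme.dataset_groups)
    if groups is not None:
        allowed = set(groups)
        pool = [
            d for d in pool if scheme.groups_of_dataset(d) & allowed
        ]
    serial = iter(range(1, 10_000))
    seed_pool = _datasets_in_group(scheme, scheme.seed_lineage)
    seed_label = f"{seed_pool[int(rng.integers(len(seed_pool)))]}_{next(serial):04d}"
    leaves = [_leaf(seed_label)]
    for _ in range(n_leaves - 1):
        dataset = pool[int(rng.integers(len(pool)))]
        leaves.append(_leaf(f"{dataset}_{next(serial):04d}"))

    def support():
        return float(rng.integers(2, 101))

    root = _random_binary(leaves, rng, support)
    for child in root.children:
        if not child.is_leaf and child.support is None:
            child.support = support()
    tree = PhyloTree(tree_id="random", root=root)
    return tree, seed_label


# -- constructed ties -------------------------------------------------------

def planted_nonnested_tie(support: float = 85.0) -> tuple[PhyloTree, str]:
    """Seed sister to a pure endosymbiont clade on one side and a pure
    green clade on the other, at equal support: the origin call must be
    unresolved."""
    seed = "Karenia_brevis_0001"
    h = [_leaf("Chrysochromulina_tobinii_0001"), _leaf("Emiliania_huxleyi_0001")]
    g = [_leaf("Chlamydomonas_reinhardtii_0001"), _leaf("Micromonas_pusilla_0001")]
    hclade = Node(children=h, support=float(support))
    gclade = Node(children=g, support=float(support))
    root = Node(children=[_leaf(seed), hclade, gclade])
    return PhyloTree(tree_id="tie_nonnested", root=root), seed


def planted_nested_tie(
    support: float = 85.0,
) -> tuple[PhyloTree, str, str, str]:
    """Host-signal and pan-alveolate categories tied at equal support with
    nested qualifying sides; the wider category (alveolate) must win.

    Returns (tree, seed, narrower category, wider category).
    """
    seed = "Karenia_brevis_0001"
    d = [
        _leaf("Symbiodinium_microadriaticum_0001"),
        _leaf("Alexandrium_tamarense_0001"),
    ]
    dclade = Node(children=d, support=50.0)
    inner = Node(children=[dclade, _leaf(seed)], support=float(support))
    with_cil = Node(
        children=[inner, _leaf("Tetrahymena_thermophila_0001")],
        support=float(support),
    )
    root = Node(
        children=[
            with_cil,
            _leaf("Chrysochromulina_tobinii_0002"),
            _leaf("Emiliania_huxleyi_0002"),
        ]
    )
    tree = PhyloTree(tree_id="tie_nested", root=root)
    return tree, seed, "plastid-early", "alveolate"


# ---------------------------------------------------------------------------
# alignments

def simulate_alignment(
    n_rows: int,
    n_cols: int,
    gap_fracs: Sequence[float],
    rng_seed: int = 0,
) -> AlignmentMatrix:
    """Random alignment where row *i* has exactly ``round(gap_fracs[i] *
    n_cols)`` gaps at random positions, residues uniform over the 20-letter
    alphabet."""
    if len(gap_fracs) != n_rows:
        raise ValueError("gap_fracs must have one entry per row")
    if any(not (0.0 <= f <= 1.0) for f in gap_fracs):
        raise ValueError("gap fractions must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    letters = np.array(list(AMINO_ACIDS))
    rows = {}
    for i, frac in enumerate(gap_fracs):
        residues = letters[rng.integers(0, 20, size=n_cols)]
        n_gaps = round(frac * n_cols)
        gap_positions = rng.choice(n_cols, size=n_gaps, replace=False)
        residues[gap_positions] = "-"
        rows[f"seq{i + 1}"] = "".join(residues)
    return AlignmentMatrix(rows=rows)


# ---------------------------------------------------------------------------
# presequences

# window -5..+21: end of the signal peptide (...GHG before the cleavage
# site) followed by an arginine-rich transit-peptide start with a conserved
# proline downstream.
DEFAULT_CONSENSUS = "ACGHG" + "RR" + "ASSATSAASTASA" + "P" + "SSTAAR"


def sharp_pssm(
    consensus: str = DEFAULT_CONSENSUS,
    concentration: float = 0.9,
    positions: Sequence[int] | None = None,
) -> PSSM:
    """A matrix whose positional distributions put ``concentration`` mass
    on the consensus residue and spread the rest uniformly."""
    if not (0.0 < concentration < 1.0):
        raise ValueError("concentration must lie in (0, 1)")
    length = len(consensus)
    if positions is None:
        positions = tuple(range(-5, length - 5))
    bg = np.full(20, 1.0 / 20)
    freq = np.full((length, 20), (1.0 - concentration) / 19)
    for i, residue in enumerate(consensus):
        freq[i, AMINO_ACIDS.index(residue)] = concentration
    scores = np.log2(freq / bg[None, :])
    return PSSM(positions=tuple(positions), scores=scores, background=bg)


def flat_pssm(window_length: int = 27) -> PSSM:
    """A background-equal matrix: every window scores 0 in expectation."""
    positions = tuple(range(-5, window_length - 5))
    bg = np.full(20, 1.0 / 20)
    return PSSM(
        positions=positions,
        scores=np.zeros((window_length, 20)),
        background=bg,
    )


def format_signalp5(
    calls: Sequence[tuple[str, int | None]], probability: float = 0.97
) -> str:
    """A SignalP 5.0 short-format document for (id, cleavage or None)."""
    lines = [
        "# SignalP-5.0\tOrganism: Euk",
        "# ID\tPrediction\tSP(Sec/SPI)\tOTHER\tCS Position",
    ]
    for sid, cleavage in calls:
        if cleavage is None:
            lines.append(f"{sid}\tOTHER\t{1 - probability:.4f}\t{probability:.4f}")
        else:
            lines.append(
                f"{sid}\tSP(Sec/SPI)\t{probability:.4f}\t{1 - probability:.4f}"
                f"\tCS pos: {cleavage}-{cleavage + 1}. Pr: {probability:.4f}"
            )
    return "\n".join(lines) + "\n"


def simulate_presequences(
    matrix: PSSM,
    n: int,
    sp_len_range: tuple[int, int] = (15, 30),
    rng_seed: int = 0,
    tail_length: int = 35,
) -> tuple[dict[str, str], dict[str, int], str]:
    """Sequences with true cleavage sites drawn from a PSSM.

    Each sequence is a random signal peptide of sampled length followed by
    cleavage-window residues sampled from the matrix's positional
    distributions and a random tail.  Returns (id -> sequence, id -> true
    cleavage position, matching SignalP 5.0 short-format document).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = sp_len_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid sp_len_range")
    rng = np.random.default_rng(rng_seed)
    letters = list(AMINO_ACIDS)
    distributions = {
        p: matrix.positional_distribution(p) for p in matrix.positions
    }
    seqs: dict[str, str] = {}
    truth: dict[str, int] = {}
    for i in range(n):
        sid = f"sim{i + 1:04d}"
        sp_len = int(rng.integers(lo, hi + 1))
        total = sp_len + tail_length
        residues = [letters[j] for j in rng.integers(0, 20, size=total)]
        residues[0] = "M"
        for p in matrix.positions:
            idx = sp_len + 1 + p  # 1-based
            if 1 <= idx <= total:
                dist = distributions[p]
                residues[idx - 1] = letters[int(rng.choice(20, p=dist))]
        seqs[sid] = "".join(residues)
        truth[sid] = sp_len
    table = format_signalp5([(sid, truth[sid]) for sid in seqs])
    return seqs, truth, table


def write_fasta(seqs: dict[str, str], path) -> None:
    from pathlib import Path

    text = "".join(f">{sid}\n{seq}\n" for sid, seq in seqs.items())
    Path(path).write_text(text)
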
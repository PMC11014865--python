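"""Mapping of sequence/leaf identifiers to datasets and nested taxon groups.

The sorter's criteria are expressed over *groups* (haptophytes, its six
families, dinoflagellates, ciliates, alveolates, green, brown, prokaryotes,
...), arranged in an acyclic parent hierarchy.  Leaves resolve to a source
*dataset* via ordered prefix/regex rules (first match wins), and a dataset
belongs transitively to every ancestor of its declared groups.

The seed lineage (Kareniaceae by default) is special: its sequences are the
queries whose trees are sorted, so by default they are *neutral* in clade
purity checks - a clade of haptophytes with a few kareniacean leaves inside
still counts as purely haptophyte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "SchemeError",
    "TaxonScheme",
    "CategoryDef",
    "load_scheme",
    "load_categories",
    "default_scheme",
    "default_categories",
    "HAPTOPHYTE_FAMILIES",
    "KARENIACEAN_GENERA",
]

HAPTOPHYTE_FAMILIES = (
    "Chrysochromulinaceae",
    "Isochrysidales",
    "Prymnesiales",
    "Phaeocystales",
    "Coccolithales",
    "Pavlovales",
)

KARENIACEAN_GENERA = ("Karenia", "Karlodinium", "Takayama")


class SchemeError(ValueError):
    """Raised for invalid scheme configuration or unresolvable leaves."""


@dataclass(frozen=True)
class TaxonScheme:
    """Sequence-ID -> dataset -> nested-group mapping.

    Parameters
    ----------
    leaf_rules
        Ordered (regex pattern, dataset id) pairs; ``re.match`` semantics,
        first match wins, so arbitrary suffixes after a dataset prefix are
        tolerated.
    dataset_groups
        Dataset id -> its *directly* declared groups (>= 1 each).
    group_parents
        Group id -> parent group id (or None for a top-level group).
    seed_lineage
        Group whose members are treated as neutral in purity checks when
        ``seed_lineage_neutral`` is set.
    fucoxanthin_datasets
        Datasets that are fucoxanthin-dinoflagellate libraries (the
        homology filter keeps the best five hits per such library instead
        of the best single hit kept per reference dataset).
    contaminant_groups
        Groups whose confident best-hits flag a query as contamination.
    """

    leaf_rules: tuple[tuple[str, str], ...]
    dataset_groups: Mapping[str, frozenset[str]]
    group_parents: Mapping[str, str | None]
    seed_lineage: str = "Kareniaceae"
    seed_lineage_neutral: bool = True
    fucoxanthin_datasets: frozenset[str] = frozenset()
    contaminant_groups: frozenset[str] = frozenset(
        {"eubacteria", "archaea", "metazoa"}
    )
    _compiled: list = field(default_factory=list, repr=False, compare=False)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self._validate()
        self._compiled.extend(
            (re.compile(pattern), dataset) for pattern, dataset in self.leaf_rules
        )

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        for group in self.group_parents:
            seen = set()
            g: str | None = group
            while g is not None:
                if g in seen:
                    raise SchemeError(f"cyclic group nesting at {g!r}")
                seen.add(g)
                parent = self.group_parents.get(g)
                if parent is not None and parent not in self.group_parents:
                    raise SchemeError(
                        f"group {g!r} has undeclared parent {parent!r}"
                    )
                g = parent
        for dataset, groups in self.dataset_groups.items():
            if not groups:
                raise SchemeError(f"dataset {dataset!r} maps to no group")
            for g in groups:
                if g not in self.group_parents:
                    raise SchemeError(
                        f"dataset {dataset!r} references undeclared group {g!r}"
                    )
        for _pattern, dataset in self.leaf_rules:
            if dataset not in self.dataset_groups:
                raise SchemeError(
                    f"rule references undeclared dataset {dataset!r}"
                )
        if self.seed_lineage not in self.group_parents:
            raise SchemeError(
                f"seed lineage {self.seed_lineage!r} is not a declared group"
            )

    # -- queries ------------------------------------------------------------

    @property
    def groups(self) -> frozenset[str]:
        return frozenset(self.group_parents)

    def ancestors(self, group: str) -> frozenset[str]:
        """``group`` itself plus all its transitive parents."""
        out = []
        g: str | None = group
        while g is not None:
            out.append(g)
            g = self.group_parents.get(g)
        return frozenset(out)

    def is_within(self, group: str, ancestor: str) -> bool:
        return ancestor in self.ancestors(group)

    def groups_of_dataset(self, dataset: str) -> frozenset[str]:
        try:
            direct = self.dataset_groups[dataset]
        except KeyError:
            raise SchemeError(f"unknown dataset {dataset!r}") from None
        out: set[str] = set()
        for g in direct:
            out |= self.ancestors(g)
        return frozenset(out)

    def resolve_leaf(self, leaf: str) -> tuple[str, frozenset[str]]:
        """Dataset and transitive group set for a leaf label (first rule wins)."""
        hit = self._cache.get(leaf)
        if hit is not None:
            return hit
        for regex, dataset in self._compiled:
            if regex.match(leaf):
                result = (dataset, self.groups_of_dataset(dataset))
                self._cache[leaf] = result
                return result
        raise SchemeError(f"no rule matches leaf {leaf!r}")

    def dataset_of(self, leaf: str) -> str:
        return self.resolve_leaf(leaf)[0]

    def groups_of(self, leaf: str) -> frozenset[str]:
        return self.resolve_leaf(leaf)[1]

    def is_neutral(self, leaf: str) -> bool:
        """True for seed-lineage leaves when the scheme declares them neutral."""
        return self.seed_lineage_neutral and (
            self.seed_lineage in self.groups_of(leaf)
        )

    def check_leaves(self, leaves: Iterable[str]) -> list[str]:
        """Labels that no rule resolves (empty when the scheme is total)."""
        bad = []
        for leaf in leaves:
            try:
                self.resolve_leaf(leaf)
            except SchemeError:
                bad.append(leaf)
        return bad


@dataclass(frozen=True)
class CategoryDef:
    """One evolutionary-origin category for the tree sorter.

    The seed qualifies for the category when it is sister to or nested
    within a clade of at least ``min_members`` leaves belonging exclusively
    to ``member_group`` (seed-lineage leaves ignored).  A
    ``required_witness_group`` (a subgroup of the member group) must
    additionally contribute at least one leaf - e.g. the pan-alveolate
    category requires a ciliate witness so that a purely dinoflagellate
    clade does not also qualify as alveolate.
    """

    name: str
    member_group: str
    required_witness_group: str | None = None
    min_members: int = 2

    def __post_init__(self):
        if self.min_members < 2:
            raise ValueError("min_members must be >= 2")


# ---------------------------------------------------------------------------
# configuration loading

def load_scheme(config: str | Path | Mapping) -> TaxonScheme:
    """Build a validated TaxonScheme from a YAML/JSON document or mapping.

    Expected keys: ``groups`` (group -> parent or null), ``datasets``
    (dataset -> {groups: [...], kind: reference|fucoxanthin}), ``rules``
    (ordered list of {pattern, dataset}), and optional ``seed_lineage``,
    ``seed_lineage_neutral``, ``contaminant_groups``.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, Mapping):
        raise SchemeError("scheme configuration must be a mapping")

    raw_datasets = config.get("datasets", {})
    if len(set(raw_datasets)) != len(raw_datasets):
        raise SchemeError("duplicate dataset ids")
    dataset_groups = {}
    fucox = set()
    for dataset, decl in raw_datasets.items():
        if isinstance(decl, (list, tuple)):
            decl = {"groups": list(decl)}
        groups = decl.get("groups", [])
        dataset_groups[dataset] = frozenset(groups)
        if decl.get("kind", "reference") == "fucoxanthin":
            fucox.add(dataset)

    rules = tuple(
        (rule["pattern"], rule["dataset"]) for rule in config.get("rules", [])
    )
    kwargs = {}
    if "seed_lineage" in config:
        kwargs["seed_lineage"] = config["seed_lineage"]
    if "seed_lineage_neutral" in config:
        kwargs["seed_lineage_neutral"] = bool(config["seed_lineage_neutral"])
    if "contaminant_groups" in config:
        kwargs["contaminant_groups"] = frozenset(config["contaminant_groups"])
    return TaxonScheme(
        leaf_rules=rules,
        dataset_groups=dataset_groups,
        group_parents=dict(config.get("groups", {})),
        fucoxanthin_datasets=frozenset(fucox),
        **kwargs,
    )


def load_categories(config: str | Path | Iterable) -> list[CategoryDef]:
    """Category definitions from a YAML/JSON list of mappings."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    out = []
    for item in config:
        out.append(
            CategoryDef(
                name=item["name"],
                member_group=item["member_group"],
                required_witness_group=item.get("required_witness_group"),
                min_members=int(item.get("min_members", 2)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# packaged default scheme

_DEFAULT_GROUPS: dict[str, str | None] = {
    "alveolates": None,
    "dinoflagellates": "alveolates",
    "ciliates": "alveolates",
    "Kareniaceae": "dinoflagellates",
    "Karenia": "Kareniaceae",
    "Karlodinium": "Kareniaceae",
    "Takayama": "Kareniaceae",
    "haptophytes": None,
    "Chrysochromulinaceae": "haptophytes",
    "Isochrysidales": "haptophytes",
    "Prymnesiales": "haptophytes",
    "Phaeocystales": "haptophytes",
    "Coccolithales": "haptophytes",
    "Pavlovales": "haptophytes",
    "green": None,
    "brown": None,
    "prokaryotes": None,
    "eubacteria": "prokaryotes",
    "archaea": "prokaryotes",
    "metazoa": None,
    "other_eukaryotes": None,
}

# dataset -> (groups, kind); leaf labels follow "<dataset>_<serial>"
_DEFAULT_DATASETS: dict[str, tuple[tuple[str, ...], str]] = {
    # fucoxanthin kareniacean libraries (seed lineage)
    "Karenia_brevis": (("Karenia",), "fucoxanthin"),
    "Karenia_mikimotoi": (("Karenia",), "fucoxanthin"),
    "Karenia_papilionacea": (("Karenia",), "fucoxanthin"),
    "Karlodinium_micrum": (("Karlodinium",), "fucoxanthin"),
    "Karlodinium_armiger": (("Karlodinium",), "fucoxanthin"),
    "Takayama_helix": (("Takayama",), "fucoxanthin"),
    # haptophytes by family
    "Chrysochromulina_tobinii": (("Chrysochromulinaceae",), "reference"),
    "Emiliania_huxleyi": (("Isochrysidales",), "reference"),
    "Isochrysis_galbana": (("Isochrysidales",), "reference"),
    "Prymnesium_parvum": (("Prymnesiales",), "reference"),
    "Phaeocystis_antarctica": (("Phaeocystales",), "reference"),
    "Coccolithus_braarudii": (("Coccolithales",), "reference"),
    "Pavlova_lutheri": (("Pavlovales",), "reference"),
    # peridinin dinoflagellates
    "Symbiodinium_microadriaticum": (("dinoflagellates",), "reference"),
    "Alexandrium_tamarense": (("dinoflagellates",), "reference"),
    "Amphidinium_carterae": (("dinoflagellates",), "reference"),
    # other alveolates
    "Tetrahymena_thermophila": (("ciliates",), "reference"),
    "Paramecium_tetraurelia": (("ciliates",), "reference"),
    "Toxoplasma_gondii": (("alveolates",), "reference"),
    # LGT donor pools
    "Chlamydomonas_reinhardtii": (("green",), "reference"),
    "Micromonas_pusilla": (("green",), "reference"),
    "Phaeodactylum_tricornutum": (("brown",), "reference"),
    "Ectocarpus_siliculosus": (("brown",), "reference"),
    "Escherichia_coli": (("eubacteria",), "reference"),
    "Synechocystis_PCC6803": (("eubacteria",), "reference"),
    "Sulfolobus_solfataricus": (("archaea",), "reference"),
    # decontamination targets and outgroups
    "Homo_sapiens": (("metazoa",), "reference"),
    "Guillardia_theta": (("other_eukaryotes",), "reference"),
    "Dictyostelium_discoideum": (("other_eukaryotes",), "reference"),
}


def default_scheme() -> TaxonScheme:
    """The packaged scheme: kareniacean seed lineage, six haptophyte
    families, alveolate nesting, LGT donor groups and contaminant groups.

    Leaf labels are expected to follow ``<dataset>_<serial>`` with
    arbitrary suffixes tolerated (paralog tags etc.).
    """
    rules = tuple(
        (f"^{re.escape(dataset)}([_.]|$)", dataset) for dataset in _DEFAULT_DATASETS
    )
    return TaxonScheme(
        leaf_rules=rules,
        dataset_groups={
            d: frozenset(groups) for d, (groups, _kind) in _DEFAULT_DATASETS.items()
        },
        group_parents=dict(_DEFAULT_GROUPS),
        fucoxanthin_datasets=frozenset(
            d for d, (_g, kind) in _DEFAULT_DATASETS.items() if kind == "fucoxanthin"
        ),
    )


def default_categories() -> list[CategoryDef]:
    """The six sorting categories: endosymbiont signal (plastid-late),
    host signal (plastid-early), pan-alveolate with a ciliate witness, and
    the three LGT donor categories."""
    return [
        CategoryDef("plastid-late", "haptophytes"),
        CategoryDef("plastid-early", "dinoflagellates"),
        CategoryDef("alveolate", "alveolates", required_witness_group="ciliates"),
        CategoryDef("green-LGT", "green"),
        CategoryDef("brown-LGT", "brown"),
        CategoryDef("prokaryote-LGT", "prokaryotes"),
    ]


def family_categories(min_members: int = 2) -> list[CategoryDef]:
    """One category per haptophyte family, for affiliation tallies."""
    return [CategoryDef(f, f, min_members=min_members) for f in HAPTOPHYTE_FAMILIES]
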
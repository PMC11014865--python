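import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from plastosort.taxa import default_categories, default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def categories():
    return default_categories()


# short-hands for building example trees with scheme-resolvable labels
LEAF = {
    "seed": "Karenia_brevis_9001",
    "kar1": "Karenia_mikimotoi_0001",
    "kar2": "Karenia_papilionacea_0001",
    "kld1": "Karlodinium_micrum_0001",
    "kld2": "Karlodinium_armiger_0001",
    "tak1": "Takayama_helix_0001",
    "h1": "Chrysochromulina_tobinii_0001",
    "h2": "Emiliania_huxleyi_0001",
    "h3": "Prymnesium_parvum_0001",
    "chry1": "Chrysochromulina_tobinii_0002",
    "chry2": "Chrysochromulina_tobinii_0003",
    "iso1": "Isochrysis_galbana_0001",
    "d1": "Symbiodinium_microadriaticum_0001",
    "d2": "Alexandrium_tamarense_0001",
    "cil1": "Tetrahymena_thermophila_0001",
    "cil2": "Paramecium_tetraurelia_0001",
    "g1": "Chlamydomonas_reinhardtii_0001",
    "g2": "Micromonas_pusilla_0001",
    "b1": "Phaeodactylum_tricornutum_0001",
    "b2": "Ectocarpus_siliculosus_0001",
    "p1": "Escherichia_coli_0001",
    "p2": "Sulfolobus_solfataricus_0001",
    "mz1": "Homo_sapiens_0001",
    "o1": "Guillardia_theta_0001",
}


def expand(newick: str) -> str:
    """Replace short leaf tags in a newick template with scheme labels."""
    out = newick
    for tag in sorted(LEAF, key=len, reverse=True):
        out = out.replace(tag, LEAF[tag])
    return out


@pytest.fixture(scope="session")
def leaf():
    return LEAF
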
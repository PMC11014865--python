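"""Signal-peptide region extraction, 3-mer motif statistics and logo export.

Kareniacean plastid presequences carry characteristic short motifs (a
central LACLAC and a terminal GHG directly preceding the cleavage site);
these operations quantify them: region slicing around the predicted
cleavage site, the percentage of signal peptides containing each 3-mer at
least once, and per-position residue frequency matrices suitable for
sequence-logo rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .targeting import AMINO_ACIDS, SignalPeptideCall

__all__ = [
    "PresequenceRegions",
    "extract_regions",
    "motif_occurrence",
    "composition_and_logo",
]

GAP = "-"


@dataclass(frozen=True)
class PresequenceRegions:
    """Signal-peptide region and putative partial transit-peptide region."""

    sequence_id: str
    sp_region: str  # residues 1..cleavage_pos
    tp_region: str  # up to tp_len residues after the cleavage site

    def __post_init__(self):
        if not self.sp_region:
            raise ValueError("sp_region must be non-empty")


def extract_regions(
    seq: str, call: SignalPeptideCall, tp_len: int = 25
) -> PresequenceRegions:
    """Slice the signal peptide and the ~25 residues following the cleavage
    site (truncated at the sequence end) out of a positive call."""
    if not call.has_sp:
        raise ValueError(f"{call.sequence_id}: no signal peptide predicted")
    cp = call.cleavage_pos
    if cp > len(seq):
        raise ValueError(
            f"{call.sequence_id}: cleavage position {cp} beyond sequence end"
        )
    return PresequenceRegions(
        sequence_id=call.sequence_id,
        sp_region=seq[:cp],
        tp_region=seq[cp : cp + tp_len],
    )


def motif_occurrence(
    regions: Sequence[str], motifs: Iterable[str] | str = "all"
) -> pd.Series:
    """Percentage of regions containing each 3-letter motif at least once.

    Multiple occurrences within one region count once.  ``motifs="all"``
    enumerates every 3-mer present in at least one region.  Percentages lie
    in [0, 100].
    """
    regions = list(regions)
    if not regions:
        raise ValueError("no regions given")
    if isinstance(motifs, str):
        if motifs != "all":
            raise ValueError("motifs must be a list of 3-mers or 'all'")
        found: set[str] = set()
        for region in regions:
            found |= {region[i : i + 3] for i in range(len(region) - 2)}
        motifs = sorted(found)
    else:
        motifs = list(motifs)
        for m in motifs:
            if len(m) != 3:
                raise ValueError(f"motif {m!r} is not 3 letters")
    n = len(regions)
    values = {
        m: 100.0 * sum(1 for r in regions if m in r) / n for m in motifs
    }
    return pd.Series(values, name="percent_of_regions").sort_index()


def composition_and_logo(
    regions: Sequence[str],
) -> tuple[pd.Series, pd.DataFrame]:
    """Overall residue composition and a position x letter frequency matrix.

    Inputs must be aligned (equal length); gaps are allowed and excluded
    from all denominators.  Each position's frequencies sum to 1 over
    non-gap residues; an all-gap column is emitted with zero ``coverage``
    and zero frequencies.  The matrix (letter columns plus a ``coverage``
    column of non-gap counts) is directly exportable for logo rendering.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("no regions given")
    lengths = {len(r) for r in regions}
    if len(lengths) > 1:
        raise ValueError(f"regions differ in length: {sorted(lengths)}")
    (length,) = lengths

    letters = list(AMINO_ACIDS)
    total_counts = {a: 0 for a in letters}
    matrix_rows = []
    for pos in range(length):
        column = [r[pos] for r in regions]
        counts = {a: 0 for a in letters}
        for residue in column:
            if residue == GAP:
                continue
            if residue not in counts:
                raise ValueError(f"invalid residue {residue!r} at position {pos + 1}")
            counts[residue] += 1
            total_counts[residue] += 1
        coverage = sum(counts.values())
        freqs = {
            a: (counts[a] / coverage if coverage else 0.0) for a in letters
        }
        freqs["coverage"] = coverage
        matrix_rows.append(freqs)

    grand = sum(total_counts.values())
    composition = pd.Series(
        {a: (total_counts[a] / grand if grand else 0.0) for a in letters},
        name="frequency",
    )
    matrix = pd.DataFrame(matrix_rows, index=pd.RangeIndex(1, length + 1, name="position"))
    return composition, matrix
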
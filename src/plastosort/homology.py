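"""Homology-search hit filtering, decontamination and alignment acceptance.

These are the gates between raw similarity search output and tree building:
hits above the e-value threshold (1e-10, inclusive) are dropped; one best
hit is kept per reference dataset and the best five per fucoxanthin
dinoflagellate library (to capture recent paralogs); queries whose best hit
is a confident bacterial/archaeal/metazoan match are flagged as
contamination; and trimmed alignments are accepted only when, after
removing rows that are more than 75% gaps, at least 100 columns and 10
sequences remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxa import TaxonScheme

__all__ = [
    "HitRecord",
    "AlignmentMatrix",
    "read_hit_table",
    "filter_hits",
    "categorize_homolog_set",
    "decontaminate",
    "filter_alignment",
]

E_VALUE_MAX = 1e-10
GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular homology-search result."""

    query: str
    subject: str
    e_value: float
    score: float
    subject_dataset: str | None = None

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


def read_hit_table(path_or_text: str | Path) -> list[HitRecord]:
    """Read a 12-column tab-separated hit table (BLAST outfmt-6 dialect,
    as emitted by LAST's tab converter): qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore."""
    if isinstance(path_or_text, Path) or (
        "\t" not in str(path_or_text) and Path(str(path_or_text)).exists()
    ):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    hits = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ValueError(
                f"hit-table line {lineno}: expected 12 columns, got {len(cols)}"
            )
        hits.append(
            HitRecord(
                query=cols[0],
                subject=cols[1],
                e_value=float(cols[10]),
                score=float(cols[11]),
            )
        )
    return hits


def _resolve(hit: HitRecord, scheme: TaxonScheme) -> HitRecord:
    if hit.subject_dataset is not None:
        return hit
    dataset, _groups = scheme.resolve_leaf(hit.subject)
    return replace(hit, subject_dataset=dataset)


def filter_hits(
    hits: Iterable[HitRecord],
    scheme: TaxonScheme,
    e_max: float = E_VALUE_MAX,
    per_fucox_k: int = 5,
) -> list[HitRecord]:
    """Retain the best hit per reference dataset and the best ``per_fucox_k``
    per fucoxanthin dinoflagellate library, at e-value <= ``e_max``.

    All hits must share one query; self-hits to the query sequence are
    excluded.  "Best" orders by e-value ascending, then score descending,
    then subject id.  Output order is deterministic (best first within the
    overall ordering).
    """
    hits = [_resolve(h, scheme) for h in hits]
    queries = {h.query for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    eligible = [
        h for h in hits if h.e_value <= e_max and h.subject != h.query
    ]
    eligible.sort(key=lambda h: (h.e_value, -h.score, h.subject))
    kept: list[HitRecord] = []
    taken: dict[str, int] = {}
    for hit in eligible:
        cap = (
            per_fucox_k
            if hit.subject_dataset in scheme.fucoxanthin_datasets
            else 1
        )
        if taken.get(hit.subject_dataset, 0) < cap:
            taken[hit.subject_dataset] = taken.get(hit.subject_dataset, 0) + 1
            kept.append(hit)
    return kept


def categorize_homolog_set(
    query: str, retained_hits: Sequence[HitRecord], scheme: TaxonScheme
) -> str:
    """``lineage-specific`` (no hits), ``dinoflagellate-specific`` (all
    subjects dinoflagellate, kareniacean or otherwise) or
    ``phylogeny-candidate``."""
    if not retained_hits:
        return "lineage-specific"
    for hit in retained_hits:
        hit = _resolve(hit, scheme)
        if "dinoflagellates" not in scheme.groups_of_dataset(hit.subject_dataset):
            return "phylogeny-candidate"
    return "dinoflagellate-specific"


def decontaminate(
    best_hit: HitRecord | None,
    scheme: TaxonScheme,
    e_max: float = E_VALUE_MAX,
) -> bool:
    """Keep flag for a query given its overall best hit.

    False (drop) iff the best hit lands in a contaminant group (eubacteria,
    archaea or metazoa by default) at e-value <= ``e_max``.
    """
    if best_hit is None:
        return True
    best_hit = _resolve(best_hit, scheme)
    groups = scheme.groups_of_dataset(best_hit.subject_dataset)
    if groups & scheme.contaminant_groups and best_hit.e_value <= e_max:
        return False
    return True


# ---------------------------------------------------------------------------
# alignments

@dataclass(frozen=True)
class AlignmentMatrix:
    """A protein multiple alignment: id -> equal-length gapped row."""

    rows: Mapping[str, str]
    n_columns: int = field(default=0)

    def __post_init__(self):
        lengths = {len(row) for row in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        ncol = lengths.pop() if lengths else 0
        if self.n_columns and self.n_columns != ncol:
            raise ValueError("n_columns does not match row length")
        object.__setattr__(self, "n_columns", ncol)
        alphabet = set(AMINO_ACIDS + GAP + "X*")
        for rid, row in self.rows.items():
            bad = set(row.upper()) - alphabet
            if bad:
                raise ValueError(f"row {rid!r} has invalid residues {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def gap_fraction(self, row_id: str) -> float:
        row = self.rows[row_id]
        return row.count(GAP) / self.n_columns if self.n_columns else 0.0

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignmentMatrix":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(rows={r.id: str(r.seq) for r in records})

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(row), id=rid, description="")
            for rid, row in self.rows.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def filter_alignment(
    aln: AlignmentMatrix,
    max_gap_frac: float = 0.75,
    min_columns: int = 100,
    min_taxa: int = 10,
) -> tuple[AlignmentMatrix, bool, dict]:
    """Row-gap filtering then whole-alignment acceptance.

    Rows with gap fraction strictly greater than ``max_gap_frac`` (gap
    characters over total columns) are removed first; the alignment is then
    accepted iff it has at least ``min_columns`` columns and at least
    ``min_taxa`` remaining rows.  Retained residues are never altered.
    """
    removed = {
        rid: aln.gap_fraction(rid)
        for rid in aln.rows
        if aln.gap_fraction(rid) > max_gap_frac
    }
    kept_rows = {
        rid: row for rid, row in aln.rows.items() if rid not in removed
    }
    filtered = AlignmentMatrix(rows=kept_rows)
    reasons = []
    if aln.n_columns < min_columns:
        reasons.append(f"alignment shorter than {min_columns} positions")
    if len(kept_rows) < min_taxa:
        reasons.append(f"fewer than {min_taxa} taxa after gap filtering")
    accepted = not reasons
    report = {
        "removed_rows": removed,
        "n_columns": aln.n_columns,
        "n_rows_in": aln.n_rows,
        "n_rows_kept": filtered.n_rows,
        "accepted": accepted,
        "reasons": reasons,
    }
    return filtered, accepted, report
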
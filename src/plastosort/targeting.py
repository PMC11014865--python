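"""Bipartite plastid-targeting prediction for fucoxanthin dinoflagellates.

The predictor follows the two-step logic used for secondary red plastids:
a signal peptide call (consumed from SignalP 5.0 short-format output, with
both the original sequence and its first-methionine-trimmed variant pooled,
positives taking priority) followed by scoring of the residues flanking the
cleavage site against a position-specific scoring matrix (PSSM).  Unlike
the diatom/haptophyte consensus, kareniacean transit peptides open with
multiple arginines rather than a phenylalanine, so the matrix is custom:
log-odds over a window anchored on the cleavage site, built from training
windows with a pseudocount (:func:`build_pssm`) or loaded from TSV.

Classification mirrors the ASAFind decision structure: the window is scored
at the predicted site and at small offsets around it; a sequence is a
high-confidence plastid prediction when the at-site score is the maximum
over offsets and reaches ``t_high``, low-confidence when it reaches
``t_low``.  An alternative route (agreement of PrediSI and ChloroP-style
calls) rescues sequences the primary route rejected, prefixed ``SPTP-``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "SignalPeptideCall",
    "PSSM",
    "PresequenceCall",
    "parse_signalp5",
    "write_legacy_table",
    "parse_legacy_table",
    "first_met_trim",
    "pool_variant_calls",
    "build_pssm",
    "uniform_background",
    "asafind_classify",
    "parse_flag_table",
    "alt_positive_ids",
    "merge_routes",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class SignalPeptideCall:
    """Signal-peptide status of one protein.

    ``cleavage_pos`` is the 1-based index of the last signal-peptide
    residue (cleavage occurs between ``cleavage_pos`` and
    ``cleavage_pos + 1``).  ``source_variant`` records whether the call came
    from the original sequence or its first-methionine-trimmed variant
    (coordinates always refer to the original sequence after pooling).
    """

    sequence_id: str
    has_sp: bool
    cleavage_pos: int | None = None
    sp_probability: float | None = None
    source_variant: str = "original"

    def __post_init__(self):
        if self.has_sp and (self.cleavage_pos is None or self.cleavage_pos < 1):
            raise ValueError(
                f"{self.sequence_id}: positive call requires cleavage_pos >= 1"
            )


# ---------------------------------------------------------------------------
# SignalP 5.0 short format and the legacy 3.0-4.1-style table

_CS_RE = re.compile(r"CS pos:\s*(\d+)-(\d+)")


def parse_signalp5(table: str | Path) -> list[SignalPeptideCall]:
    """Parse a SignalP 5.0 short-format document.

    Rows are ``id <tab> prediction <tab> SP(Sec/SPI) prob <tab> OTHER prob
    [<tab> CS pos: a-b. Pr: p]``; ``#`` lines are headers.
    """
    if isinstance(table, Path) or (
        "\n" not in str(table) and Path(str(table)).exists()
    ):
        table = Path(table).read_text()
    calls = []
    for lineno, line in enumerate(str(table).splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = re.split(r"\t|\s{2,}", line.strip())
        if len(cols) < 2:
            raise ValueError(f"signalp row {lineno}: too few columns")
        seq_id, prediction = cols[0], cols[1]
        sp_prob = None
        if len(cols) >= 3:
            try:
                sp_prob = float(cols[2])
            except ValueError:
                sp_prob = None
        if prediction.startswith("SP"):
            m = _CS_RE.search(line)
            if not m:
                raise ValueError(
                    f"signalp row {lineno} ({seq_id}): SP call without a "
                    "parsable CS position"
                )
            calls.append(
                SignalPeptideCall(
                    sequence_id=seq_id,
                    has_sp=True,
                    cleavage_pos=int(m.group(1)),
                    sp_probability=sp_prob,
                )
            )
        else:
            calls.append(
                SignalPeptideCall(
                    sequence_id=seq_id, has_sp=False, sp_probability=sp_prob
                )
            )
    return calls


def write_legacy_table(calls: Iterable[SignalPeptideCall]) -> str:
    """Emit a SignalP 3.0-4.1-style short table.

    Columns: name, Cmax, pos, Ymax, pos, Smax, pos, Smean, D, ?, where
    ``pos`` is the first residue of the mature peptide (cleavage_pos + 1)
    and ``?`` is Y/N.  Probabilities not tracked by the 5.0 parser are
    written as the SP probability or 0.
    """
    lines = ["# name\tCmax\tpos\tYmax\tpos\tSmax\tpos\tSmean\tD\t?"]
    for call in calls:
        p = call.sp_probability if call.sp_probability is not None else 0.0
        pos = (call.cleavage_pos + 1) if call.has_sp else 0
        flag = "Y" if call.has_sp else "N"
        lines.append(
            f"{call.sequence_id}\t{p:.3f}\t{pos}\t{p:.3f}\t{pos}"
            f"\t{p:.3f}\t{pos}\t{p:.3f}\t{p:.3f}\t{flag}"
        )
    return "\n".join(lines) + "\n"


def parse_legacy_table(table: str | Path) -> list[SignalPeptideCall]:
    """Read the legacy-dialect table back (round-trips id/has_sp/cleavage)."""
    if isinstance(table, Path):
        table = table.read_text()
    calls = []
    for line in str(table).splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 10:
            raise ValueError(f"legacy table row has {len(cols)} columns")
        has_sp = cols[9].strip() == "Y"
        calls.append(
            SignalPeptideCall(
                sequence_id=cols[0],
                has_sp=has_sp,
                cleavage_pos=int(cols[4]) - 1 if has_sp else None,
                sp_probability=float(cols[1]),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# variant pooling

def first_met_trim(seq: str) -> str | None:
    """The subsequence starting at the first methionine, or None.

    Accommodates translated UTRs or spliced leaders upstream of the true
    start: both the original and the trimmed variant are submitted to the
    signal-peptide predictor and pooled afterwards.
    """
    if not seq:
        raise ValueError("empty sequence")
    idx = seq.find("M")
    if idx < 0:
        return None
    return seq[idx:]


def pool_variant_calls(
    original: SignalPeptideCall,
    trimmed: SignalPeptideCall | None,
    trim_offset: int = 0,
) -> SignalPeptideCall:
    """Pool the two variant calls, positives taking priority.

    A positive call from the trimmed variant is shifted by ``trim_offset``
    (residues removed before the first methionine) back into original
    coordinates.  When both variants are positive the original-coordinates
    call is kept.
    """
    if trimmed is not None and trimmed.sequence_id != original.sequence_id:
        raise ValueError("pooled calls must refer to the same protein")
    if original.has_sp:
        return original
    if trimmed is not None and trimmed.has_sp:
        return replace(
            trimmed,
            cleavage_pos=trimmed.cleavage_pos + trim_offset,
            source_variant="first_met_trimmed",
        )
    return original


# ---------------------------------------------------------------------------
# PSSM

def uniform_background() -> dict[str, float]:
    return {a: 1.0 / len(AMINO_ACIDS) for a in AMINO_ACIDS}


@dataclass(frozen=True)
class PSSM:
    """Log-odds matrix over a contiguous window anchored on the cleavage
    site.

    Window coordinates are relative: position ``-1`` is the last
    signal-peptide residue, ``0`` the first residue of the mature peptide
    (transit-peptide start).  Position ``p`` addresses 1-based sequence
    index ``cleavage_pos + 1 + p``.
    """

    positions: tuple[int, ...]
    scores: np.ndarray  # shape (len(positions), 20), bits
    background: np.ndarray  # shape (20,)
    pseudocount: float = 1.0

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "background", background)
        if scores.shape != (len(self.positions), len(AMINO_ACIDS)):
            raise ValueError("scores shape must be (n_positions, 20)")
        if background.shape != (len(AMINO_ACIDS),):
            raise ValueError("background must cover the 20-letter alphabet")
        if abs(background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        diffs = np.diff(self.positions)
        if len(self.positions) == 0 or (len(diffs) and not np.all(diffs == 1)):
            raise ValueError("window positions must be contiguous")

    @property
    def window_length(self) -> int:
        return len(self.positions)

    def score_of(self, position: int, residue: str) -> float:
        i = self.positions.index(position)
        j = _AA_INDEX.get(residue)
        if j is None:
            raise KeyError(f"unknown residue {residue!r}")
        return float(self.scores[i, j])

    def max_window_score(self) -> float:
        """Sum of per-position maxima: the consensus window's score."""
        return float(self.scores.max(axis=1).sum())

    def positional_distribution(self, position: int) -> np.ndarray:
        """Residue frequencies implied by the log-odds at one position."""
        i = self.positions.index(position)
        freq = self.background * np.exp2(self.scores[i])
        return freq / freq.sum()

    def score_window(self, seq: str, cleavage_pos: int, offset: int = 0) -> float:
        """Score the window anchored ``offset`` residues from the cleavage
        site; positions falling outside the sequence contribute the
        background expectation, 0."""
        total = 0.0
        any_inside = False
        for i, p in enumerate(self.positions):
            idx = cleavage_pos + 1 + p + offset  # 1-based
            if 1 <= idx <= len(seq):
                any_inside = True
                j = _AA_INDEX.get(seq[idx - 1])
                if j is not None:  # X/ambiguous residues score 0
                    total += float(self.scores[i, j])
        if not any_inside:
            raise ValueError(
                "scoring window lies entirely outside the sequence"
            )
        return total

    # -- serialization: TSV with a header of relative coordinates ----------

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["position\t" + "\t".join(AMINO_ACIDS)]
        for i, p in enumerate(self.positions):
            row = "\t".join(f"{self.scores[i, j]:.6f}" for j in range(20))
            lines.append(f"{p}\t{row}")
        lines.append("# background\t" + "\t".join(f"{b:.6f}" for b in self.background))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, path_or_text: str | Path) -> "PSSM":
        if isinstance(path_or_text, Path) or (
            "\n" not in str(path_or_text) and Path(str(path_or_text)).exists()
        ):
            text = Path(path_or_text).read_text()
        else:
            text = str(path_or_text)
        positions, rows = [], []
        background = None
        header_letters = None
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("# background"):
                background = np.array(
                    [float(x) for x in line.split("\t")[1:]], dtype=float
                )
                continue
            if line.startswith("position"):
                header_letters = line.split("\t")[1:]
                continue
            cols = line.split("\t")
            positions.append(int(cols[0]))
            rows.append([float(x) for x in cols[1:]])
        scores = np.array(rows, dtype=float)
        if header_letters is not None and header_letters != list(AMINO_ACIDS):
            order = [header_letters.index(a) for a in AMINO_ACIDS]
            scores = scores[:, order]
            if background is not None:
                background = background[order]
        if background is None:
            background = np.full(20, 0.05)
        return cls(
            positions=tuple(positions), scores=scores, background=background
        )


def build_pssm(
    training_windows: Sequence[str],
    background: Mapping[str, float] | None = None,
    pseudocount: float = 1.0,
    positions: Sequence[int] | None = None,
) -> PSSM:
    """Log-odds matrix from equal-length cleavage-anchored windows.

    ``score[p, a] = log2(((count(p, a) + pseudocount * bg[a]) / (N +
    pseudocount)) / bg[a])``: zero for a column matching the background,
    ``log2(1 / bg[a])`` for a pure column with no pseudocount.

    ``positions`` defaults to ``-5 ... +21`` for 27-residue windows (the
    packaged geometry: the signal-peptide motif region plus the
    arginine-rich transit-peptide start) and otherwise to a window starting
    at ``-5``.
    """
    if not training_windows:
        raise ValueError("at least one training window required")
    length = len(training_windows[0])
    if any(len(w) != length for w in training_windows):
        raise ValueError("training windows must share one length")
    if background is None:
        background = uniform_background()
    missing = set(AMINO_ACIDS) - set(background)
    if missing:
        raise ValueError(f"background missing letters {sorted(missing)}")
    bg = np.array([background[a] for a in AMINO_ACIDS], dtype=float)
    if positions is None:
        positions = tuple(range(-5, length - 5))
    positions = tuple(positions)
    if len(positions) != length:
        raise ValueError("positions must match window length")

    counts = np.zeros((length, 20), dtype=float)
    for window in training_windows:
        for i, residue in enumerate(window):
            j = _AA_INDEX.get(residue)
            if j is None:
                raise ValueError(f"unknown residue {residue!r} in window")
            counts[i, j] += 1
    n = float(len(training_windows))
    freq = (counts + pseudocount * bg[None, :]) / (n + pseudocount)
    with np.errstate(divide="ignore"):
        scores = np.log2(freq / bg[None, :])
    return PSSM(
        positions=positions,
        scores=scores,
        background=bg,
        pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------------
# classification

@dataclass(frozen=True)
class PresequenceCall:
    """Final bipartite-presequence decision for one protein."""

    sequence_id: str
    sp: SignalPeptideCall
    at_site_score: float | None
    best_offset_score: float | None
    best_offset: int | None
    klass: str  # plastid_high | plastid_low | not_plastid | no_sp
    route: str = "asafind"

    @property
    def output_id(self) -> str:
        if self.route == "sptp_alternative":
            return f"SPTP-{self.sequence_id}"
        return self.sequence_id

    @property
    def is_plastid(self) -> bool:
        return self.klass in ("plastid_high", "plastid_low")


DEFAULT_OFFSETS = range(-2, 3)


def default_thresholds(matrix: PSSM) -> tuple[float, float]:
    """Matrix-relative defaults: half / a quarter of the consensus score."""
    s_max = matrix.max_window_score()
    return 0.5 * s_max, 0.25 * s_max


def asafind_classify(
    seq: str,
    sp: SignalPeptideCall,
    matrix: PSSM,
    offsets: Iterable[int] = DEFAULT_OFFSETS,
    t_high: float | None = None,
    t_low: float | None = None,
) -> PresequenceCall:
    """Score the cleavage-site window and classify the presequence.

    ``plastid_high`` requires the at-site score to be both the maximum over
    the scanned offsets and at least ``t_high``; ``plastid_low`` only
    requires ``t_low`` at the site; otherwise ``not_plastid``.  A negative
    signal-peptide call short-circuits to ``no_sp``.
    """
    if t_high is None or t_low is None:
        th, tl = default_thresholds(matrix)
        t_high = th if t_high is None else t_high
        t_low = tl if t_low is None else t_low
    if t_low > t_high:
        raise ValueError("t_low must not exceed t_high")
    if not sp.has_sp:
        return PresequenceCall(
            sequence_id=sp.sequence_id, sp=sp, at_site_score=None,
            best_offset_score=None, best_offset=None, klass="no_sp",
        )
    offsets = list(offsets)
    if 0 not in offsets:
        offsets.append(0)
    scored = {
        d: matrix.score_window(seq, sp.cleavage_pos, offset=d) for d in offsets
    }
    at_site = scored[0]
    best_offset = max(sorted(scored), key=lambda d: scored[d])
    best_score = scored[best_offset]
    if at_site >= t_high and at_site >= best_score:
        klass = "plastid_high"
    elif at_site >= t_low:
        klass = "plastid_low"
    else:
        klass = "not_plastid"
    return PresequenceCall(
        sequence_id=sp.sequence_id,
        sp=sp,
        at_site_score=at_site,
        best_offset_score=best_score,
        best_offset=best_offset,
        klass=klass,
    )


# ---------------------------------------------------------------------------
# alternative route and merging

def parse_flag_table(table: str | Path, positive: str = "Y") -> dict[str, bool]:
    """Read a simple two-plus-column prediction table (PrediSI- or
    ChloroP-style): id, then a Y/N flag in the last column (a trailing
    score column is tolerated when the flag is second-to-last)."""
    if isinstance(table, Path) or (
        "\n" not in str(table) and Path(str(table)).exists()
    ):
        table = Path(table).read_text()
    out: dict[str, bool] = {}
    for line in str(table).splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = re.split(r"\s+", line.strip())
        flags = [c for c in cols[1:] if c in (positive, "N", "n", "Y", "y")]
        if not flags:
            raise ValueError(f"no Y/N flag in row: {line!r}")
        out[cols[0]] = flags[-1].upper() == positive
    return out


def alt_positive_ids(
    predisi: Mapping[str, bool], chlorop: Mapping[str, bool]
) -> set[str]:
    """Proteins positive by *both* alternative predictors."""
    return {
        sid for sid, flag in predisi.items() if flag and chlorop.get(sid, False)
    }


def merge_routes(
    primary_calls: Iterable[PresequenceCall],
    alt_positive: set[str] = frozenset(),
) -> list[str]:
    """Final plastid-proteome id list.

    Primary-route positives keep their ids; sequences rejected by the
    primary route but positive by the alternative route are appended with
    the ``SPTP-`` prefix.  No duplicates.
    """
    primary_calls = list(primary_calls)
    final: list[str] = []
    seen: set[str] = set()
    positive_primary = set()
    for call in primary_calls:
        if call.is_plastid and call.sequence_id not in seen:
            final.append(call.sequence_id)
            seen.add(call.sequence_id)
            positive_primary.add(call.sequence_id)
    for sid in sorted(alt_positive):
        if sid not in positive_primary:
            out = f"SPTP-{sid}"
            if out not in seen:
                final.append(out)
                seen.add(out)
    return final
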
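"""Nucleotide-binding-motif scanning and alignment-column conservation.

Nucleotide-dependent RCK domains carry the classical Rossmann-fold
glycine-box motif G-x-G-x-x-G followed, 17–18 residues downstream, by an
acidic residue (GxGxxG[17-18]xE/D).  The conserved interface glutamate
(E125 in B. subtilis KtrA numbering) is assessed on ortholog alignments:
percent identity at the E125-equivalent column, the two-residue context
motif (PE/RE/TE/GE), and a length-based split of Kef-family sequences
(KefC proteins have at least 580 residues; shorter ones are KefC-like).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO, SeqIO

from .errors import UsageError

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"

#: KefC-family length threshold, residues.
KEFC_MIN_LENGTH = 580

# non-greedy spacer so the shorter (17) spacer is preferred on overlap;
# finditer yields non-overlapping matches leftmost-first
_NBS_PATTERN = re.compile(r"G.G..G(.{17,18}?)([ED])")


@dataclass
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise UsageError(f"sequence {self.id!r} is empty")
        bad = sorted(set(self.sequence.upper()) - AA_ALPHABET)
        if bad:
            raise UsageError(f"sequence {self.id!r} has invalid characters: {''.join(bad)}")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Alignment:
    rows: list[tuple[str, str]]  # (id, gapped sequence)

    def __post_init__(self):
        if not self.rows:
            raise UsageError("alignment has no rows")
        lengths = {len(seq) for _id, seq in self.rows}
        if len(lengths) != 1:
            raise UsageError("alignment rows have unequal lengths")
        self.rows = [(rid, seq.upper()) for rid, seq in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def row(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise UsageError(f"row {row_id!r} not in alignment")

    def column(self, column: int) -> list[str]:
        """Residues at a 1-based column, one per row."""
        if not 1 <= column <= self.n_columns:
            raise UsageError(f"column {column} out of range 1..{self.n_columns}")
        return [seq[column - 1] for _id, seq in self.rows]


@dataclass
class MotifHit:
    start: int          # 1-based ungapped position of the first glycine
    end: int            # 1-based position of the acidic residue
    spacer_length: int  # 17 or 18
    acidic_residue: str  # E or D


@dataclass
class ColumnReport:
    column: int
    reference_position: int | None
    counts: dict[str, int]
    n_rows: int
    target_residues: frozenset[str]
    percent_identity: int


@dataclass
class ContextMotifTable:
    column: int
    counts: dict[str, int]   # two-letter motif -> row count
    gap_rows: int            # rows with a gap at either position


@dataclass
class FamilyCall:
    label: str   # "KefC" | "KefC-like"
    length: int


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file."""
    if fmt not in {"fasta", "clustal"}:
        raise UsageError(f"unsupported alignment format {fmt!r}")
    aln = AlignIO.read(str(path), fmt)
    return Alignment(rows=[(rec.id, str(rec.seq)) for rec in aln])


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in aln.rows:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Operations


def scan_nbs_motif(seq: SequenceRecord | str, spacer_range: tuple[int, int] = (17, 18)) -> list[MotifHit]:
    """Non-overlapping Rossmann nucleotide-binding-motif matches, leftmost-first.

    Pattern: G-x-G-x-x-G, a spacer of 17–18 arbitrary residues, then E or D.
    On overlapping alternatives the shorter spacer is preferred.  Positions
    are 1-based on the ungapped sequence.
    """
    if isinstance(seq, str):
        seq = SequenceRecord("query", seq)
    lo, hi = spacer_range
    if not (0 < lo <= hi):
        raise UsageError(f"invalid spacer range {spacer_range}")
    if (lo, hi) == (17, 18):
        pattern = _NBS_PATTERN
    else:
        pattern = re.compile(r"G.G..G(.{%d,%d}?)([ED])" % (lo, hi))
    hits = []
    for m in pattern.finditer(seq.sequence):
        hits.append(
            MotifHit(
                start=m.start() + 1,
                end=m.end(),
                spacer_length=len(m.group(1)),
                acidic_residue=m.group(2),
            )
        )
    return hits


def map_reference_position(aln: Alignment, reference_id: str, ungapped_position: int) -> int:
    """Alignment column (1-based) holding the reference row's Nth residue."""
    seq = aln.row(reference_id)
    if ungapped_position < 1:
        raise UsageError("ungapped position must be >= 1")
    count = 0
    for col, ch in enumerate(seq, start=1):
        if ch != GAP:
            count += 1
            if count == ungapped_position:
                return col
    raise UsageError(
        f"position {ungapped_position} beyond ungapped length {count} of row {reference_id!r}"
    )


def column_to_reference_position(aln: Alignment, reference_id: str, column: int) -> int | None:
    """Inverse mapping: ungapped reference position at a column (None on a gap)."""
    seq = aln.row(reference_id)
    if not 1 <= column <= aln.n_columns:
        raise UsageError(f"column {column} out of range 1..{aln.n_columns}")
    if seq[column - 1] == GAP:
        return None
    return sum(1 for ch in seq[:column] if ch != GAP)


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def column_conservation(
    aln: Alignment,
    column: int,
    target_residues: frozenset[str] | set[str] = frozenset({"E"}),
    reference_id: str | None = None,
) -> ColumnReport:
    """Residue counts and percent identity of a target set at one column.

    Gaps are counted in the composition but never toward target matches.
    Percent identity is rounded half away from zero to an integer percent
    (13 of 15 -> 87%).
    """
    residues = aln.column(column)
    counts: dict[str, int] = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    target = frozenset(r.upper() for r in target_residues) - {GAP}
    n_match = sum(1 for r in residues if r in target)
    percent = _round_half_away(100.0 * n_match / aln.n_rows)
    ref_pos = (
        column_to_reference_position(aln, reference_id, column) if reference_id else None
    )
    return ColumnReport(
        column=column,
        reference_position=ref_pos,
        counts=counts,
        n_rows=aln.n_rows,
        target_residues=target,
        percent_identity=percent,
    )


def context_motif(aln: Alignment, column: int) -> ContextMotifTable:
    """Two-residue context motifs (column-1, column) per row, e.g. PE/RE/TE/GE.

    Rows with a gap at either position are counted separately; motif counts
    plus gap rows sum to the number of rows.
    """
    if column < 2:
        raise UsageError("context motif needs column >= 2")
    left = aln.column(column - 1)
    right = aln.column(column)
    counts: dict[str, int] = {}
    gap_rows = 0
    for a, b in zip(left, right):
        if a == GAP or b == GAP:
            gap_rows += 1
        else:
            counts[a + b] = counts.get(a + b, 0) + 1
    return ContextMotifTable(column=column, counts=counts, gap_rows=gap_rows)


def classify_kef_family(seq: SequenceRecord | str) -> FamilyCall:
    """KefC iff the sequence has at least 580 residues, otherwise KefC-like."""
    if isinstance(seq, str):
        seq = SequenceRecord("query", seq)
    label = "KefC" if len(seq) >= KEFC_MIN_LENGTH else "KefC-like"
    return FamilyCall(label=label, length=len(seq))
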
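"""Alignment conservation scanning and Fe(II)-triad candidate detection.

2-oxoglutarate/Fe(II) oxygenases, including ethylene-forming enzymes
and ACC oxidases, coordinate their catalytic ferrous ion through a
2-His-1-carboxylate facial triad: His-x-Asp/Glu two residues apart,
plus a second His some tens of residues downstream (His177/Asp179/His234
in petunia ACC oxidase; His189/Asp191/His268 proposed for the Kudzu
EFE).  This module scans any protein multiple alignment for conserved
columns and for column triples matching that arrangement, reporting
positions in the numbering of a chosen reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
ACIDIC = frozenset("DE")


class AlignmentFormatError(ValueError):
    """Raised for empty files or rows of unequal length."""


@dataclass(frozen=True)
class Alignment:
    """Ordered aligned sequences (uppercase residues, '-' for gaps)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentFormatError("duplicate sequence ids")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise AlignmentFormatError("rows of unequal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None

    def column(self, col: int) -> str:
        """1-based column as a string of residues."""
        return "".join(r[col - 1] for r in self.rows)


@dataclass(frozen=True)
class TriadCandidate:
    """Candidate 2-His-1-carboxylate triad.

    Columns are 1-based alignment columns; ``ref_positions`` are the
    corresponding residue numbers in the reference sequence (gaps
    skipped); ``conservation`` is the per-column fraction of non-gap
    rows matching the reference residue class (H; D/E; H).
    """

    his1: int
    acidic: int
    his2: int
    ref_positions: tuple[int, int, int]
    conservation: tuple[float, float, float]

    @property
    def spacing(self) -> int:
        return self.ref_positions[2] - self.ref_positions[0]

    @property
    def mean_conservation(self) -> float:
        return sum(self.conservation) / 3


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA; '.' is normalized to '-', residues uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    ids, rows = [], []
    length = None
    for rec in records:
        seq = str(rec.seq).upper().replace(".", GAP)
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentFormatError(
                f"record {rec.id!r} has length {len(seq)}, expected {length}"
            )
        ids.append(rec.id)
        rows.append(seq)
    return Alignment(ids=tuple(ids), rows=tuple(rows))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.ids, aln.rows)]
    SeqIO.write(records, str(path), "fasta")


def conserved_columns(
    aln: Alignment, threshold: float = 1.0
) -> list[tuple[int, str, float]]:
    """Columns whose modal non-gap residue reaches the given frequency.

    Frequencies are computed over non-gap rows only (gaps never count
    toward conservation).  Returns (1-based column, residue, fraction).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if aln.n_seqs == 0:
        raise ValueError("empty alignment")
    out = []
    for col in range(1, aln.length + 1):
        residues = [c for c in aln.column(col) if c != GAP]
        if not residues:
            continue
        modal = max(set(residues), key=residues.count)
        frac = residues.count(modal) / len(residues)
        if frac >= threshold:
            out.append((col, modal, frac))
    return out


def column_to_ref_position(aln: Alignment, ref_id: str, column: int) -> int:
    """1-based residue number in the reference at a 1-based column."""
    row = aln.row(ref_id)
    if not 1 <= column <= aln.length:
        raise IndexError(f"column {column} outside alignment of length {aln.length}")
    if row[column - 1] == GAP:
        raise ValueError(f"reference {ref_id!r} has a gap at column {column}")
    return len(row[:column].replace(GAP, ""))


def _class_conservation(aln: Alignment, col: int, residue_class: frozenset[str]) -> float:
    residues = [c for c in aln.column(col) if c != GAP]
    if not residues:
        return 0.0
    return sum(c in residue_class for c in residues) / len(residues)


def find_triads(
    aln: Alignment,
    ref_id: str,
    window: tuple[int, int] = (40, 120),
    threshold: float = 1.0,
) -> list[TriadCandidate]:
    """All conserved His / (Asp|Glu at +2) / downstream-His triples.

    The +2 offset and the downstream spacing window are measured in
    reference residue numbering (gaps skipped), matching how triads are
    reported for real enzymes.  Candidates are sorted by mean
    conservation (descending), then by first-His column.
    """
    row = aln.row(ref_id)
    lo, hi = window
    # reference residue number -> column, for non-gap positions
    ref_cols: list[int] = [i + 1 for i, c in enumerate(row) if c != GAP]

    def conserved(col: int, cls: frozenset[str]) -> float | None:
        frac = _class_conservation(aln, col, cls)
        return frac if frac >= threshold else None

    candidates = []
    for pos1, col1 in enumerate(ref_cols, start=1):
        if row[col1 - 1] != "H":
            continue
        if pos1 + 2 > len(ref_cols):
            continue
        col_acidic = ref_cols[pos1 + 2 - 1]
        if row[col_acidic - 1] not in ACIDIC:
            continue
        c1 = conserved(col1, frozenset("H"))
        ca = conserved(col_acidic, ACIDIC)
        if c1 is None or ca is None:
            continue
        for pos2 in range(pos1 + lo, min(pos1 + hi, len(ref_cols)) + 1):
            col2 = ref_cols[pos2 - 1]
            if row[col2 - 1] != "H":
                continue
            c2 = conserved(col2, frozenset("H"))
            if c2 is None:
                continue
            candidates.append(
                TriadCandidate(
                    his1=col1,
                    acidic=col_acidic,
                    his2=col2,
                    ref_positions=(pos1, pos1 + 2, pos2),
                    conservation=(c1, ca, c2),
                )
            )
    candidates.sort(key=lambda t: (-t.mean_conservation, t.his1))
    return candidates


def triads_to_rows(triads: Iterable[TriadCandidate]) -> list[dict]:
    """Rows for a candidate TSV: rank, positions, spacing, conservation."""
    return [
        {
            "rank": i,
            "ref_his1": t.ref_positions[0],
            "ref_acidic": t.ref_positions[1],
            "ref_his2": t.ref_positions[2],
            "spacing": t.spacing,
            "mean_conservation": round(t.mean_conservation, 4),
        }
        for i, t in enumerate(triads, start=1)
    ]
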
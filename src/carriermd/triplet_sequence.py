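"""Carrier-fold repeat decomposition, residue triplets, sequence identity.

Mitochondrial carriers (SLC25 family) arose from an ancestral gene
triplication and carry a threefold pseudo-symmetric fold of three
paralogous two-helix repeats.  Aligning the three repeats of one
sequence maps every alignment column onto a *triplet* of paralogous
residues, one per repeat.  Triplets are named by the one-letter codes of
the three members followed by the residue number of the first-repeat
member — e.g. ``FIW88`` for F88/I187/W281 — and are *symmetric* when all
three members are identical (e.g. ``RRR84``).

The module also computes pairwise percent identity between sequences of
a multiple alignment, with a configurable denominator (co-ungapped
columns by default).
"""

from __future__ import annotations

import re
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import AlignIO, SeqIO

from .errors import AnalysisError

__all__ = [
    "RepeatAlignment",
    "TripletColumn",
    "TripletMap",
    "IdentityResult",
    "map_triplets",
    "pairwise_identity",
    "parse_triplet_label",
    "read_alignment",
    "read_sequences",
    "align_repeats_mafft",
]

_GAPS = "-."


def _degap(s: str) -> str:
    return s.replace("-", "").replace(".", "")


def read_alignment(path: str | Path):
    """Read an aligned FASTA file into a Biopython MultipleSeqAlignment."""
    return AlignIO.read(str(path), "fasta")


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Repeat alignment and triplet mapping
# ---------------------------------------------------------------------------

@dataclass
class RepeatAlignment:
    """Three repeat intervals of one sequence plus their mutual alignment.

    ``boundaries`` are 1-based inclusive (start, end) residue-number
    intervals, ordered and non-overlapping.  ``rows`` are the three
    aligned repeat subsequences (equal length, gap characters allowed);
    each row degapped must equal the corresponding slice of the parent
    sequence.  ``column_residues(col)`` maps an alignment column to the
    residue number in each repeat, or ``None`` at a gap.
    """

    sequence: str
    boundaries: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    rows: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.boundaries) != 3 or len(self.rows) != 3:
            raise AnalysisError("exactly three repeats are required")
        prev_end = 0
        for start, end in self.boundaries:
            if not (1 <= start <= end <= len(self.sequence)):
                raise AnalysisError(
                    f"repeat interval ({start}, {end}) outside sequence "
                    f"of length {len(self.sequence)}")
            if start <= prev_end:
                raise AnalysisError("repeat intervals must be ordered and "
                                    "non-overlapping")
            prev_end = end
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise AnalysisError("aligned repeat rows differ in length")
        for r, ((start, end), row) in enumerate(zip(self.boundaries, self.rows)):
            expected = self.sequence[start - 1:end]
            got = _degap(row)
            if got != expected:
                pos = next((i for i, (a, b) in enumerate(zip(got, expected))
                            if a != b), min(len(got), len(expected)))
                raise AnalysisError(
                    f"repeat {r + 1} alignment row does not match the "
                    f"sequence slice {start}-{end}: first discrepancy at "
                    f"repeat position {pos + 1} "
                    f"({got[pos:pos+1] or '∅'} vs {expected[pos:pos+1] or '∅'})")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def column_residues(self, column: int) -> list[tuple[int, str] | None]:
        """(residue number, one-letter code) per repeat at a column."""
        out: list[tuple[int, str] | None] = []
        for (start, _end), row in zip(self.boundaries, self.rows):
            if row[column] in _GAPS:
                out.append(None)
            else:
                offset = sum(1 for ch in row[:column] if ch not in _GAPS)
                out.append((start + offset, row[column]))
        return out


@dataclass(frozen=True)
class TripletColumn:
    """One fully ungapped alignment column: a residue triplet."""

    label: str                              # e.g. "FIW88"
    members: tuple[tuple[int, str], ...]    # ((88,'F'), (187,'I'), (281,'W'))
    symmetric: bool
    column: int

    @staticmethod
    def from_members(members: Sequence[tuple[int, str]],
                     column: int) -> "TripletColumn":
        codes = "".join(code for _num, code in members)
        label = f"{codes}{members[0][0]}"
        return TripletColumn(label=label, members=tuple(members),
                             symmetric=len(set(codes)) == 1, column=column)


@dataclass
class TripletMap:
    """All triplets of a repeat alignment plus incomplete (gapped) columns."""

    triplets: list[TripletColumn]
    incomplete_columns: list[int]

    def by_first_repeat_residue(self, resid: int) -> TripletColumn:
        for t in self.triplets:
            if t.members[0][0] == resid:
                return t
        raise KeyError(f"no complete triplet has first-repeat residue {resid}")

    def by_label(self, label: str) -> TripletColumn:
        for t in self.triplets:
            if t.label == label:
                return t
        raise KeyError(label)


def map_triplets(sequence: str,
                 boundaries: Sequence[tuple[int, int]],
                 rows: Sequence[str]) -> TripletMap:
    """Map every column of a 3-repeat alignment onto residue triplets.

    Fully ungapped columns become :class:`TripletColumn` entries named by
    the convention "one-letter codes + first-repeat residue number";
    columns with a gap in any repeat are reported as incomplete.
    """
    ra = RepeatAlignment(sequence=sequence,
                         boundaries=tuple(boundaries),  # type: ignore[arg-type]
                         rows=tuple(rows))              # type: ignore[arg-type]
    triplets: list[TripletColumn] = []
    incomplete: list[int] = []
    for col in range(ra.width):
        members = ra.column_residues(col)
        if any(m is None for m in members):
            incomplete.append(col)
        else:
            triplets.append(TripletColumn.from_members(
                [m for m in members if m is not None], col))
    return TripletMap(triplets=triplets, incomplete_columns=incomplete)


def parse_triplet_label(label: str) -> tuple[str, int]:
    """Split a triplet label into its codes and first-repeat number.

    ``parse_triplet_label("FIW88") == ("FIW", 88)``; round-trips with
    :meth:`TripletColumn.from_members`.
    """
    m = re.fullmatch(r"([A-Za-z]{3})(\d+)", label)
    if not m:
        raise ValueError(f"malformed triplet label {label!r}")
    return m.group(1), int(m.group(2))


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentityResult:
    """Percent identity between two rows of a multiple alignment."""

    seq_a: str
    seq_b: str
    columns_considered: int
    identical_columns: int
    percent_identity: int   # integer-rounded, 0–100


def pairwise_identity(alignment, seq_a: str, seq_b: str,
                      denominator: str = "co_ungapped") -> IdentityResult:
    """Percent identity of two sequences in a multiple alignment.

    ``denominator`` selects what identical columns are divided by:
    ``"co_ungapped"`` (columns where both sequences have a residue; the
    default), ``"alignment_length"``, or ``"shorter"`` (the shorter
    ungapped sequence length).  The result is rounded to the nearest
    integer percent and symmetric in the pair.
    """
    rows = {rec.id: str(rec.seq).upper() for rec in alignment}
    for sid in (seq_a, seq_b):
        if sid not in rows:
            raise AnalysisError(f"sequence {sid!r} not found in alignment "
                                f"(have {sorted(rows)})")
    a, b = rows[seq_a], rows[seq_b]
    if len(a) != len(b):
        raise AnalysisError("aligned sequences differ in length")
    both = [(x, y) for x, y in zip(a, b) if x not in _GAPS and y not in _GAPS]
    identical = sum(1 for x, y in both if x == y)
    if denominator == "co_ungapped":
        denom = len(both)
    elif denominator == "alignment_length":
        denom = len(a)
    elif denominator == "shorter":
        denom = min(len(_degap(a)), len(_degap(b)))
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    if denom == 0:
        raise AnalysisError(
            f"sequences {seq_a!r} and {seq_b!r} share no co-ungapped "
            "columns; identity is undefined")
    return IdentityResult(seq_a=seq_a, seq_b=seq_b,
                          columns_considered=denom,
                          identical_columns=identical,
                          percent_identity=round(100.0 * identical / denom))


# ---------------------------------------------------------------------------
# Optional external alignment of the three repeats
# ---------------------------------------------------------------------------

def align_repeats_mafft(sequence: str,
                        boundaries: Sequence[tuple[int, int]],
                        mafft_exe: str = "mafft") -> tuple[str, str, str]:
    """Align the three repeat subsequences with MAFFT (external tool).

    Convenience only: the core :func:`map_triplets` accepts any
    precomputed repeat alignment, so manual adjustments (e.g. moving a
    single-gap placement chosen on structural grounds) can be supplied
    as input rather than decided here.
    """
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "repeats.fasta"
        with open(fasta, "w") as fh:
            for i, (start, end) in enumerate(boundaries, start=1):
                fh.write(f">repeat{i}\n{sequence[start - 1:end]}\n")
        proc = subprocess.run([mafft_exe, "--auto", str(fasta)],
                              capture_output=True, text=True, check=True)
    rows: list[str] = []
    current: list[str] = []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if current:
                rows.append("".join(current))
                current = []
        else:
            current.append(line.strip())
    if current:
        rows.append("".join(current))
    if len(rows) != 3:
        raise AnalysisError(f"expected 3 aligned repeats, got {len(rows)}")
    return rows[0].upper(), rows[1].upper(), rows[2].upper()
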
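"""Pairwise global alignment, alignment coordinate maps and percent identity.

Positional machinery for every downstream stage: affine-gap global
(Needleman-Wunsch) alignment of proteins and cDNAs, bidirectional
residue <-> column maps over alignments (including imported multiple
alignments), and pairwise percent identity.

Multiple sequence alignments are imported from aligned FASTA, never
computed here; only pairwise alignment is implemented.  Protein scoring
defaults to BLOSUM62 with affine gaps (open 11, extend 1).  The
upstream analyses this package reproduces used MAFFT with BLOSUM62,
gap penalty 1.53 and offset 0.123; those values are recorded in
configuration provenance but the internal pairwise aligner uses the
standard affine scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "Alignment",
    "AlignmentMap",
    "global_align",
    "global_align_nt",
    "percent_identity",
    "build_alignment_map",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "load_substitution_matrix",
]

_AA_OK = set("ACDEFGHIKLMNPQRSTVWYX")
_NT_OK = set("ACGTUN")


@dataclass
class Alignment:
    """A gapped alignment: rows of (id, gapped string) plus an optional score.

    All gapped strings have equal length, and removing the gaps from any
    row reproduces the input sequence for that row.
    """

    rows: list[tuple[str, str]]
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        width = len(self.rows[0][1])
        for rid, gapped in self.rows:
            if len(gapped) != width:
                raise ValueError(f"row {rid!r} has length {len(gapped)}, expected {width}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def row(self, row_id: str) -> str:
        for rid, gapped in self.rows:
            if rid == row_id:
                return gapped
        raise KeyError(f"no alignment row with id {row_id!r}")

    def degapped(self, row_id: str) -> str:
        return self.row(row_id).replace("-", "")

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]


@dataclass
class AlignmentMap:
    """Bidirectional residue <-> column maps for every row of an alignment.

    ``seq_to_col[row][i]`` is the column holding residue ``i``;
    ``col_to_seq[row][c]`` is the residue at column ``c`` or ``None`` for
    a gap.  Both directions are strictly increasing over their domains.
    """

    seq_to_col: dict[str, list[int]]
    col_to_seq: dict[str, list[int | None]]

    def residue_column(self, row_id: str, residue_index: int) -> int:
        return self.seq_to_col[row_id][residue_index]

    def column_residue(self, row_id: str, column: int) -> int | None:
        return self.col_to_seq[row_id][column]


def load_substitution_matrix(name_or_path: str) -> substitution_matrices.Array:
    """Load a substitution matrix by name (e.g. BLOSUM62) or NCBI-format file."""
    try:
        return substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        with open(name_or_path) as fh:
            return substitution_matrices.read(fh)


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # Affine convention: a gap of length k costs gap_open + k * gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _pairwise(a: str, b: str, aligner: Align.PairwiseAligner,
              ids: tuple[str, str]) -> Alignment:
    result = aligner.align(a, b)
    best = result[0]  # deterministic: Biopython's canonical traceback order
    return Alignment(rows=[(ids[0], str(best[0])), (ids[1], str(best[1]))],
                     score=float(best.score))


def global_align(a: str, b: str, matrix: str = "BLOSUM62",
                 gap_open: float = 11.0, gap_extend: float = 1.0,
                 ids: tuple[str, str] = ("a", "b")) -> Alignment:
    """Optimal affine-gap global alignment of two protein sequences.

    Raises on empty input or on characters outside the 20 amino acids
    plus X.  The returned alignment is deterministic for a given input.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    for name, seq in (("a", a), ("b", b)):
        bad = set(seq) - _AA_OK
        if bad:
            raise ValueError(f"sequence {name} contains non-amino-acid characters {sorted(bad)}")
    return _pairwise(a, b, _make_aligner(load_substitution_matrix(matrix), gap_open, gap_extend), ids)


def global_align_nt(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
                    gap_open: float = 10.0, gap_extend: float = 0.5,
                    ids: tuple[str, str] = ("a", "b")) -> Alignment:
    """Affine-gap global alignment of two nucleotide sequences."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    for name, seq in (("a", a), ("b", b)):
        bad = set(seq) - _NT_OK
        if bad:
            raise ValueError(f"sequence {name} contains non-nucleotide characters {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    result = aligner.align(a, b)
    best = result[0]
    return Alignment(rows=[(ids[0], str(best[0])), (ids[1], str(best[1]))],
                     score=float(best.score))


def _pair_identity(r1: str, r2: str, mode: str) -> float:
    start = max(_first_nongap(r1), _first_nongap(r2))
    end = min(_last_nongap(r1), _last_nongap(r2)) + 1
    if end <= start:
        raise ValueError("zero-length overlap between alignment rows")
    matches = 0
    aligned_pairs = 0
    for c in range(start, end):
        x, y = r1[c], r2[c]
        if x != "-" and y != "-":
            aligned_pairs += 1
            if x == y:
                matches += 1
    if mode == "aligned_columns":
        denom = end - start
    elif mode == "ungapped_pairs":
        denom = aligned_pairs
    else:
        raise ValueError(f"unknown percent-identity mode {mode!r}")
    if denom == 0:
        raise ValueError("zero-length overlap between alignment rows")
    return 100.0 * matches / denom


def _first_nongap(row: str) -> int:
    for i, ch in enumerate(row):
        if ch != "-":
            return i
    raise ValueError("all-gap alignment row")


def _last_nongap(row: str) -> int:
    for i in range(len(row) - 1, -1, -1):
        if row[i] != "-":
            return i
    raise ValueError("all-gap alignment row")


def percent_identity(aln: Alignment, mode: str = "aligned_columns") -> float:
    """Percent identity over an alignment.

    ``mode="aligned_columns"`` (default) divides identical non-gap column
    pairs by the number of columns excluding terminal-gap columns;
    ``mode="ungapped_pairs"`` divides by columns where both rows have a
    residue.  With more than two rows the mean over all row pairs is
    returned.
    """
    if len(aln.rows) < 2:
        raise ValueError("percent identity needs at least 2 alignment rows")
    values = []
    for i in range(len(aln.rows)):
        for j in range(i + 1, len(aln.rows)):
            values.append(_pair_identity(aln.rows[i][1], aln.rows[j][1], mode))
    return sum(values) / len(values)


def build_alignment_map(aln: Alignment) -> AlignmentMap:
    """Build bidirectional residue <-> column maps for every row."""
    seq_to_col: dict[str, list[int]] = {}
    col_to_seq: dict[str, list[int | None]] = {}
    for rid, gapped in aln.rows:
        s2c: list[int] = []
        c2s: list[int | None] = []
        residue = 0
        for col, ch in enumerate(gapped):
            if ch == "-":
                c2s.append(None)
            else:
                s2c.append(col)
                c2s.append(residue)
                residue += 1
        seq_to_col[rid] = s2c
        col_to_seq[rid] = c2s
    return AlignmentMap(seq_to_col=seq_to_col, col_to_seq=col_to_seq)


def read_aligned_fasta(path: str | Path) -> Alignment:
    """Read a multiple alignment from aligned (gapped) FASTA."""
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"no alignment rows found in {path}")
    return Alignment(rows=rows)


def write_aligned_fasta(aln: Alignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, gapped in aln.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(gapped), width):
                fh.write(gapped[i : i + width] + "\n")
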
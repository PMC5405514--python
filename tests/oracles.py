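"""Independent brute-force oracles used to verify the fast implementations.

These deliberately share no code with the package: alignment scores come
from exhaustive enumeration of every global alignment, and coordinate
maps from a linear scan.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62_score(x: str, y: str) -> float:
    return float(_BLOSUM62[x, y])


def bruteforce_global_score(a: str, b: str, score_fn=blosum62_score,
                            gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal affine-gap global alignment score by exhaustive enumeration.

    A gap of length k costs gap_open + k * gap_extend.  Feasible for
    sequences up to length ~8.
    """
    best = float("-inf")
    la, lb = len(a), len(b)

    def rec(i: int, j: int, prev: str | None, acc: float) -> None:
        nonlocal best
        if i == la and j == lb:
            if acc > best:
                best = acc
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, "M", acc + score_fn(a[i], b[j]))
        if i < la:
            cost = gap_extend if prev == "D" else gap_open + gap_extend
            rec(i + 1, j, "D", acc - cost)
        if j < lb:
            cost = gap_extend if prev == "I" else gap_open + gap_extend
            rec(i, j + 1, "I", acc - cost)

    rec(0, 0, None, 0.0)
    return best


def scan_map(gapped: str) -> tuple[list[int], list[int | None]]:
    """Residue<->column maps by a direct linear scan of one gapped row."""
    seq_to_col: list[int] = []
    col_to_seq: list[int | None] = []
    k = 0
    for col, ch in enumerate(gapped):
        if ch == "-":
            col_to_seq.append(None)
        else:
            seq_to_col.append(col)
            col_to_seq.append(k)
            k += 1
    return seq_to_col, col_to_seq
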
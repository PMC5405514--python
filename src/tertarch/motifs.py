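"""Motif annotation transfer, conservation profiles and conserved-block mining.

Canonical telomerase reverse transcriptase (TERT) motifs -- GQ in the
TEN domain; CP, QFP and T in the TRBD; 1, 2, A, B', C, D and E in the RT
domain -- are defined as residue intervals on a reference protein and
transferred to every other row of a multiple alignment by regional
comparison: a target's coverage of the reference motif columns decides
whether the motif is called present, partial or absent.  Two further
regions are derived rather than annotated: the N-terminal linker (between
GQ and CP) and the C-terminal extension (CTE, after motif E).

Column-wise conservation profiles (frequency of the modal residue) and a
scanner for lineage-restricted conserved blocks -- maximal runs of
columns nearly fixed within a clade but variable outside it, emitted as
degenerate consensus strings like ``(I/V)QQRVxLQF`` -- complete the
module.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .alignment import Alignment, build_alignment_map

__all__ = [
    "MotifDefinition",
    "MotifCall",
    "ProfileColumn",
    "ConservedBlock",
    "CANONICAL_MOTIFS",
    "TRBD_MOTIFS",
    "RT_MOTIFS",
    "load_motif_definitions",
    "packaged_motif_definitions",
    "derive_regions",
    "transfer_motifs",
    "conservation_profile",
    "find_conserved_blocks",
]

CANONICAL_MOTIFS = ("GQ", "CP", "QFP", "T", "1", "2", "A", "Bprime", "C", "D", "E")
TRBD_MOTIFS = ("CP", "QFP", "T")
RT_MOTIFS = ("1", "2", "A", "Bprime", "C", "D", "E")

_NAME_ALIASES = {"B'": "Bprime", "B′": "Bprime", "Bp": "Bprime"}


@dataclass(frozen=True)
class MotifDefinition:
    """A named motif interval on a reference protein (0-based half-open)."""

    name: str
    reference_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid motif interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MotifCall:
    """A transferred motif's presence status in one target sequence.

    ``coverage`` is the fraction of reference motif columns aligned to a
    target residue; ``target_interval`` is the smallest residue range on
    the target spanning those aligned positions (``None`` iff coverage
    is zero).
    """

    motif: str
    status: str
    coverage: float
    target_interval: tuple[int, int] | None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if (self.target_interval is None) != (self.coverage == 0.0):
            raise ValueError("target_interval must be None iff coverage == 0")


@dataclass(frozen=True)
class ProfileColumn:
    column: int
    consensus_residue: str
    frequency: float


@dataclass
class ConservedBlock:
    """A clade-restricted run of conserved columns with a degenerate consensus."""

    clade: str
    col_start: int
    col_end: int
    consensus: str
    mean_frequency: float


def _canonical_name(name: str) -> str:
    return _NAME_ALIASES.get(name, name)


def load_motif_definitions(path: str | Path) -> tuple[str, int, list[MotifDefinition]]:
    """Load motif definitions from a JSON config.

    Schema: ``{"reference_id": ..., "reference_length": ..., "motifs":
    {name: [start, end], ...}}`` with 0-based half-open residue
    intervals.  Returns (reference_id, reference_length, definitions).
    """
    with open(path) as fh:
        doc = json.load(fh)
    ref_id = doc["reference_id"]
    ref_len = int(doc["reference_length"])
    defs = []
    for name, (s, e) in doc["motifs"].items():
        if e > ref_len:
            raise ValueError(f"motif {name!r} interval [{s},{e}) outside reference length {ref_len}")
        defs.append(MotifDefinition(name=_canonical_name(name), reference_id=ref_id,
                                    start=int(s), end=int(e)))
    return ref_id, ref_len, defs


def packaged_motif_definitions(reference: str = "hTERT") -> tuple[str, int, list[MotifDefinition]]:
    """Load one of the packaged reference motif coordinate sets.

    ``reference`` is ``"hTERT"`` or ``"celegans"``.  The packaged
    intervals are approximate, literature-derived fixtures the user may
    override with their own JSON config.
    """
    fname = {"hTERT": "htert_motifs.json", "celegans": "celegans_tert_motifs.json"}[reference]
    with resources.files("tertarch.data").joinpath(fname).open() as fh:
        doc = json.load(fh)
    ref_id = doc["reference_id"]
    ref_len = int(doc["reference_length"])
    defs = [MotifDefinition(name=_canonical_name(n), reference_id=ref_id, start=s, end=e)
            for n, (s, e) in doc["motifs"].items()]
    return ref_id, ref_len, defs


def derive_regions(defs: list[MotifDefinition], reference_length: int) -> list[MotifDefinition]:
    """Add the derived linker (GQ end -> CP start) and CTE (E end -> C terminus).

    Returns a new list; regions whose anchors are missing, or already
    present, are left alone.
    """
    by_name = {d.name: d for d in defs}
    out = list(defs)
    ref_id = defs[0].reference_id if defs else ""
    if "linker" not in by_name and "GQ" in by_name and "CP" in by_name:
        if by_name["GQ"].end < by_name["CP"].start:
            out.append(MotifDefinition("linker", ref_id, by_name["GQ"].end, by_name["CP"].start))
    if "CTE" not in by_name and "E" in by_name and by_name["E"].end < reference_length:
        out.append(MotifDefinition("CTE", ref_id, by_name["E"].end, reference_length))
    return out


def _check_nonoverlap(defs: list[MotifDefinition]) -> None:
    # DAT is allowed to nest inside GQ; linker/CTE are derived flanks.
    core = sorted((d for d in defs if d.name not in ("DAT", "linker", "CTE")),
                  key=lambda d: d.start)
    for d1, d2 in zip(core, core[1:]):
        if d2.start < d1.end:
            raise ValueError(f"motifs {d1.name} and {d2.name} overlap on the reference")


def transfer_motifs(
    aln: Alignment,
    defs: list[MotifDefinition],
    present_min: float = 0.70,
    partial_min: float = 0.20,
) -> dict[str, list[MotifCall]]:
    """Transfer reference motif intervals to every other alignment row.

    The reference row is the one whose id matches ``defs[0].reference_id``
    and must degap to a sequence at least as long as the largest motif
    end.  For each target and motif, coverage is the fraction of the
    motif's reference columns aligned to a target residue; status is
    ``present`` if coverage >= ``present_min``, ``partial`` if
    >= ``partial_min``, else ``absent``.
    """
    if not defs:
        raise ValueError("no motif definitions supplied")
    _check_nonoverlap(defs)
    ref_id = defs[0].reference_id
    ref_seq = aln.degapped(ref_id)  # KeyError if the reference row is missing
    for d in defs:
        if d.end > len(ref_seq):
            raise ValueError(
                f"motif {d.name!r} interval [{d.start},{d.end}) outside reference of length {len(ref_seq)}"
            )
    amap = build_alignment_map(aln)
    motif_cols = {d.name: [amap.residue_column(ref_id, r) for r in range(d.start, d.end)]
                  for d in defs}
    out: dict[str, list[MotifCall]] = {}
    for rid, _ in aln.rows:
        if rid == ref_id:
            continue
        calls = []
        for d in defs:
            hits = [amap.column_residue(rid, c) for c in motif_cols[d.name]]
            hits = [h for h in hits if h is not None]
            coverage = len(hits) / d.length
            if coverage >= present_min:
                status = "present"
            elif coverage >= partial_min:
                status = "partial"
            else:
                status = "absent"
            interval = (min(hits), max(hits) + 1) if hits else None
            calls.append(MotifCall(motif=d.name, status=status, coverage=coverage,
                                   target_interval=interval))
        out[rid] = calls
    return out


def conservation_profile(aln: Alignment, region: tuple[int, int] | None = None) -> list[ProfileColumn]:
    """Column-wise frequency of the modal non-gap residue.

    ``region`` is a half-open column range (default: whole alignment).
    All-gap columns are dropped; gaps are excluded from denominators.
    Modal ties break alphabetically for determinism.
    """
    if len(aln.rows) < 2:
        raise ValueError("conservation profile needs at least 2 rows")
    c0, c1 = region if region is not None else (0, aln.n_columns)
    if not 0 <= c0 < c1 <= aln.n_columns:
        raise ValueError(f"empty or invalid column region [{c0}, {c1})")
    out = []
    for c in range(c0, c1):
        residues = [gapped[c] for _, gapped in aln.rows if gapped[c] != "-"]
        if not residues:
            continue
        counts = Counter(residues)
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
        out.append(ProfileColumn(column=c, consensus_residue=best[0],
                                 frequency=best[1] / len(residues)))
    return out


def _column_state(residues: list[str], n_members: int, f_within: float,
                  max_states: int) -> tuple[bool, str, float]:
    """Within-clade pass test for one column.

    Gaps count against coverage (a clade member with a gap does not
    support the block).  Returns (passes, consensus token, coverage).
    """
    counts = Counter(r for r in residues if r != "-")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for k in range(1, max_states + 1):
        top = ranked[:k]
        covered = sum(n for _, n in top)
        if covered / n_members >= f_within:
            if k == 1:
                token = top[0][0]
            else:
                token = "(" + "/".join(r for r, _ in top) + ")"
            return True, token, covered / n_members
    return False, "x", (ranked[0][1] / n_members) if ranked else 0.0


def find_conserved_blocks(
    aln: Alignment,
    clade_labels: dict[str, str],
    clade: str,
    f_within: float = 0.8,
    max_states: int = 2,
    min_block_length: int = 4,
    f_background_max: float = 0.5,
) -> list[ConservedBlock]:
    """Mine clade-restricted conserved blocks from a labelled alignment.

    A block is a maximal run of columns where, within the clade, at most
    ``max_states`` residues jointly cover >= ``f_within`` of members
    (rendered as a single letter or ``(A/B)``), while the modal residue
    frequency outside the clade stays below ``f_background_max``.
    Columns failing the within-clade test inside a run are rendered
    ``x`` when flanked by at least 2 passing columns on each side; runs
    shorter than ``min_block_length`` are discarded.  Output is
    deterministic, non-overlapping and sorted by column.
    """
    clade_rows = [g for rid, g in aln.rows if clade_labels.get(rid) == clade]
    other_rows = [g for rid, g in aln.rows
                  if rid in clade_labels and clade_labels[rid] != clade]
    if len(clade_rows) < 3:
        raise ValueError(f"clade {clade!r} has fewer than 3 labelled members")
    n = aln.n_columns
    passes: list[bool] = []
    tokens: list[str] = []
    freqs: list[float] = []
    for c in range(n):
        ok, token, freq = _column_state([row[c] for row in clade_rows],
                                        len(clade_rows), f_within, max_states)
        if ok and other_rows:
            bg = [row[c] for row in other_rows if row[c] != "-"]
            if bg:
                bg_modal = max(Counter(bg).values()) / len(other_rows)
                if bg_modal >= f_background_max:
                    ok, token = False, "x"
        passes.append(ok)
        tokens.append(token)
        freqs.append(freq)

    blocks: list[ConservedBlock] = []
    c = 0
    while c < n:
        if not passes[c]:
            c += 1
            continue
        # Extend a run: failing columns are bridged only when the 2 columns on
        # each side (inside the run) pass.
        end = c
        j = c
        while j < n:
            if passes[j]:
                end = j
                j += 1
            else:
                left_ok = j >= c + 2 and passes[j - 1] and passes[j - 2]
                right_ok = j + 2 < n and passes[j + 1] and passes[j + 2]
                if left_ok and right_ok:
                    j += 1
                else:
                    break
        if end - c + 1 >= min_block_length:
            run_tokens = [tokens[k] if passes[k] else "x" for k in range(c, end + 1)]
            run_freqs = [freqs[k] for k in range(c, end + 1) if passes[k]]
            blocks.append(ConservedBlock(
                clade=clade, col_start=c, col_end=end + 1,
                consensus="".join(run_tokens),
                mean_frequency=sum(run_freqs) / len(run_freqs),
            ))
        c = end + 1
    return blocks
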
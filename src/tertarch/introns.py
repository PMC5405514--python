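"""Intron-position projection and cross-species conservation calls.

An intron's transcript-space boundary is projected into protein
coordinates (the 0-based index of the codon containing, or immediately
following, the boundary, plus the codon phase) and then mapped through a
pairwise alignment with a reference species.  A query intron whose
hosting residue shares an alignment column with a reference intron is
called *conserved*; otherwise it is *species-specific*.  Human TERT,
with its 15 introns, is the canonical reference for the analyses this
package was built around, but any reference works.

Phase convention: phase is the number of nucleotides of the interrupted
codon lying 5' of the intron (0, 1 or 2).  The hosting residue of a
phase-0 boundary is the residue immediately after the boundary, which
keeps ``residue_index = (boundary - cds_start) // 3`` uniform across
phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .alignment import Alignment, build_alignment_map
from .gene_models import TranscriptModel

__all__ = [
    "IntronPosition",
    "IntronComparison",
    "project_introns",
    "utr_boundaries",
    "classify_introns",
    "conservation_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntronPosition:
    """An intron boundary in transcript-nt, protein-residue and phase coordinates."""

    transcript_nt: int
    residue_index: int
    phase: int

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase}")


@dataclass
class IntronComparison:
    """One query intron's conservation status relative to a reference."""

    query_intron: IntronPosition
    ref_column: int | None
    matched_ref_intron: IntronPosition | None
    status: str

    def __post_init__(self) -> None:
        conserved = self.matched_ref_intron is not None
        if self.status != ("conserved" if conserved else "species_specific"):
            raise ValueError("status inconsistent with matched_ref_intron")


def project_introns(t: TranscriptModel) -> list[IntronPosition]:
    """Project each exon boundary inside the CDS into protein coordinates.

    Boundaries in UTRs are excluded (see :func:`utr_boundaries`), as are
    boundaries falling in a trailing partial codon.
    """
    out = []
    n_residues = (t.cds_end_nt - t.cds_start_nt) // 3
    for b in t.exon_boundaries_nt:
        if not t.cds_start_nt <= b < t.cds_end_nt:
            continue
        rel = b - t.cds_start_nt
        residue, phase = divmod(rel, 3)
        if residue >= n_residues:  # boundary inside dropped trailing partial codon
            continue
        out.append(IntronPosition(transcript_nt=b, residue_index=residue, phase=phase))
    return out


def utr_boundaries(t: TranscriptModel) -> list[int]:
    """Exon boundaries lying in the 5' or 3' UTR, reported separately."""
    return [b for b in t.exon_boundaries_nt
            if not t.cds_start_nt <= b < t.cds_end_nt]


def classify_introns(
    query: tuple[str, list[IntronPosition]],
    reference: tuple[str, list[IntronPosition]],
    aln: Alignment,
    tolerance_columns: int = 0,
    require_phase: bool = False,
) -> list[IntronComparison]:
    """Classify each query intron as conserved or species-specific.

    ``query`` and ``reference`` are (protein, introns) pairs; ``aln`` is
    a two-row alignment whose first row degaps to the query protein and
    second row to the reference protein.  A query intron is conserved
    iff some reference intron's hosting residue maps to an alignment
    column within ``tolerance_columns`` of the query intron's column
    (phases must also match when ``require_phase``).  Each reference
    intron matches at most one query intron; matching is greedy from the
    5' end with ties broken toward the 5'-most reference intron.
    """
    if tolerance_columns < 0:
        raise ValueError("tolerance_columns must be >= 0")
    q_protein, q_introns = query
    r_protein, r_introns = reference
    (q_id, q_row), (r_id, r_row) = aln.rows[0], aln.rows[1]
    if aln.degapped(q_id) != q_protein:
        raise ValueError("first alignment row does not degap to the query protein")
    if aln.degapped(r_id) != r_protein:
        raise ValueError("second alignment row does not degap to the reference protein")
    amap = build_alignment_map(aln)

    def host_column(row_id: str, protein: str, ip: IntronPosition) -> int | None:
        if ip.residue_index >= len(protein):
            return None  # boundary beyond translated region (partial sequence)
        col = amap.residue_column(row_id, ip.residue_index)
        assert amap.column_residue(row_id, col) is not None
        return col

    ref_cols = [(host_column(r_id, r_protein, ip), ip) for ip in r_introns]
    ref_cols = sorted(((c, ip) for c, ip in ref_cols if c is not None),
                      key=lambda t: t[0])
    taken: set[int] = set()
    out: list[IntronComparison] = []
    for q_ip in sorted(q_introns, key=lambda ip: ip.transcript_nt):
        q_col = host_column(q_id, q_protein, q_ip)
        if q_col is None:
            out.append(IntronComparison(q_ip, None, None, "species_specific"))
            continue
        best: tuple[int, int] | None = None  # (distance, ref index)
        for k, (r_col, r_ip) in enumerate(ref_cols):
            if k in taken:
                continue
            d = abs(r_col - q_col)
            if d > tolerance_columns:
                continue
            if require_phase and r_ip.phase != q_ip.phase:
                continue
            if best is None or d < best[0]:
                best = (d, k)  # ties keep the earlier (5'-most) reference intron
        if best is None:
            out.append(IntronComparison(q_ip, q_col, None, "species_specific"))
        else:
            taken.add(best[1])
            out.append(IntronComparison(q_ip, q_col, ref_cols[best[1]][1], "conserved"))
    return out


def conservation_table(
    species_set: dict[str, tuple[str, list[IntronPosition], Alignment | None]],
    reference: tuple[str, list[IntronPosition]],
    tolerance_columns: int = 0,
    require_phase: bool = False,
) -> pd.DataFrame:
    """Per-species intron conservation tally against one reference.

    ``species_set`` maps species name to (protein, introns, pairwise
    alignment to the reference); a species with no alignment is skipped
    with a logged warning.  ``matched_ref_ranks`` lists the 1-based ranks
    of the reference introns matched by that species (1..15 for human
    TERT).
    """
    r_protein, r_introns = reference
    rank_of = {ip: k + 1 for k, ip in
               enumerate(sorted(r_introns, key=lambda ip: ip.transcript_nt))}
    rows = []
    for species, (protein, introns, aln) in species_set.items():
        if aln is None:
            logger.warning("species %s has no alignment to the reference; skipped", species)
            continue
        comps = classify_introns((protein, introns), reference, aln,
                                 tolerance_columns=tolerance_columns,
                                 require_phase=require_phase)
        n_cons = sum(c.status == "conserved" for c in comps)
        ranks = sorted(rank_of[c.matched_ref_intron] for c in comps
                       if c.matched_ref_intron is not None)
        rows.append({
            "species": species,
            "n_introns": len(comps),
            "n_conserved": n_cons,
            "n_specific": len(comps) - n_cons,
            "matched_ref_ranks": ",".join(map(str, ranks)),
        })
    return pd.DataFrame(rows, columns=["species", "n_introns", "n_conserved",
                                       "n_specific", "matched_ref_ranks"])
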
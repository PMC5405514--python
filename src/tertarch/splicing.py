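"""Structural classification of alternative-splice variants.

Variant cDNAs are mapped onto the full-length reference transcript
("isoform 1") by global nucleotide alignment; maximal gap runs become
deletion or insertion segments, and each segment is classified as an
exon-skipping event (deletion bounded by annotated exon boundaries), an
intron retention (insertion matching an adjacent genomic intron) or a
splice-site mutation (everything else; when no genomic intron sequence
is available a boundary-adjacent insertion is flagged as a possible
retention instead).  Each variant is then translated in the reference
reading frame, checked for a premature termination codon, and its motif
complement re-called by alignment to the reference protein, from which
the TRBD and RT domain statuses (intact / truncated / missing) derive.

Exon ranks are 1-based throughout the reports, so "deletion of exons
8 to 10" reads exactly as in the comparative literature this package
mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .alignment import Alignment, build_alignment_map, global_align, global_align_nt, percent_identity
from .gene_models import OrfReport, TranscriptModel, translate_cds
from .introns import IntronPosition, project_introns
from .motifs import MotifDefinition, RT_MOTIFS, TRBD_MOTIFS, transfer_motifs

__all__ = [
    "SpliceVariant",
    "IndelSegment",
    "SpliceEvent",
    "VariantAnnotation",
    "map_variant",
    "classify_events",
    "infer_boundaries_by_projection",
    "annotate_variant",
    "derive_domain_status",
    "summarize_variants",
]


@dataclass
class SpliceVariant:
    """A variant cDNA (or protein) tied to its species' isoform 1."""

    id: str
    species: str
    seq: str
    reference_id: str
    moltype: str = "nt"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for variant {self.id!r}")
        if self.moltype not in ("nt", "aa"):
            raise ValueError("moltype must be 'nt' or 'aa'")


@dataclass
class IndelSegment:
    """One maximal gap run from the variant/reference alignment.

    Deletions carry a reference-coordinate interval; insertions carry a
    variant-coordinate interval plus the reference anchor position
    (``ref_start == ref_end``) and the inserted sequence.
    """

    kind: str  # "deletion" | "insertion"
    ref_start: int
    ref_end: int
    var_start: int
    var_end: int
    seq: str = ""

    @property
    def length(self) -> int:
        return (self.ref_end - self.ref_start) if self.kind == "deletion" \
            else (self.var_end - self.var_start)


@dataclass
class SpliceEvent:
    """A classified structural event relating a variant to isoform 1."""

    type: str  # exon_skip | intron_retention | splice_site_mutation
    segment: tuple[int, int]
    length: int
    exons: tuple[int, ...] = ()          # 1-based skipped exon ranks (exon_skip)
    intron: int | None = None            # 1-based retained intron rank
    possible_retention: bool = False     # boundary insertion, no genome available


@dataclass
class VariantAnnotation:
    """Full structural annotation of one variant."""

    variant_id: str
    species: str
    events: list[SpliceEvent]
    orf: OrfReport | None
    domain_status: dict[str, str]
    motif_status: dict[str, str]
    no_start: bool = False


def map_variant(v: SpliceVariant, ref: TranscriptModel,
                min_identity: float = 80.0,
                **align_params) -> tuple[list[IndelSegment], Alignment]:
    """Align a variant cDNA to its reference and extract indel segments.

    Raises ``ValueError`` when the identity of aligned non-gap positions
    falls below ``min_identity`` percent ("not a variant of this
    reference").  Returns the segments and the underlying alignment.
    """
    if v.moltype != "nt":
        raise ValueError("map_variant needs a nucleotide variant")
    aln = global_align_nt(ref.cdna, v.seq, ids=("ref", "var"), **align_params)
    ident = percent_identity(aln, mode="ungapped_pairs")
    if ident < min_identity:
        raise ValueError(
            f"{v.id}: {ident:.1f}% identity to {ref.transcript_id}; not a variant of this reference"
        )
    ref_row, var_row = aln.row("ref"), aln.row("var")
    segments: list[IndelSegment] = []
    ref_pos = var_pos = 0
    col = 0
    n = len(ref_row)
    while col < n:
        r, q = ref_row[col], var_row[col]
        if q == "-":  # deletion in the variant
            start_ref = ref_pos
            while col < n and var_row[col] == "-":
                ref_pos += 1
                col += 1
            segments.append(IndelSegment("deletion", start_ref, ref_pos, var_pos, var_pos))
        elif r == "-":  # insertion in the variant
            start_var = var_pos
            while col < n and ref_row[col] == "-":
                var_pos += 1
                col += 1
            segments.append(IndelSegment("insertion", ref_pos, ref_pos, start_var, var_pos,
                                         seq=v.seq[start_var:var_pos]))
        else:
            ref_pos += 1
            var_pos += 1
            col += 1
    return segments, aln


def _near(a: int, b: int, tol: int) -> bool:
    return abs(a - b) <= tol


def classify_events(segments: list[IndelSegment], ref: TranscriptModel,
                    intron_seqs: dict[int, str] | None = None,
                    tol_nt: int = 3,
                    retention_min_identity: float = 90.0) -> list[SpliceEvent]:
    """Classify each indel segment; every segment yields exactly one event.

    A deletion whose ends both fall within ``tol_nt`` of annotated exon
    boundaries is an exon skip of the enclosed exon run.  An insertion
    matching (>= ``retention_min_identity`` percent) a genomic intron
    adjacent to its site is an intron retention; ``intron_seqs`` maps
    1-based intron ranks to sequences.  Everything else falls through to
    ``splice_site_mutation``.
    """
    bounds = [0, *ref.exon_boundaries_nt, len(ref.cdna)]
    events: list[SpliceEvent] = []
    for seg in segments:
        if seg.kind == "deletion":
            i = next((k for k in range(len(bounds) - 1)
                      if _near(seg.ref_start, bounds[k], tol_nt)), None)
            j = next((k for k in range(len(bounds) - 1, 0, -1)
                      if _near(seg.ref_end, bounds[k], tol_nt)), None)
            if i is not None and j is not None and j > i:
                events.append(SpliceEvent(
                    type="exon_skip",
                    segment=(seg.ref_start, seg.ref_end),
                    length=seg.length,
                    exons=tuple(range(i + 1, j + 1)),
                ))
                continue
            events.append(SpliceEvent(type="splice_site_mutation",
                                      segment=(seg.ref_start, seg.ref_end),
                                      length=seg.length))
        else:
            at_boundary = next(
                (k for k in range(1, len(bounds) - 1) if _near(seg.ref_start, bounds[k], tol_nt)),
                None)
            if intron_seqs is not None and at_boundary is not None:
                intron_seq = intron_seqs.get(at_boundary)
                if intron_seq and _insertion_matches_intron(
                        seg.seq, intron_seq, retention_min_identity):
                    events.append(SpliceEvent(
                        type="intron_retention",
                        segment=(seg.var_start, seg.var_end),
                        length=seg.length,
                        intron=at_boundary,
                    ))
                    continue
            events.append(SpliceEvent(
                type="splice_site_mutation",
                segment=(seg.var_start, seg.var_end),
                length=seg.length,
                possible_retention=intron_seqs is None and at_boundary is not None,
            ))
    return events


def _insertion_matches_intron(ins: str, intron: str, min_identity: float) -> bool:
    if not ins or not intron:
        return False
    if abs(len(ins) - len(intron)) > max(10, 0.2 * len(intron)):
        return False
    aln = global_align_nt(ins, intron)
    return percent_identity(aln, mode="ungapped_pairs") >= min_identity


def infer_boundaries_by_projection(
    target_cdna: str,
    target_protein: str,
    target_cds_start: int,
    donor: TranscriptModel,
    donor_protein: str,
    aln: Alignment | None = None,
    transcript_id: str = "projected",
) -> tuple[TranscriptModel, list[IntronPosition]]:
    """Project a donor's exon-intron boundaries onto a related isoform 1.

    Used when a species has cloned transcripts but no genome: each donor
    intron's hosting residue is mapped through a protein alignment to a
    target residue and converted back to a target cDNA offset using the
    donor's codon phase.  Boundaries whose hosting residue aligns to a
    gap are returned as unplaced; more than 50% unplaced raises (the
    projection is unreliable).
    """
    donor_introns = project_introns(donor)
    if aln is None:
        aln = global_align(donor_protein, target_protein, ids=("donor", "target"))
    donor_id, target_id = aln.ids()[0], aln.ids()[1]
    if aln.degapped(donor_id) != donor_protein or aln.degapped(target_id) != target_protein:
        raise ValueError("alignment rows do not degap to (donor, target) proteins")
    amap = build_alignment_map(aln)
    boundaries: list[int] = []
    unplaced: list[IntronPosition] = []
    for ip in donor_introns:
        if ip.residue_index >= len(donor_protein):
            unplaced.append(ip)
            continue
        col = amap.residue_column(donor_id, ip.residue_index)
        tgt_res = amap.column_residue(target_id, col)
        if tgt_res is None:
            unplaced.append(ip)
            continue
        b = target_cds_start + 3 * tgt_res + ip.phase
        if 0 < b < len(target_cdna):
            boundaries.append(b)
        else:
            unplaced.append(ip)
    if donor_introns and len(unplaced) > len(donor_introns) / 2:
        raise ValueError(
            f"projection unreliable: {len(unplaced)}/{len(donor_introns)} boundaries unplaced"
        )
    model = TranscriptModel(
        transcript_id=transcript_id,
        cdna=target_cdna,
        exon_boundaries_nt=sorted(set(boundaries)),
        cds_start_nt=target_cds_start,
        cds_end_nt=len(target_cdna),
    )
    return model, unplaced


def derive_domain_status(motif_status: dict[str, str],
                         schema: dict[str, tuple[str, ...]] | None = None) -> dict[str, str]:
    """Derive TRBD/RT domain status from constituent motif statuses.

    A domain is ``intact`` iff all its motifs are present, ``missing``
    iff all are absent, ``truncated`` otherwise.  Motifs absent from the
    reference annotation (e.g. CP in planarians) are simply not part of
    the domain's schema.  Pure function of ``motif_status``.
    """
    if schema is None:
        schema = {
            "TRBD": tuple(m for m in TRBD_MOTIFS if m in motif_status),
            "RT": tuple(m for m in RT_MOTIFS if m in motif_status),
        }
    out = {}
    for domain, motifs in schema.items():
        statuses = [motif_status[m] for m in motifs if m in motif_status]
        if not statuses:
            out[domain] = "missing"
        elif all(s == "present" for s in statuses):
            out[domain] = "intact"
        elif all(s == "absent" for s in statuses):
            out[domain] = "missing"
        else:
            out[domain] = "truncated"
    return out


def _translate_in_reference_frame(var_cdna: str, ref: TranscriptModel,
                                  aln: Alignment) -> tuple[OrfReport | None, bool]:
    """Translate the variant from the image of the reference start codon.

    Returns (orf report, no_start).  ``no_start`` is set when the
    variant region aligned to the reference start codon is deleted.
    """
    amap = build_alignment_map(aln)
    start = None
    for ref_pos in range(ref.cds_start_nt, min(ref.cds_start_nt + 3, ref.cds_end_nt)):
        col = amap.residue_column("ref", ref_pos)
        var_pos = amap.column_residue("var", col)
        if var_pos is not None:
            start = var_pos
            break
    if start is None:
        return None, True
    sub = var_cdna[start:]
    if len(sub) < 3:
        return None, True
    t = TranscriptModel(transcript_id="variant", cdna=sub, exon_boundaries_nt=[],
                        cds_start_nt=0, cds_end_nt=len(sub))
    return translate_cds(t), False


def annotate_variant(
    v: SpliceVariant,
    ref: TranscriptModel,
    ref_protein: str,
    defs: list[MotifDefinition],
    intron_seqs: dict[int, str] | None = None,
    tol_nt: int = 3,
    present_min: float = 0.70,
    partial_min: float = 0.20,
) -> VariantAnnotation:
    """Structurally annotate one variant against its isoform-1 reference.

    Nucleotide variants get the full path (events + frame + motifs);
    protein-only variants skip nucleotide-level event typing and get
    motif/domain calls only.
    """
    ref_defs = [MotifDefinition(d.name, "ref", d.start, d.end) for d in defs]
    if v.moltype == "nt":
        segments, aln = map_variant(v, ref)
        events = classify_events(segments, ref, intron_seqs=intron_seqs, tol_nt=tol_nt)
        orf, no_start = _translate_in_reference_frame(v.seq, ref, aln)
        # no_start: the start-codon region is deleted; orf stays None and the
        # variant reports as not ORF-retained with reason "no start".
        protein = orf.protein if orf else ""
    else:
        events = []
        no_start = False
        interior = v.seq.rstrip("*")
        if "*" in interior:
            orf = OrfReport(protein=interior[: interior.index("*")],
                            ptc_residue_index=interior.index("*"), orf_retained=False)
        else:
            orf = OrfReport(protein=interior, ptc_residue_index=None, orf_retained=True)
        protein = orf.protein
    if protein:
        paln = global_align(ref_protein, protein, ids=("ref", "var"))
        calls = transfer_motifs(paln, ref_defs, present_min=present_min,
                                partial_min=partial_min)["var"]
        motif_status = {c.motif: c.status for c in calls}
    else:
        motif_status = {d.name: "absent" for d in ref_defs}
    domain_status = derive_domain_status(motif_status)
    return VariantAnnotation(
        variant_id=v.id,
        species=v.species,
        events=events,
        orf=orf,
        domain_status=domain_status,
        motif_status=motif_status,
        no_start=no_start,
    )


def summarize_variants(annotations: list[VariantAnnotation]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant report plus per-species aggregate counts.

    Returns (per-variant table, aggregate table).  Aggregate categories
    partition the variants, so counts sum to the species total.
    """
    if not annotations:
        raise ValueError("no annotations to summarize")
    rows = []
    for a in annotations:
        event_desc = ";".join(
            (f"skip_exons_{e.exons[0]}-{e.exons[-1]}" if e.type == "exon_skip"
             else f"retain_intron_{e.intron}" if e.type == "intron_retention"
             else f"M_{e.length}nt")
            for e in a.events
        )
        rows.append({
            "variant_id": a.variant_id,
            "species": a.species,
            "n_events": len(a.events),
            "events": event_desc,
            "orf_retained": a.orf.orf_retained if a.orf else False,
            "ptc_residue": a.orf.ptc_residue_index if a.orf else None,
            "TRBD": a.domain_status.get("TRBD", "missing"),
            "RT": a.domain_status.get("RT", "missing"),
        })
    per_variant = pd.DataFrame(rows)
    per_variant["ptc_residue"] = per_variant["ptc_residue"].astype("Int64")
    agg_rows = []
    for species, grp in per_variant.groupby("species", sort=True):
        agg_rows.append({
            "species": species,
            "n_variants": len(grp),
            "orf_retained": int(grp["orf_retained"].sum()),
            "rt_partial_or_missing": int((grp["RT"] != "intact").sum()),
            "trbd_partial_or_missing": int((grp["TRBD"] != "intact").sum()),
            "both_truncated": int(((grp["TRBD"] != "intact") & (grp["RT"] != "intact")).sum()),
            "trbd_only_truncated": int(((grp["TRBD"] != "intact") & (grp["RT"] == "intact")).sum()),
            "intact_both": int(((grp["TRBD"] == "intact") & (grp["RT"] == "intact")).sum()),
        })
    aggregate = pd.DataFrame(agg_rows)
    return per_variant, aggregate
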
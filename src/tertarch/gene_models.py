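"""Sequences, gene models and transcript-space coordinates.

This module handles the plumbing every downstream analysis relies on:
reading FASTA sequence collections, reading gene models (exon/CDS
intervals) from GFF3, deriving transcript-space exon boundaries from a
gene model plus its genomic sequence, and translating a CDS while
checking for premature termination codons (PTCs).

Coordinate conventions
----------------------
GFF3 input is 1-based inclusive; every internal coordinate is 0-based
half-open.  An exon boundary is stored as the transcript offset of the
first nucleotide of the downstream exon, so a single integer fully
determines the intron site in transcript space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "TranscriptModel",
    "OrfReport",
    "read_fasta",
    "write_fasta",
    "read_sidecar_metadata",
    "read_gff3_gene_model",
    "build_transcript_model",
    "translate_cds",
]

_NT_ALPHABET = set("ACGTUNRYSWKMBDHV")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass
class SequenceRecord:
    """One sequence with optional species metadata.

    ``moltype`` is ``"nt"`` or ``"aa"``; the sequence must be consistent
    with it (IUPAC nucleotides including N, or the 20 amino acids plus X
    and ``*``).
    """

    id: str
    species: str
    seq: str
    moltype: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.moltype not in ("nt", "aa"):
            raise ValueError(f"moltype must be 'nt' or 'aa', got {self.moltype!r}")
        alphabet = _NT_ALPHABET if self.moltype == "nt" else _AA_ALPHABET
        bad = set(self.seq.upper()) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} not valid for moltype {self.moltype!r}"
            )


@dataclass
class GeneModel:
    """Genomic exon/CDS coordinates for one transcript of one gene.

    Intervals are 0-based half-open genomic coordinates, stored sorted
    5'->3' in *transcript* orientation (descending genomic start on the
    minus strand).
    """

    gene_id: str
    seq_region: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    transcript_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for s, e in ivs:
                if s >= e:
                    raise ValueError(f"{name} interval ({s},{e}) is empty or inverted")
        self.exons = self._orient(self.exons)
        self.cds = self._orient(self.cds)
        self._check_disjoint(self.exons, "exons")
        self._check_disjoint(self.cds, "cds")
        for c in self.cds:
            if not any(c[0] >= s and c[1] <= e for s, e in self.exons):
                raise ValueError(f"cds interval {c} not contained in any exon")
        if sum(e - s for s, e in self.cds) < 3:
            raise ValueError("total CDS length must be >= 3")

    def _orient(self, ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        return sorted(ivs, key=lambda iv: iv[0], reverse=self.strand == "-")

    @staticmethod
    def _check_disjoint(ivs: Sequence[tuple[int, int]], name: str) -> None:
        by_start = sorted(ivs)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 < e1:
                raise ValueError(f"{name} intervals ({s1},{e1}) and ({s2},{e2}) overlap")


@dataclass
class TranscriptModel:
    """A spliced transcript with the location of each exon boundary.

    ``exon_boundaries_nt`` holds, for each intron, the transcript offset
    of the first nucleotide downstream of the boundary (0-based
    half-open), so ``len(exon_boundaries_nt) == n_exons - 1``.
    ``cds_frame_warning`` records that the joined CDS length was not a
    multiple of three and the trailing 1-2 nt are dropped on translation.
    """

    transcript_id: str
    cdna: str
    exon_boundaries_nt: list[int]
    cds_start_nt: int
    cds_end_nt: int
    cds_frame_warning: bool = False

    def __post_init__(self) -> None:
        n = len(self.cdna)
        self.exon_boundaries_nt = sorted(self.exon_boundaries_nt)
        for b in self.exon_boundaries_nt:
            if not 0 < b < n:
                raise ValueError(f"exon boundary {b} outside (0, {n})")
        if len(set(self.exon_boundaries_nt)) != len(self.exon_boundaries_nt):
            raise ValueError("duplicate exon boundaries")
        if not 0 <= self.cds_start_nt < self.cds_end_nt <= n:
            raise ValueError(
                f"invalid CDS interval [{self.cds_start_nt}, {self.cds_end_nt}) for cdna of length {n}"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exon_boundaries_nt) + 1

    def exon_sequences(self) -> list[str]:
        """Split the cDNA back into exon sequences at the stored boundaries."""
        cuts = [0, *self.exon_boundaries_nt, len(self.cdna)]
        return [self.cdna[s:e] for s, e in zip(cuts, cuts[1:])]

    def cds_sequence(self) -> str:
        return self.cdna[self.cds_start_nt : self.cds_end_nt]


@dataclass
class OrfReport:
    """Translation outcome: the protein, and whether the ORF is retained.

    ``ptc_residue_index`` is the 0-based residue index of a stop codon
    occurring before the final codon of the CDS (a premature termination
    codon); it is ``None`` iff ``orf_retained``.
    """

    protein: str
    ptc_residue_index: int | None
    orf_retained: bool

    def __post_init__(self) -> None:
        if self.orf_retained != (self.ptc_residue_index is None):
            raise ValueError("orf_retained must be True iff ptc_residue_index is None")
        if "*" in self.protein:
            raise ValueError("protein must not contain internal stop characters")


def read_fasta(path: str | Path, moltype: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The species is parsed from a ``[species=...]`` tag in the header
    description when present, else left empty (a sidecar TSV can supply
    it, see :func:`read_sidecar_metadata`).  ``moltype="auto"`` infers
    nucleotide vs amino acid from the residue alphabet.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        species = ""
        desc = rec.description
        if "[species=" in desc:
            species = desc.split("[species=", 1)[1].split("]", 1)[0]
        seq = str(rec.seq).upper()
        mt = moltype
        if mt == "auto":
            mt = "nt" if set(seq) <= _NT_ALPHABET else "aa"
        records.append(SequenceRecord(id=rec.id, species=species, seq=seq, moltype=mt))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.species:
                header += f" [species={rec.species}]"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_sidecar_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a TSV of (id, species[, clade]) used when FASTA headers carry no tag."""
    meta: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            row = dict(zip(header, fields))
            meta[row["id"]] = row
    return meta


def read_gff3_gene_model(path: str | Path, transcript_id: str) -> GeneModel:
    """Extract one transcript's gene model from a GFF3 file.

    Collects ``exon`` and ``CDS`` features whose ``Parent`` attribute
    names ``transcript_id``.  GFF3 coordinates (1-based inclusive) are
    converted to 0-based half-open.  A gene model can carry several
    transcripts; the caller must name the one to use.
    """
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    seq_region = strand = gene_id = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line (expected 9 fields): {line!r}")
            seqid, _, ftype, start, end, _, fstrand, _, attrs = fields
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            if ftype not in ("exon", "CDS"):
                continue
            parents = attr.get("Parent", "").split(",")
            if transcript_id not in parents:
                continue
            iv = (int(start) - 1, int(end))
            if ftype == "exon":
                exons.append(iv)
            else:
                cds.append(iv)
            seq_region, strand = seqid, fstrand
            gene_id = attr.get("gene_id", attr.get("Parent", transcript_id))
    if not exons:
        raise ValueError(f"no exon features found for transcript {transcript_id!r} in {path}")
    if not cds:
        raise ValueError(f"no CDS features found for transcript {transcript_id!r} in {path}")
    return GeneModel(
        gene_id=gene_id or transcript_id,
        seq_region=seq_region,
        strand=strand,
        exons=exons,
        cds=cds,
        transcript_id=transcript_id,
    )


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_transcript_model(gene: GeneModel, genome_seq: str) -> TranscriptModel:
    """Splice a gene model against its genomic sequence.

    The cDNA is the concatenation of exon sequences in transcript
    orientation (minus-strand exons are reverse-complemented), and each
    exon boundary is recorded as a cumulative exon-length offset.  A
    minus-strand gene yields a transcript model identical to its
    plus-strand mirror.
    """
    n = len(genome_seq)
    for s, e in gene.exons + gene.cds:
        if not 0 <= s < e <= n:
            raise ValueError(f"interval ({s},{e}) outside genome sequence of length {n}")
    pieces = []
    for s, e in gene.exons:
        piece = genome_seq[s:e]
        if gene.strand == "-":
            piece = _revcomp(piece)
        pieces.append(piece)
    cdna = "".join(pieces).upper()
    boundaries = []
    acc = 0
    for piece in pieces[:-1]:
        acc += len(piece)
        boundaries.append(acc)

    # Genomic -> transcript coordinate of the CDS start/end, walking exons
    # in transcript orientation.
    def to_transcript(gpos: int) -> int:
        off = 0
        for s, e in gene.exons:
            if s <= gpos < e:
                return off + ((gpos - s) if gene.strand == "+" else (e - 1 - gpos))
            off += e - s
        raise ValueError(f"genomic position {gpos} not in any exon")

    cds_len = sum(e - s for s, e in gene.cds)
    if gene.strand == "+":
        first_cds_base = min(s for s, _ in gene.cds)
    else:
        first_cds_base = max(e for _, e in gene.cds) - 1
    cds_start = to_transcript(first_cds_base)
    cds_end = cds_start + cds_len
    frame_warning = cds_len % 3 != 0
    if frame_warning:
        warnings.warn(
            f"{gene.transcript_id}: CDS length {cds_len} is not a multiple of 3; "
            "trailing nucleotides will be dropped on translation",
            stacklevel=2,
        )
    return TranscriptModel(
        transcript_id=gene.transcript_id,
        cdna=cdna,
        exon_boundaries_nt=boundaries,
        cds_start_nt=cds_start,
        cds_end_nt=cds_end,
        cds_frame_warning=frame_warning,
    )


def translate_cds(t: TranscriptModel) -> OrfReport:
    """Translate the CDS with the standard genetic code.

    Translation stops at the first stop codon.  A stop before the final
    codon of the CDS is a premature termination codon and the ORF is not
    retained.  Codons containing N translate to 'X'.  Trailing partial
    codons are dropped.
    """
    cds = t.cds_sequence()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    usable = len(cds) - len(cds) % 3
    n_codons = usable // 3
    aa = str(Seq(cds[:usable]).translate())
    stop_at = aa.find("*")
    if stop_at == -1:
        return OrfReport(protein=aa, ptc_residue_index=None, orf_retained=True)
    if stop_at == n_codons - 1:
        return OrfReport(protein=aa[:stop_at], ptc_residue_index=None, orf_retained=True)
    return OrfReport(protein=aa[:stop_at], ptc_residue_index=stop_at, orf_retained=False)
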
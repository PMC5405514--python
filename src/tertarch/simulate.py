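"""Synthetic gene-family generator with exact ground truth.

Evolves a multi-exon, codon-structured ancestral gene along a user
tree: substitutions, codon-aligned indels, intron loss and gain, and
motif-region deletions, then emits splice variants per leaf (exon
skipping, intron retention, boundary-jittered deletions) with
frame-preserving and frame-shifting cases.  Every event is recorded, so
the truth can be replayed against the ancestor and every pipeline stage
(intron projection/conservation, motif transfer, splice-event
classification) can be scored exactly.

The regime the defaults emulate: a TERT-like gene of 16 exons
(15 introns, as in human TERT), canonical motifs spread along the
protein, widespread intron loss in some lineages and occasional gains,
motif losses such as the GQ/CP losses seen in protostomes, and variant
sets dominated by exon skipping.  Substitutions are sampled uniformly
over alternative nucleotides (no empirical matrix): the tests need
divergence, not mutational realism.  Substitutions that would create an
in-frame stop are rejected and resampled so that frame logic, not ORF
noise, is under test; ``reject_stops=False`` disables this for PTC
studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .gene_models import (GeneModel, SequenceRecord, TranscriptModel,
                          translate_cds, write_fasta)

__all__ = [
    "SimConfig",
    "SpeciesSim",
    "VariantSim",
    "SimulatedFamily",
    "simulate_family",
    "generate_variants",
    "replay_events",
    "default_motif_map",
]

_NT = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# Depths chosen so leaf proteins stay clearly alignable (~75-90% pairwise
# identity): substitutions here are uniform and unconstrained, so unlike real
# orthologs nothing anchors an alignment once divergence is deep.
DEFAULT_TREE = ("((human:0.02,macaque:0.02):0.04,(chicken:0.04,frog:0.05):0.03,"
                "((beetle:0.06,bee:0.06):0.04,(planarian:0.08,oyster:0.07):0.03):0.04);")


@dataclass
class SimConfig:
    """Parameters of one simulated gene family.

    Branch lengths are in expected substitutions per site, so
    ``substitution_rate`` is a unitless multiplier (default 1).
    ``indel_rate`` is per site per branch-length unit; indel lengths are
    geometric in codons.  ``intron_loss_prob`` and ``motif_loss_prob``
    are per element per branch; ``intron_gain_rate`` is the expected
    number of gains per branch.  ``variant_event_mix`` gives the
    probabilities of (exon_skip, intron_retention,
    boundary_jitter_deletion).
    """

    tree: str = DEFAULT_TREE
    n_exons: int = 16
    exon_length: tuple[int, int] = (90, 240)
    substitution_rate: float = 1.0
    indel_rate: float = 0.0
    indel_length_p: float = 0.5
    intron_loss_prob: float = 0.0
    intron_gain_rate: float = 0.0
    motif_map: list[tuple[str, int, int]] | None = None
    motif_loss_prob: float = 0.0
    n_variants: int = 0
    variant_event_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)
    frame_preserving_fraction: float = 0.5
    seed: int = 0
    reject_stops: bool = True

    def __post_init__(self) -> None:
        if self.n_exons < 2:
            raise ValueError("n_exons must be >= 2")
        for p in (self.intron_loss_prob, self.motif_loss_prob,
                  self.frame_preserving_fraction, *self.variant_event_mix):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for r in (self.substitution_rate, self.indel_rate, self.intron_gain_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class _State:
    """Mutable per-lineage state threaded down the tree."""

    cdna: str
    boundaries: list[tuple[str, int]]      # (intron id, transcript offset)
    motifs: dict[str, tuple[int, int]]     # name -> residue interval
    events: list[tuple] = field(default_factory=list)

    def copy(self) -> "_State":
        return _State(self.cdna, list(self.boundaries), dict(self.motifs),
                      list(self.events))


@dataclass
class VariantSim:
    id: str
    species: str
    cdna: str
    event_type: str                  # generator event: exon_skip | intron_retention | boundary_jitter_deletion
    expected_classification: str     # what a boundary-tolerant classifier should call
    segment: tuple[int, int]
    exons: tuple[int, ...]
    intron: str | None
    frame_preserving: bool
    orf_retained: bool


@dataclass
class SpeciesSim:
    name: str
    cdna: str
    boundaries: list[tuple[str, int]]
    motifs: dict[str, tuple[int, int]]
    events: list[tuple]
    intron_seqs: dict[str, str]
    protein: str = ""
    variants: list[VariantSim] = field(default_factory=list)

    @property
    def surviving_ancestral_introns(self) -> list[str]:
        return [i for i, _ in self.boundaries if not i.startswith("g")]

    @property
    def gained_introns(self) -> list[str]:
        return [i for i, _ in self.boundaries if i.startswith("g")]

    def intron_seqs_by_rank(self) -> dict[int, str]:
        """Map 1-based intron ranks (5'->3') to their genomic sequences."""
        ordered = sorted(self.boundaries, key=lambda t: t[1])
        return {k + 1: self.intron_seqs[iid] for k, (iid, _) in enumerate(ordered)}

    def transcript_model(self) -> TranscriptModel:
        return TranscriptModel(
            transcript_id=f"{self.name}_t1",
            cdna=self.cdna,
            exon_boundaries_nt=sorted(off for _, off in self.boundaries),
            cds_start_nt=0,
            cds_end_nt=len(self.cdna),
        )

    def genome(self) -> tuple[str, GeneModel]:
        """Interleave exons and intron sequences into a genomic record."""
        cuts = [0, *sorted(off for _, off in self.boundaries), len(self.cdna)]
        exon_seqs = [self.cdna[s:e] for s, e in zip(cuts, cuts[1:])]
        intron_order = [i for i, _ in sorted(self.boundaries, key=lambda t: t[1])]
        pieces = []
        exon_ivs = []
        pos = 0
        for k, ex in enumerate(exon_seqs):
            pieces.append(ex)
            exon_ivs.append((pos, pos + len(ex)))
            pos += len(ex)
            if k < len(intron_order):
                iseq = self.intron_seqs[intron_order[k]]
                pieces.append(iseq)
                pos += len(iseq)
        gene = GeneModel(
            gene_id=f"{self.name}_g1", seq_region=self.name, strand="+",
            exons=exon_ivs, cds=list(exon_ivs), transcript_id=f"{self.name}_t1",
        )
        return "".join(pieces), gene


@dataclass
class SimulatedFamily:
    config: SimConfig
    ancestor: _State
    ancestral_intron_seqs: dict[str, str]
    species: dict[str, SpeciesSim]

    def truth(self) -> dict:
        out: dict = {"species": {}, "variants": {}}
        for name, sp in self.species.items():
            out["species"][name] = {
                "surviving_ancestral_introns": sp.surviving_ancestral_introns,
                "gained_introns": sp.gained_introns,
                "lost_motifs": sorted(set(self.ancestor.motifs) - set(sp.motifs)),
                "intron_offsets": {i: off for i, off in sp.boundaries},
                "motif_intervals": {m: list(iv) for m, iv in sp.motifs.items()},
                "events": [list(e) for e in sp.events],
            }
            for v in sp.variants:
                out["variants"][v.id] = {
                    "species": v.species,
                    "event_type": v.event_type,
                    "expected_classification": v.expected_classification,
                    "segment": list(v.segment),
                    "exons": list(v.exons),
                    "intron": v.intron,
                    "frame_preserving": v.frame_preserving,
                    "orf_retained": v.orf_retained,
                }
        return out

    def write(self, outdir: str | Path) -> None:
        """Write genomes/proteins/transcripts FASTA, gene models GFF3,
        variants FASTA and the truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genomes, proteins, transcripts, variants = [], [], [], []
        gff_lines = ["##gff-version 3"]
        for name, sp in sorted(self.species.items()):
            gseq, gene = sp.genome()
            genomes.append(SequenceRecord(name, name, gseq, "nt"))
            proteins.append(SequenceRecord(f"{name}_t1", name, sp.protein, "aa"))
            transcripts.append(SequenceRecord(f"{name}_t1", name, sp.cdna, "nt"))
            glen = len(gseq)
            gff_lines.append(
                f"{name}\ttertarch_sim\tgene\t1\t{glen}\t.\t+\t.\tID={gene.gene_id}")
            gff_lines.append(
                f"{name}\ttertarch_sim\tmRNA\t1\t{glen}\t.\t+\t.\t"
                f"ID={gene.transcript_id};Parent={gene.gene_id}")
            for s, e in gene.exons:
                gff_lines.append(
                    f"{name}\ttertarch_sim\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"Parent={gene.transcript_id}")
            for s, e in gene.cds:
                gff_lines.append(
                    f"{name}\ttertarch_sim\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                    f"Parent={gene.transcript_id}")
            for v in sp.variants:
                variants.append(SequenceRecord(v.id, name, v.cdna, "nt"))
        write_fasta(genomes, outdir / "genomes.fasta")
        write_fasta(proteins, outdir / "proteins.fasta")
        write_fasta(transcripts, outdir / "transcripts.fasta")
        if variants:
            write_fasta(variants, outdir / "variants.fasta")
        (outdir / "models.gff3").write_text("\n".join(gff_lines) + "\n")
        (outdir / "truth.json").write_text(json.dumps(self.truth(), indent=1))


def default_motif_map(protein_length: int) -> list[tuple[str, int, int]]:
    """Spread the 11 canonical motif names evenly along a protein."""
    names = ["GQ", "CP", "QFP", "T", "1", "2", "A", "Bprime", "C", "D", "E"]
    width = max(6, protein_length // 30)
    span = protein_length - 10
    out = []
    for k, name in enumerate(names):
        start = 5 + int(k * span / len(names))
        out.append((name, start, min(start + width, protein_length - 2)))
    return out


def _random_codons(rng: np.random.Generator, n: int) -> str:
    out = []
    while len(out) < n:
        codon = "".join(_NT[i] for i in rng.integers(0, 4, size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _build_ancestor(cfg: SimConfig, rng: np.random.Generator) -> tuple[_State, dict[str, str]]:
    lo, hi = cfg.exon_length
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_exons)]
    total = sum(lengths)
    pad = (-total) % 3
    lengths[-1] += pad
    total += pad
    n_codons = total // 3
    if n_codons < 4:
        raise ValueError("ancestral CDS too short")
    cdna = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
    boundaries = []
    acc = 0
    for k, L in enumerate(lengths[:-1]):
        acc += L
        boundaries.append((f"i{k + 1}", acc))
    protein_len = n_codons - 1
    motif_map = cfg.motif_map if cfg.motif_map is not None else default_motif_map(protein_len)
    motifs = {}
    for name, s, e in motif_map:
        if not 0 < s < e <= protein_len:
            raise ValueError(f"motif {name!r} interval [{s},{e}) outside protein of length {protein_len}")
        motifs[name] = (s, e)
    intron_seqs = {}
    for iid, _ in boundaries:
        ilen = int(rng.integers(60, 201))
        core = "".join(_NT[i] for i in rng.integers(0, 4, size=ilen - 4))
        intron_seqs[iid] = "GT" + core + "AG"
    return _State(cdna=cdna, boundaries=boundaries, motifs=motifs), intron_seqs


def _codon_at(cdna: str, pos: int) -> str:
    c = pos - pos % 3
    return cdna[c : c + 3]


def _apply_substitutions(state: _State, p: float, reject_stops: bool,
                         rng: np.random.Generator) -> None:
    L = len(state.cdna)
    if p <= 0:
        return
    hits = np.nonzero(rng.random(L) < min(p, 0.75))[0]
    seq = list(state.cdna)
    for pos in hits:
        pos = int(pos)
        if pos < 3 or pos >= L - 3:   # keep start and stop codons anchored
            continue
        old = seq[pos]
        choices = [b for b in _NT if b != old]
        rng.shuffle(choices)
        for new in choices:
            codon_start = pos - pos % 3
            codon = "".join(seq[codon_start : codon_start + 3])
            trial = codon[: pos - codon_start] + new + codon[pos - codon_start + 1 :]
            if reject_stops and trial in _STOPS:
                continue
            seq[pos] = new
            state.events.append(("sub", pos, new))
            break
    state.cdna = "".join(seq)


def _offsets(state: _State) -> list[int]:
    return [off for _, off in state.boundaries]


def _shift_after(state: _State, pos: int, delta_nt: int) -> None:
    state.boundaries = [(i, off + delta_nt if off > pos else off)
                        for i, off in state.boundaries]
    d_res = delta_nt // 3
    res_pos = pos // 3
    state.motifs = {
        name: ((s + d_res, e + d_res) if s >= res_pos else (s, e))
        for name, (s, e) in state.motifs.items()
    }


def _indel_site_ok(state: _State, s: int, Lnt: int, deletion: bool) -> bool:
    L = len(state.cdna)
    if s % 3 != 0 or s < 3:
        return False
    if deletion and s + Lnt > L - 3:
        return False
    if not deletion and s > L - 3:
        return False
    lo, hi = (s, s + Lnt) if deletion else (s - 3, s + 3)
    for _, off in state.boundaries:
        if lo < off <= hi:
            return False
    s_res, e_res = s // 3, (s + (Lnt if deletion else 0)) // 3
    for ms, me in state.motifs.values():
        if ms < e_res + 1 and s_res < me:   # would touch a motif interval
            return False
    return True


def _apply_indels(state: _State, expected: float, p_geom: float,
                  rng: np.random.Generator) -> None:
    if expected <= 0:
        return
    for _ in range(int(rng.poisson(expected))):
        deletion = bool(rng.random() < 0.5)
        Lnt = 3 * int(rng.geometric(p_geom))
        placed = False
        for _try in range(50):
            s = 3 * int(rng.integers(1, max(2, len(state.cdna) // 3 - 1)))
            if _indel_site_ok(state, s, Lnt, deletion):
                placed = True
                break
        if not placed:
            continue
        if deletion:
            state.cdna = state.cdna[:s] + state.cdna[s + Lnt:]
            _shift_after(state, s, -Lnt)
            state.events.append(("del", s, Lnt))
        else:
            ins = _random_codons(rng, Lnt // 3)
            state.cdna = state.cdna[:s] + ins + state.cdna[s:]
            _shift_after(state, s, +Lnt)
            state.events.append(("ins", s, ins))


def _apply_intron_turnover(state: _State, loss_prob: float, gain_rate: float,
                           intron_seqs: dict[str, str], gain_counter: list[int],
                           rng: np.random.Generator) -> None:
    if loss_prob > 0:
        kept = []
        for iid, off in state.boundaries:
            if rng.random() < loss_prob:
                state.events.append(("intron_loss", iid))
            else:
                kept.append((iid, off))
        state.boundaries = kept
    if gain_rate > 0:
        for _ in range(int(rng.poisson(gain_rate))):
            L = len(state.cdna)
            for _try in range(50):
                pos = int(rng.integers(4, L - 3))
                if all(abs(pos - off) > 3 for off in _offsets(state)):
                    gain_counter[0] += 1
                    iid = f"g{gain_counter[0]}"
                    state.boundaries.append((iid, pos))
                    ilen = int(rng.integers(60, 201))
                    core = "".join(_NT[i] for i in rng.integers(0, 4, size=ilen - 4))
                    intron_seqs[iid] = "GT" + core + "AG"
                    state.events.append(("intron_gain", iid, pos))
                    break


def _apply_motif_loss(state: _State, prob: float, rng: np.random.Generator) -> None:
    if prob <= 0:
        return
    for name in sorted(state.motifs):
        if rng.random() >= prob:
            continue
        s_res, e_res = state.motifs.pop(name)
        s, Lnt = 3 * s_res, 3 * (e_res - s_res)
        lost = [iid for iid, off in state.boundaries if s < off <= s + Lnt]
        state.boundaries = [(iid, off) for iid, off in state.boundaries
                            if not s < off <= s + Lnt]
        state.cdna = state.cdna[:s] + state.cdna[s + Lnt:]
        _shift_after(state, s, -Lnt)
        state.events.append(("motif_loss", name, s, Lnt, lost))


def replay_events(ancestor_cdna: str, ancestor_boundaries: list[tuple[str, int]],
                  events: list[tuple]) -> tuple[str, list[tuple[str, int]]]:
    """Replay a recorded event list against the ancestral state.

    Returns the reconstructed (cdna, boundaries); used to check that the
    emitted truth is internally consistent with the emitted sequences.
    """
    cdna = ancestor_cdna
    boundaries = list(ancestor_boundaries)

    def shift(pos: int, d: int) -> None:
        nonlocal boundaries
        boundaries = [(i, off + d if off > pos else off) for i, off in boundaries]

    for ev in events:
        tag = ev[0]
        if tag == "sub":
            _, pos, new = ev
            cdna = cdna[:pos] + new + cdna[pos + 1:]
        elif tag == "del":
            _, s, Lnt = ev
            cdna = cdna[:s] + cdna[s + Lnt:]
            shift(s, -Lnt)
        elif tag == "ins":
            _, s, ins = ev
            cdna = cdna[:s] + ins + cdna[s:]
            shift(s, len(ins))
        elif tag == "intron_loss":
            boundaries = [(i, off) for i, off in boundaries if i != ev[1]]
        elif tag == "intron_gain":
            _, iid, pos = ev
            boundaries.append((iid, pos))
        elif tag == "motif_loss":
            _, _name, s, Lnt, _lost = ev
            boundaries = [(i, off) for i, off in boundaries if not s < off <= s + Lnt]
            cdna = cdna[:s] + cdna[s + Lnt:]
            shift(s, -Lnt)
        else:  # pragma: no cover
            raise ValueError(f"unknown event {tag!r}")
    return cdna, boundaries


def simulate_family(cfg: SimConfig) -> SimulatedFamily:
    """Run the full simulation; deterministic for a given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    ancestor, intron_seqs = _build_ancestor(cfg, rng)
    all_intron_seqs = dict(intron_seqs)
    gain_counter = [0]
    states: dict[int, _State] = {id(tree.seed_node): ancestor.copy()}
    species: dict[str, SpeciesSim] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        st = parent_state.copy()
        blen = node.edge.length or 0.0
        _apply_substitutions(st, cfg.substitution_rate * blen, cfg.reject_stops, rng)
        _apply_indels(st, cfg.indel_rate * blen * len(st.cdna), cfg.indel_length_p, rng)
        _apply_intron_turnover(st, cfg.intron_loss_prob, cfg.intron_gain_rate,
                               all_intron_seqs, gain_counter, rng)
        _apply_motif_loss(st, cfg.motif_loss_prob, rng)
        states[id(node)] = st
        if node.is_leaf():
            name = node.taxon.label.replace(" ", "_")
            sp = SpeciesSim(
                name=name, cdna=st.cdna, boundaries=sorted(st.boundaries, key=lambda t: t[1]),
                motifs=dict(st.motifs), events=list(st.events),
                intron_seqs={i: all_intron_seqs[i] for i, _ in st.boundaries},
            )
            sp.protein = translate_cds(sp.transcript_model()).protein
            species[name] = sp
    if cfg.n_variants > 0:
        for name in sorted(species):
            species[name].variants = generate_variants(species[name], cfg, rng)
    return SimulatedFamily(config=cfg, ancestor=ancestor,
                           ancestral_intron_seqs=intron_seqs, species=species)


def _variant_orf_ok(cdna: str) -> bool:
    t = TranscriptModel(transcript_id="v", cdna=cdna, exon_boundaries_nt=[],
                        cds_start_nt=0, cds_end_nt=len(cdna))
    return translate_cds(t).orf_retained


def generate_variants(sp: SpeciesSim, cfg: SimConfig,
                      rng: np.random.Generator) -> list[VariantSim]:
    """Sample ``cfg.n_variants`` splice variants from one leaf's gene model.

    Event types are drawn from ``variant_event_mix`` and never resampled
    (so the realized mix is an unbiased draw); the frame-preserving
    target is enforced by resampling the event's *parameters* (which
    exon run / which intron / which jitter).  Intron retention can
    rarely preserve the frame (the intron must be a multiple of 3 with
    no in-frame stop), so when ``frame_preserving_fraction`` is exactly
    1.0 an unsatisfiable draw falls back to an exon skip rather than
    failing; at any lower fraction the realized frame outcome is simply
    recorded in the truth.
    """
    offsets = sorted(off for _, off in sp.boundaries)
    bounds = [0, *offsets, len(sp.cdna)]
    n_exons = len(bounds) - 1
    iid_at = {off: iid for iid, off in sp.boundaries}
    mix = np.array(cfg.variant_event_mix, dtype=float)
    if mix.sum() == 0:
        raise ValueError("variant_event_mix sums to zero")
    mix = mix / mix.sum()
    variants: list[VariantSim] = []
    for k in range(cfg.n_variants):
        etype = ("exon_skip", "intron_retention", "boundary_jitter_deletion")[
            int(rng.choice(3, p=mix))]
        if etype in ("exon_skip", "boundary_jitter_deletion") and n_exons < 3:
            etype = "intron_retention"
        if etype == "intron_retention" and not offsets:
            continue  # intronless gene: no variant possible
        must_preserve = bool(rng.random() < cfg.frame_preserving_fraction)

        def draw(ety: str):
            if ety == "intron_retention":
                off = offsets[int(rng.integers(0, len(offsets)))]
                iid = iid_at[off]
                iseq = sp.intron_seqs[iid]
                cdna = sp.cdna[:off] + iseq + sp.cdna[off:]
                preserved = len(iseq) % 3 == 0 and _variant_orf_ok(cdna)
                return (cdna, (off, off + len(iseq)), (), iid,
                        "intron_retention", preserved)
            first = int(rng.integers(2, n_exons))          # interior exon rank
            run = int(rng.integers(1, min(3, n_exons - first) + 1))
            last = first + run - 1
            s, e = bounds[first - 1], bounds[last]
            if ety == "boundary_jitter_deletion":
                delta = int(rng.choice([-2, -1, 1, 2]))
                if rng.random() < 0.5:
                    s = max(1, s + delta)
                else:
                    e = min(len(sp.cdna) - 1, e + delta)
                if e <= s:
                    return None
            cdna = sp.cdna[:s] + sp.cdna[e:]
            preserved = (e - s) % 3 == 0 and _variant_orf_ok(cdna)
            return (cdna, (s, e), tuple(range(first, last + 1)), None,
                    "exon_skip", preserved)

        type_options = [etype]
        if (must_preserve and cfg.frame_preserving_fraction == 1.0
                and etype != "exon_skip" and n_exons >= 3):
            type_options.append("exon_skip")  # retention rarely preserves frame
        chosen = last_draw = None
        realized_type = etype
        for ety in type_options:
            for _try in range(500):
                d = draw(ety)
                if d is None:
                    continue
                last_draw = d
                if d[5] == must_preserve:
                    chosen, realized_type = d, ety
                    break
            if chosen is not None:
                break
        if chosen is None:
            if last_draw is None:
                continue
            if must_preserve and cfg.frame_preserving_fraction == 1.0:
                raise RuntimeError(
                    f"{sp.name}: no frame-preserving variant found; "
                    "gene structure offers no suitable event")
            chosen = last_draw  # accept the realized frame outcome
        cdna, seg, exons, intron, expected, preserved = chosen
        variants.append(VariantSim(
            id=f"{sp.name}_v{k + 1}", species=sp.name, cdna=cdna,
            event_type=realized_type, expected_classification=expected,
            segment=seg, exons=exons, intron=intron,
            frame_preserving=preserved,
            orf_retained=_variant_orf_ok(cdna),
        ))
    return variants
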
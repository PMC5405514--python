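# Methods

This note documents the models and procedures behind `tertarch`, the
parameters that matter, the design choices that were genuinely open,
and what the synthetic-data tests do and do not demonstrate about real
data.

## Coordinate model

All internal coordinates are 0-based half-open; GFF3 input (1-based
inclusive) is converted on read. An exon boundary is stored as the
transcript offset of the first nucleotide of the downstream exon — a
single integer that fully determines the intron site in transcript
space. Minus-strand gene models are reverse-complemented on splicing
so that a minus-strand gene and its plus-strand mirror yield identical
transcript models (property-tested over random gene structures).

An intron at transcript offset `b` within a CDS starting at `s`
projects to residue index `⌊(b−s)/3⌋` and codon phase `(b−s) mod 3`.
The hosting residue of a phase-0 boundary is the residue *after* the
boundary; this keeps the residue formula uniform across phases.
Boundaries in UTRs are excluded from conservation analyses and
reported separately, because positions are compared on the protein.
Trailing partial codons (common in partial sequences) are dropped with
a recorded warning rather than a hard error.

## Pairwise alignment

Protein alignment is global affine-gap Needleman–Wunsch with BLOSUM62,
gap open 11, gap extend 1 (a gap of length *k* costs `11 + k`),
delegated to Biopython's `PairwiseAligner`; the first alignment of its
canonical traceback order is taken, so outputs are bit-reproducible.
Optimality is verified against an independent exhaustive-enumeration
oracle (every global alignment of every pair over a reduced alphabet;
see below). Multiple alignments are *imported* from aligned FASTA and
never computed — the analyses this package supports typically build
MSAs with a dedicated aligner (historically MAFFT with BLOSUM62, gap
penalty 1.53, offset 0.123; those values are recorded as provenance
only and are not the internal scoring).

Nucleotide alignment (variant ↔ isoform 1) uses match 2, mismatch −3,
gap open 10, gap extend 0.5 — conventional values exposed in
configuration, not estimated from data.

Percent identity is not uniquely defined in the literature, so the
denominator is a mode flag: `aligned_columns` (default) counts all
columns between the outermost residue overlap of the pair (terminal
gap columns excluded); `ungapped_pairs` counts only columns where both
rows hold a residue. Multi-row input returns the mean over all pairs.

## Intron conservation calls

A query intron is conserved when some reference intron's hosting
residue maps to an alignment column within `tolerance_columns` of the
query intron's column. Defaults: tolerance 0 (exact shared column) and
phase ignored — positions are compared on the protein; phase is
recorded and can be required (`require_phase=True`) for sensitivity
analysis. Each reference intron matches at most one query intron;
matching is greedy from the 5′ end with ties to the 5′-most reference
intron (the contested case is rare and needs a deterministic rule).
`n_conserved + n_specific = n_introns` holds by construction and is
property-tested, as is monotonicity of `n_conserved` in the tolerance.

## Motif transfer, profiles and conserved blocks

Motif presence is decided by *coverage*: the fraction of the reference
motif's alignment columns at which the target holds a residue.
Thresholds present ≥ 0.70, partial ≥ 0.20 are pragmatic defaults for
turning qualitative present/absent judgements into a reproducible
rule; they are configuration keys written into every output's
provenance header, not biological constants. Coverage is invariant
under all-gap column insertion.

Conservation profiles report, per column, the frequency of the modal
non-gap residue; gap rows are excluded from the denominator and
all-gap columns dropped (the alternative, counting gaps against the
denominator, is obtainable by filtering the input alignment). Modal
ties break alphabetically for determinism.

The conserved-block scanner formalises what is usually a manual call:
within a labelled clade (≥ 3 members), a column passes when at most
`max_states` (default 2) residues jointly cover ≥ `f_within` (default
0.8) of members *and* the modal residue frequency outside the clade is
below `f_background_max` (default 0.5). Maximal runs of passing
columns ≥ `min_block_length` (default 4) are emitted as degenerate
consensus strings — a single letter, `(A/B)` for two states, `x` for
an interior failing column bridged by ≥ 2 passing columns on each
side. These parameters approximate, rather than replicate, expert
judgement; blocks should be read as candidates.

## Splice-variant classification

Variants are accepted when the aligned non-gap identity to their
reference is ≥ 80%; below that the sequence is rejected as "not a
variant of this reference" (listed in a rejects file by the CLI, which
continues). Gap runs become segments; classification uses a boundary
tolerance `tol_nt = 3`: wide enough to absorb alignment slippage at
junctions (gap placement is ambiguous when junction sequence repeats),
narrow enough never to bridge distinct exons at realistic exon sizes.
A deletion matching boundaries at both ends is an exon skip (ranks
reported 1-based, so "exons 8–10" reads naturally); an insertion at a
boundary matching its adjacent genomic intron at ≥ 90% identity is an
intron retention; everything else is a splice-site mutation, flagged
"possible retention" when no genomic intron sequence was available to
check — mirroring the pooled annotation such data usually receive.

Variant translation starts at the variant image of the reference start
codon (through the nucleotide alignment); a variant whose start region
is deleted is reported as not ORF-retained with reason "no start"
rather than given a premature-stop index. Domain status is a pure
function of motif status — TRBD from {CP, QFP, T} (or {QFP, T} when
the reference annotation lacks CP, as in planarian-style references),
RT from {1, 2, A, B′, C, D, E}: intact iff all present, missing iff
all absent, truncated otherwise — exhaustively tested over all 3⁹
status combinations.

For species with cloned transcripts but no genome, exon–intron
boundaries can be projected from a related donor gene model through a
protein alignment, converting each donor intron back to a target cDNA
offset using the donor's phase; the projection errors out when more
than half the boundaries land in alignment gaps.

## The simulator: what it emulates, and what it does not

The generator evolves a codon-structured ancestral gene (default 16
exons — a TERT-like architecture with 15 introns; exon lengths uniform
on 90–240 nt) along a user tree with branch lengths in substitutions
per site. Substitutions are uniform over alternative nucleotides, with
stop-creating changes rejected by default (`reject_stops=False`
disables this for PTC studies); indels are codon-aligned and placed
away from boundaries and motif intervals so that the recorded truth
stays exact; intron loss (per intron per branch), intron gain (per
branch, never within 3 nt of an existing boundary) and motif loss
(in-frame deletion of the motif interval) complete the event set.
Every event is logged, and replaying the log against the ancestor must
reproduce each leaf byte-for-byte — this closure is itself a test.

Variants are sampled per leaf from a type mix (exon skip of 1–3
interior exons / intron retention / boundary-jittered deletion of
±1–2 nt). Event types are never resampled, so the realized mix is an
unbiased multinomial draw; the frame-preserving fraction is enforced
by resampling event *parameters*. One documented exception: at
`frame_preserving_fraction = 1.0` an unsatisfiable retention draw
(random introns rarely have length ≡ 0 mod 3 and no in-frame stop)
falls back to an exon skip, because the all-preserving contract
outranks mix fidelity there.

What the simulator deliberately does not model: empirical substitution
matrices or site-rate variation (tests need divergence, not realism),
frameshifting indels during lineage evolution (frame logic is tested
separately on raw sequences), intron sequence evolution, gene
duplication and loss, and — most importantly — purifying selection.
The last point sets a realism limit worth stating: simulated proteins
have no conserved anchors, so once divergence is deep their alignment
degrades much faster than real orthologs'. The default demonstration
tree is therefore shallow enough to keep leaves at ~75–90% pairwise
identity, the alignable-ortholog regime in which position-based intron
comparison is meaningful. Passing recovery tests show the machinery is
correct on alignable sequences with known truth; they do not show that
any particular real pair of proteins is alignable.

## Validation problem sizes

The acceptance script and test suite use these scales, chosen to give
tight checks at interactive runtimes:

- aligner vs oracle: every pair over the two-letter alphabet {A, G} up
  to length 4 (tests) or 5 (script), plus 100 seeded random pairs of
  length 5–6 — ~500–2,000 pairs, each scored by full enumeration;
- coordinate round trips: 1,000 random gene models (1–8 exons);
- intron recovery: 20 replicate two-species families (10 ancestral
  introns, loss 0.2/branch, branch length 0.1), substitution-only and
  at indel rate 0.01/site;
- splice-event accuracy: 200 variants at exact boundaries and 200 with
  ±2 nt jitter, classified at `tol_nt = 3`;
- simulator closure: an 8-leaf family with all event types enabled,
  plus a 50-leaf star tree (10 introns, loss 0.3) whose mean intron
  survival is compared with the binomial expectation of 7.0 within two
  standard errors.

## Known limitations

- Packaged hTERT / *C. elegans* TERT motif coordinates are approximate
  literature-derived fixtures, not authoritative annotations; override
  them for exact work.
- The block scanner's thresholds encode one reasonable formalisation
  of "clade-restricted conservation"; other parameterisations will
  call different block boundaries.
- Intron retention cannot be positively identified without the genomic
  intron sequence; such insertions are reported as splice-site
  mutations with a possible-retention flag.
- Percent-identity values depend on the mode flag; comparisons with
  published figures should state the mode.
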
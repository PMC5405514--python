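# tertarch

Comparative analysis of gene architecture evolution across a protein
family, built around the questions raised by telomerase reverse
transcriptase (TERT): which introns have kept their ancestral positions
across half a billion years, which canonical motifs a lineage has lost,
which lineage-restricted sequence blocks have appeared, and how
alternative splicing reshapes the domain content of individual
transcripts.

It is aimed at molecular evolution researchers comparing exon–intron
structure and domain architecture across species — the kind of analysis
that starts from per-species FASTA + GFF3 gene models plus a protein
multiple alignment, and ends in presence/absence matrices and
conservation tables.

## What it computes

**Intron-position conservation.** Exon boundaries are projected from
transcript coordinates into protein coordinates: an intron interrupting
codon *r* with *p* nucleotides of that codon 5′ of the boundary has
residue index `r = ⌊(b − cds_start)/3⌋` and codon phase
`p = (b − cds_start) mod 3`. Boundaries are then mapped through a
pairwise protein alignment with a reference species (human TERT, with
its 15 introns, in the motivating analyses); a query intron whose
hosting residue shares an alignment column with a reference intron is
*conserved*, otherwise *species-specific*.

**Motif annotation transfer.** Reference motif intervals (the canonical
TERT set GQ, CP, QFP, T, 1, 2, A, B′, C, D, E, plus the derived linker
and C-terminal extension) are carried through an alignment; each
target's *coverage* of the reference motif columns decides
present (≥ 0.70) / partial (≥ 0.20) / absent. Column-wise conservation
profiles report the frequency of the modal residue, and a scanner mines
clade-restricted conserved blocks emitted as degenerate consensus
strings such as `(I/V)QQRVxLQF`.

**Splice-variant classification.** Variant cDNAs are globally aligned
to their full-length "isoform 1"; gap runs become deletion/insertion
segments classified as exon skipping (boundary-matched deletions),
intron retention (insertions matching a genomic intron) or splice-site
mutations. Each variant is translated in the reference frame, checked
for a premature termination codon, and its TRBD and RT domains called
intact / truncated / missing from the recomputed motif complement.

**Synthetic ground truth.** A simulator evolves a multi-exon ancestral
gene along a tree — substitutions, codon-aligned indels, intron loss
and gain, motif-region deletions — and emits splice variants with known
events, so every stage above can be scored against exact truth.

## Worked example

Simulate an 8-species family, tabulate intron conservation against one
species, and classify its splice variants:

```sh
tertarch simulate --seed 5 --out-dir demo --n-exons 8 --n-variants 3 \
    --intron-loss-prob 0.15 --intron-gain-rate 0.1 --motif-loss-prob 0.0
tertarch introns --gff demo/models.gff3 --genomes demo/genomes.fasta \
    --reference bee_t1 --out demo/conservation.tsv
tertarch splice --gff demo/models.gff3 --genomes demo/genomes.fasta \
    --transcript bee_t1 --variants demo/variants.fasta --out-dir demo/splice
```

`demo/conservation.tsv` (provenance header omitted):

```
species      n_introns  n_conserved  n_specific  matched_ref_ranks
bee_t1       5          5            0           1,2,3,4,5
beetle_t1    6          5            1           1,2,3,4,5
chicken_t1   8          4            4           1,2,3,5
frog_t1      7          3            4           2,3,5
human_t1     5          4            1           1,2,3,5
macaque_t1   4          4            0           1,2,3,5
oyster_t1    3          2            1           2,3
planarian_t1 3          2            1           2,3
```

Read: the reference conserves all of its own introns by definition;
`beetle_t1` carries the same five ancestral introns plus one lineage
gain; the oyster and planarian lineages have lost three of the five and
kept introns 2 and 3 at reference-equivalent positions.

The per-variant report (`demo/splice/variants.tsv`) starts:

```
variant_id  species  n_events  events          orf_retained  ptc_residue  TRBD    RT
bee_v1      bee      1         skip_exons_3-3  False         170          intact  missing
bee_v2      bee      1         skip_exons_3-4  False         176          intact  missing
bee_v3      bee      1         skip_exons_2-2  False         73           truncated  missing
```

Read: each variant skips a run of exons; the skips shift the reading
frame, so translation hits a premature stop (`ptc_residue`) and the
downstream RT domain is missing; the exon-2 skip truncates the TRBD as
well.

The same operations are available as library calls
(`tertarch.project_introns`, `tertarch.classify_introns`,
`tertarch.transfer_motifs`, `tertarch.find_conserved_blocks`,
`tertarch.map_variant`, `tertarch.annotate_variant`,
`tertarch.simulate_family`, …); the CLI is a thin layer over them.

## Packaged reference data

`tertarch.motifs.packaged_motif_definitions()` ships approximate,
literature-derived residue intervals for the canonical motifs of human
TERT (1132 aa) and *C. elegans* TERT (514 aa) as JSON fixtures. They are
conveniences for getting started; for exact work supply your own JSON
config (`--motifs-config`).
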
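# Methods

This note documents the models, thresholds and numerical choices behind
`genelosskit`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Disruption scanning

**Model.** A candidate gene is compared exon-by-exon against a reference
gene model (coordinates 1-based inclusive, minus-strand models stored on
plus-strand coordinates and reverse-complemented at extraction). Each
reference exon, carrying 20 bp of intronic flank on either side
(configurable), is aligned into a window of the target sequence by
global affine-gap alignment — match +1, mismatch −1, gap open −4 (first
gap base), gap extension −1 — with free end gaps on the window side, so
the window may be generously larger than the exon. Alignment is
delegated to Biopython's `PairwiseAligner`; its first traceback is
deterministic, and gap placement at ties follows that canonical order
rather than any bespoke preference ladder (the downstream calls depend
on net indels and identity, not on where equal-scoring gaps sit).

**Exon presence.** An exon is *found* when three conditions hold over
the exon-proper alignment columns: identity ≥ 0.5 on aligned columns,
≥ 50% of the exon's reference bases aligned, and alignment score
≥ 0.2 per exon base. The score floor is what rejects spurious
placements: under ±1 match/mismatch scoring, optimal alignments of
unrelated sequence cherry-pick enough matches to reach ~50% column
identity, but they hover near score 0 (measured maximum ≈ 0.13/base
over hundreds of random and reversed-sequence trials), whereas genuine
exons at up to ~30–35% nucleotide divergence stay above ≈ 0.3/base. The
intended operating range is therefore intra-class comparisons (e.g.
mammals against a mammalian reference); beyond ~35% divergence exons
will start dropping out as "not found", which mirrors how far genomic
alignment of this kind carries in practice.

**Mutation classes.**

- *Frameshift:* net indel within an exon (insertions minus deletions
  over exon-proper columns) ≢ 0 (mod 3). Compensating indels in one exon
  cancel; the premature-stop scan catches intra-exon scrambling that a
  balanced indel pair can cause. One event per exon at most.
- *Premature stop:* each exon is "repaired" to reference length —
  substituted bases kept, deleted columns refilled with the reference
  base, inserted bases dropped — and the concatenated repaired CDS is
  scanned codon-by-codon in the reference frame. Every in-frame stop
  strictly upstream of the reference terminal stop is an event,
  attributed to the exon containing the codon's first base. Codons with
  N translate to X and never count as stops. Exons that were not found
  contribute their reference sequence, so they can neither create nor
  mask stops.
- *Splice mutation:* the donor dinucleotide is read from the target
  immediately after the last target base aligned inside the exon, the
  acceptor from the two target bases preceding the first; this stays
  correct when an insertion straddles the junction. Donor ≠ GT or
  acceptor ≠ AG is an event (donor attributed to the preceding exon,
  acceptor to the following one). GC donors — a real, if rare, U2 splice
  variant — are still reported, flagged `noncanonical` in the detail
  field. Junctions of unfound exons are skipped, not called.

**Status.** ≥ 2 disruptions ⇒ `INACTIVATED`; exactly 1 ⇒
`POTENTIALLY_INTACT` (a single apparent mutation can be a sequencing
error or a rare allele); 0 with every exon found ⇒ `INTACT`; 0 with
missing exons ⇒ `POTENTIALLY_INTACT` (absence of evidence is not a
disruption). Species with no sequence at all defer to the synteny call:
`DELETED` or `UNRESOLVED`. Tabulated output follows the two-column
convention of published disruption tables: premature stops fold into the
frameshift column; the JSON report keeps all four categories.

**Window placement.** The scanner assumes rough colinearity between
reference and target locus: each exon's window is centred on its
reference position corrected by the drift observed at previously located
exons, ± a margin (default 300 bp). This is appropriate for orthologous
loci without major rearrangement; it is not a general gene finder.

## Synteny absence calls

Per species, an ordered map of (fragment, gene symbol, orientation,
position) hits is consulted. Conserved flanks are discovered from
reference maps as the nearest symbols on each side of the target with
consistent relative orientation; maps showing only one side of the
target abstain for the other side rather than vetoing (draft-assembly
fragments are short). The verdicts:

- `PRESENT` — target hit anywhere in the species map;
- `DELETED` — both flanks on a single fragment, same relative
  orientation, no target between them. Intervening unrelated genes do
  not block the call (fish neighborhoods are rearranged); the target
  must be absent from the whole map;
- `UNRESOLVED` — anything else.

All checks use relative order/orientation only, so calls are invariant
to mirroring a fragment (assembly polarity is arbitrary).

## Dollo parsimony

Gene inactivation is modelled as irreversible: the root is functional,
a branch may lose the gene, and a loss is never regained. Under this
model the minimum event set is exactly the stems of the maximal clades
that contain ≥ 1 nonfunctional tip and no functional tip (missing-state
tips are unconstrained and absorbed for free); one post-order pass
computes it. A reversible (Fitch) count is available as a diagnostic
only. The exhaustive oracle enumerates subsets of candidate edges —
edges whose clade holds a nonfunctional tip and no functional tip — in
increasing cardinality; its size guard caps candidate edges (26) rather
than tips, so it also verifies large trees whose nonfunctional tips are
clustered, as in the packaged consensus tree (18 candidates).

Tip states for the packaged analysis: nonfunctional = the 13 species
whose gene carries both a frameshift and a splice mutation; functional =
species with intact coding regions; everything else missing. On the
packaged topology the strict minimum is 9 events. Published narrations
of such reconstructions sometimes merge sister superorders into a single
ancestral event; with an intact elephant nested inside Afrotheria,
strict Dollo cannot, which is why the headline claim is a lower bound
("at least six") and is tested as such.

## Relative-rate tests

Over a protein alignment, columns with a gap or X in lineage A, lineage
B, or the outgroup are excluded (complete-case deletion, which keeps the
counts integral). n_A counts columns where A differs while B and the
outgroup agree; n_B symmetrically; columns where all three differ are
informative for neither lineage and are reported separately as
uninformative. The test statistic is chi² = (n_A − n_B)²/(n_A + n_B)
with 1 df, upper-tail p from scipy; (0,0) gives chi² = 0, p = 1. No
continuity correction: the published worked values ((22−15)²/37 = 1.32,
etc.) reproduce only without it. No multiple-testing adjustment is
applied by default, matching how such test batteries are conventionally
reported; a Bonferroni column is a caller-side one-liner.

## Distances, NJ, bootstrap, rooting

p-distance is the mismatch fraction over pairwise-complete columns;
Poisson correction is −ln(1 − p) (saturated pairs, p = 1, raise).
Maximum-likelihood matrix distances (JTT/Dayhoff) are out of scope; for
the questions asked here — is a lineage's branch conspicuously long —
Poisson-corrected distances carry the same signal. Neighbor joining is
the standard Saitou–Nei agglomeration with the rate-corrected Q
criterion, deterministic tie-break on the lowest creation-order index
pair, and negative branch lengths clamped to zero for reporting
(topology unaffected); on additive matrices it recovers the generating
topology exactly, which the tests exploit, and an independent
implementation (scikit-bio) is used as a cross-check oracle. Bootstrap
resamples alignment columns with replacement; all replicate index draws
come from one seeded generator, drawn up front, so supports are
bit-reproducible; rows are canonicalised to sorted order first so
supports do not depend on input row order. Support is the percentage of
replicate NJ trees containing each original bipartition. Rooting places
the root at the midpoint of the outgroup's pendant edge and is
idempotent.

## Synthetic data generator

The generator emulates the data situation of a vertebrate pseudogene
survey. The default gene architecture matches the surveyed locus: 19
coding exons (60–150 bp, total forced to a multiple of 3, ATG start,
single terminal stop), GT–AG introns of 0.8–2.2 kb, 300 bp outer flanks
— a locus of roughly 25–30 kb. Defaults for rates: 0.02 substitutions
and 0.002 indels per site per unit branch length, geometric indel
lengths (p = 0.5), and a 2× rate multiplier on and below loss branches,
in line with the roughly twofold acceleration expected once purifying
selection ends.

On functional branches the ORF is conserved by rejection sampling:
substitutions may not create or destroy a reference-frame stop, touch
the start or terminal codon, or hit a splice dinucleotide; indels are
confined to intron interiors. On a designated loss branch, configured
disruptions are injected: frameshifting indels (lengths ≢ 0 mod 3, at
most one per exon, placed ≥ 5 bp from the junctions because attribution
of a boundary indel to exon versus intron is not well defined),
premature stops as single-base nonsense changes at reference-frame
codons of indel-free exons, and splice dinucleotide mutations. Below a
loss, splice sites and introns mutate freely, while exon substitutions
remain stop-neutral and frame-shifted exons change only through their
injected indel — a deliberate narrowing of the mutational process that
keeps the truth table exactly computable: truth per tip is read off the
generator's final state (per-exon net length change, final splice
dinucleotides, and a stop scan of the indel-undone CDS), so overlapping
and ancestral-plus-derived mutations are handled exactly.

All randomness flows through a single `numpy` generator seeded from the
configuration, consumed in pre-order traversal order: outputs are
byte-reproducible per seed.

**What passing these tests shows — and does not.** Recovery of ≥ 99% of
injected (category, exon) truth sets across 500 replicates demonstrates
that alignment, repair and attribution are correct when the orthologous
locus is colinear, moderately diverged, and fully assembled. Real data
add hazards the generator does not model: repeats and low-complexity
sequence, assembly gaps inside the locus, paralogs and processed
pseudogene copies, GC-biased substitution, rate heterogeneity across
sites, and tandem exon duplications. The residual <1% of simulated
failures are genuinely ambiguous junction cases (an indel and a splice
mutation interacting at the same boundary), which is the right mental
model for the field: exon-boundary calls are the fragile part.

**Test problem sizes.** The packaged tests run the same 19-exon
architecture with 80–160 bp introns and a compact 3-taxon tree, and the
relative-rate recovery uses 2000 sites × 100 seeds; these sizes give
stable statistics (binomial SEs well inside the asserted bands) while
keeping the suite quick. Intron length does not enter any detection
rule, so shrinking introns does not ease the task.

## Degenerate inputs and numerical conventions

Empty FASTA files, duplicate record ids, non-ACGTN characters, mixed
strands within a gene, overlapping CDS features, out-of-bounds exons,
unbalanced Newick parentheses, negative substitution counts, saturated
distances and empty species maps all raise typed errors rather than
propagating garbage. Translation maps any codon containing a non-ACGT
symbol to X. Locus spans are end − start + 1 on 1-based inclusive
coordinates; published minus-strand spans arrive end-first and are
normalised on load. Report writers emit fixed column orders and
sorted-key JSON so identical runs are byte-identical.

## Known limitations

- The scanner requires rough colinearity and a single orthologous copy;
  multi-copy loci (e.g. lineage-specific duplications) need caller-side
  disambiguation first.
- Splice assessment is the GT–AG dinucleotide rule only, not a
  position-weight-matrix score; noncanonical-but-functional sites are
  flagged, not excused.
- Exon presence thresholds (identity 0.5, coverage 0.5, score 0.2/base)
  are package conventions chosen from the measured separation between
  true and spurious placements, not field standards.
- The brute-force parsimony oracle is exponential in candidate edges;
  trees with many scattered losses exceed its guard and only the DP
  answer is available there.
- Bootstrap supports on very short alignments are dominated by the NJ
  tie-break and flagged by nothing; interpret supports on < 100 columns
  with care.
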
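# Methods

## Element vocabulary and classification

A gene model is an ordered list of exons (with CDS sub-intervals) on a
genomic contig; coordinates are stored 0-based half-open and converted
from GFF3's 1-based inclusive at the I/O boundary, so all interval
arithmetic is off-by-one-free. Exons are held in transcription order;
minus-strand genes are reported in mRNA orientation throughout
(windows, coding sequence, coordinates), which makes the architecture
of a gene identical to that of its reverse-complement mirror — a
property the test suite checks with an independent coordinate-reversal
oracle.

Elements are classified purely from geometry:

* *pre-ATG exon* — exon wholly 5' of the first coding base (combined
  length reported when several);
* *pre-ATG intron* — the 5'UTR intron immediately upstream of the first
  coding exon;
* *IG1-intron* — the **first** intron whose junction falls strictly
  inside the coding range. The definition is positional, not
  domain-based, because at least one fly gene has lost the IG1 domain
  while keeping an intron at the equivalent 5' position; positional
  classification treats both identically.
* *additional CDS introns* — every later CDS-interrupting intron, with
  its coding-nucleotide offset.

An intron whose junction coincides exactly with the CDS start or end is
a UTR intron (it does not interrupt the coding sequence). Genes without
CDS raise a "non-coding gene" error; abutting exons raise "degenerate
intron"; a CDS length that is not a codon multiple flags the record
`truncated_annotation` instead of failing, since several catalogued
genomes are annotated only to the stop codon or are 5'-incomplete.
When a gene has several mRNAs, the transcript with the longest CDS is
used (ties: leftmost), matching the one-gene-model-per-species design
of the comparative table.

## Intron phase and protein coordinates

`phase = cds_offset mod 3`, where `cds_offset` counts coding
nucleotides 5' of the junction (UTR portions of exons excluded). A
phase-0 intron falls between codons: `residue_before = cds_offset / 3`
and `residue_after = residue_before + 1`. Phase 1/2 introns split codon
`residue_before + 1` and carry a `codon_split` flag. Under this
convention the human gene's 401-bp ATG exon with a 116-nt 5'UTR yields
285 coding nt = 95 codons before the first CDS intron — insertion
between residues 95 and 96, phase 0 — which is the one externally
anchored coordinate in the packaged data.

Domain register uses the insertion point `residue_before + 0.5` against
feature intervals `[start − 0.5, end + 0.5]`: `at_boundary` within
`boundary_tolerance` residues (default 2) of a feature end, otherwise
`within` the smallest containing feature, otherwise `inter_domain`.
The packaged human domain table is a synthetic convention (the file and
its header say so): feature order follows the canonical DG domain
layout, but only the fact that the 95/96 site lies inside IG1, in the
middle of the third β-strand, is anchored; exact ranges are fixture
choices.

MSA projection counts non-gap characters of one row: the column at
which the count reaches the residue index. Single-linkage clustering of
projected columns (tolerance 2 columns, exposed as config) groups
introns whose insertion sites are positionally homologous; tolerance 2
absorbs alignment wobble at the scale of the 15-residue flanks
typically inspected around junctions. Group ids derive from the
leftmost member column, so clustering is deterministic,
permutation-invariant and idempotent.

## Splice junctions

Junction windows are contiguous genomic slices spanning the junction
(width 50 nt, junction centred by default). The exon/intron split
within the window is configurable because the published 50-nt window
convention does not fix it; 25/25 is the symmetric default. Windows are
clipped (and flagged) only at contig ends. Classification flags are
`donor_gt` (intron starts GT), `acceptor_ag` (intron ends AG) and
`exonic_ag` (exon ends AG), with `aggt = exonic_ag AND donor_gt`;
ambiguous bases at a diagnostic position make the flag indeterminate
rather than false. Summaries report GT–AG compliance and AGGT
compliance separately and list exception species per side, because the
two junction sides have distinct exception sets in real data.

The miRNA seed scan normalises U↔T, requires an unambiguous 7-mer and
returns every window within the Hamming budget sorted by position then
distance.

## Parsimony

Characters are binary presence/absence per intron homology group;
`unknown` entries (species whose relevant gene region cannot be
resolved from the annotation, e.g. uncertain structure 5' of the ATG)
are pruned per character, never imputed.

*Fitch* is implemented as unit-cost Sankoff: exact minimum change
count, plus an exact count of co-optimal labelings by dynamic
programming. The reported labeling is deterministic: the root prefers
"absent" on ties and each node prefers its parent's state.

*Dollo* allows one origin per character: the gain sits on the branch
above the MRCA of the present tips, and losses on the minimal branch
set whose subtrees contain only absent (or unknown) known tips. The
change count is defined as the number of state-change *edges* — a
character present in every tip originates on the root stem and costs 0
edges (the root-stem origin is still reported as a "gain" event). With
this definition Dollo counts agree with an exhaustive enumeration over
single-origin labelings, and Fitch ≤ Dollo holds by construction. Both
are verified against exhaustive oracles (all 2^(internals) labelings on
6-leaf trees, 200 random characters).

The packaged tree is a rooted 35-species cladogram (no branch lengths)
following the standard phylum-level backbone: sponge basal, then
placozoan, cnidarians, and bilaterians split into protostomes
(ecdysozoans: nematodes + arthropods; lophotrochozoans: molluscs +
annelids) and deuterostomes (ambulacrarians + chordates). Ctenophores
are excluded — no dystroglycan gene has been identified in them.
Internal nodes carry clade labels (`Ecdysozoa`, `Bilateria`, …) so that
event branches are stable, human-readable identifiers; unlabeled nodes
get a canonical smallest-leaf signature invariant under tip reordering.
The tree is config-replaceable.

## Scaling

Semi-log fits are OLS on log10-transformed coordinates. Because the
published plots do not state which axis is logarithmic, the default is
log-x (intron size linear in log10 predictor) and the pipeline always
computes all three variants (log-x, log-y, log-log) so a supplied
genome-size table can be matched under any convention. Genome sizes
are an external TSV; the package ships none, so the published R²
values (0.68 against genome size, 0.75 against gene size) are not
recomputable offline — the substitute checks are generator-truth
recovery (slope/intercept within 3 SE at n = 35) and a perfect fit on
noiseless data. Spearman rho uses midranks; its p-value comes from
≥ 9,999 seeded label permutations (two-sided, +1 corrected), verified
against exhaustive permutations at small n.

## Synthetic data: what it does and does not emulate

The packaged table (39 records: 35 species + 4 fish/lamprey paralogue
genes) transcribes recorded element lengths, additional-intron counts
and completeness footnotes. Three rows are flagged `low_confidence`
because their numeric cells could not be parsed unambiguously; one of
them is additionally internally inconsistent with the stated 47-bp
minimum intron size, so low-confidence rows are excluded from min/max
summaries (the 47-bp sponge minimum and 30,785-bp platypus maximum are
computed over the remaining 32 species).

Free quantities the table cannot pin down are fixed deterministically
from the seed and documented as conventions:

* 5'UTR offset inside the ATG exon: 116 nt for human (derived from the
  95/96 insertion), otherwise 0 — except that for records annotated
  only to the stop codon the mod-3 remainder of the exon sum is
  absorbed into a 0–2 nt offset so the CDS translates cleanly.
* 3'UTR: about a quarter of the terminal exon (nudged to a codon
  boundary) when the record has a 3'UTR; zero otherwise.
* Combined columns are split near-evenly into their exon pieces;
  unprinted additional-intron lengths are drawn from 80–300 bp
  (2–5 kb where the record calls them "large").
* Additional 5' introns are realised as CDS introns between the start
  codon and the recorded IG1-intron (the record says they interrupt
  N-terminal coding sequence and that those annotations start at the
  ATG). For those three genes the positional "first CDS intron" is an
  additional intron, so the table renderer recovers the recorded
  IG1-intron as CDS intron number `n_additional_5p` — the recorded
  combined ATG-side exon length is likewise the sum of the pieces.
* Filler sequence is uniform ACGT (GC 0.5); coding sequence is built
  from non-stop codons (ATG … TAA), so translation oracles work;
  introns are GT..AG unless a violation is sampled (a violating intron
  corrupts its donor or acceptor dinucleotide, 50/50). Exon-terminal
  AG is *not* enforced — overwriting coding bases at junctions could
  corrupt codons — so AGGT compliance of fixtures reflects base
  composition, while GT–AG compliance reflects the violation rate.

Fixtures are bit-stable for a given seed. They emulate gene *geometry*
with random filler: no sequence homology between species, no codon
usage, no substitutions/indels, no alternative isoforms, no real splice
regulatory context. Tests passing on fixtures therefore validate
coordinate arithmetic, classification and reconstruction logic — not
the ability to align or annotate real genomes. Likewise the "anchor
MSA" used to exercise projection is a constructed alignment in which
each species' insertion residue shares a column by design; it validates
the projection/clustering machinery, not alignment quality.

The evolution simulator gains introns as Poisson events per branch
(rate × branch length, length 1 on the cladogram) at fresh uniform
coding offsets — each gained intron is a unique character, so
histories with losses disabled are homoplasy-free and exactly
recoverable by Dollo (checked over 100 seeded replicates). Losses
remove whole introns with probability 1 − exp(−rate × length). Intron
lengths for written tip genes are log-normal with median a·g^b of
genome size (defaults a = 0.02, b = 0.7, σ = 0.4 on the log scale,
floored at 30 bp just under the smallest observed intron). The
intron-size simulator mirrors the semi-log regression model directly.

## Problem sizes and numerics

Default study sizes: 39 gene fixtures; 200 random characters on 6-leaf
trees against exhaustive oracles; 100 evolution replicates for Dollo
recovery; 500 simulated introns at violation rate 0.2 for the
boundary-rate estimate (binomial-CI check); n = 35 size records for
regression recovery; 9,999 permutations for rank-correlation p-values.
These sizes make the whole suite run in seconds while keeping
Monte-Carlo error far below the decision thresholds. All randomness
flows through seeded numpy generators; per-species streams are derived
by hashing the seed with the species code, so adding or removing one
record does not shift another's sequence.

## Known limitations

* Ortholog discovery, alignment computation (MUSCLE/MAFFT) and genome
  retrieval are out of scope: alignments, trees and domain tables are
  consumed as files.
* `cds_offset` assumes a single contiguous coding range per transcript
  (true for every model produced here); genes with trans-splicing or
  ribosomal frameshifts would need per-segment accounting.
* Dollo's minimal-loss placement can merge two sibling losses into one
  parental loss; simulated histories with losses are therefore scored
  on counts, and exact branch recovery is only guaranteed for
  homoplasy-free (gain-only) histories.
* The gnathostome-vs-rest size comparison is reported as medians and a
  strict min>max flag; on the packaged data the ranges overlap (a
  cephalochordate intron exceeds several fish introns), so the strict
  flag is false while the median contrast is large.
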
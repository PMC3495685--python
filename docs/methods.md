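# Methods

This note documents the models, heuristics, parameters, and numerical
choices behind `straincomp`, and what the synthetic validation does and
does not demonstrate about real data.

## Problem setting

Two strains of one bacterial species, sequenced and annotated
independently, are separated by (i) point substitutions at a density of a
few per kb, concentrated in non-coding DNA and at synonymous codon
positions, (ii) a small number of short indels, and (iii) strain-specific
multi-gene cassettes — mobile-element islands present in one genome only.
The pipeline quantifies all three classes of difference and classifies
every ortholog by how much its protein changed.

## Whole-genome alignment

The two chromosomes are assumed syntenic with no large-scale
rearrangements or inversions — the situation for which a collinear
aligner is adequate. For genome pairs that violate this assumption, an
externally produced XMFA alignment (e.g. from a rearrangement-aware
aligner) can be supplied and the alignment stage is skipped.

1. **Anchoring** — *k*-mers (default *k* = 15) occurring exactly once in
   each genome seed exact matches; seeds on the same diagonal merge into
   maximal runs. Unique-*k*-mer seeding is simpler than spaced seeds and
   is adequate at ≲2% divergence, where unique 15-mers occur every few
   tens of bases.
2. **Chaining** — a weighted longest-increasing-subsequence over
   (a, b) start positions keeps the maximum-total-length collinear subset
   (Fenwick-tree DP, *O*(n log n)); equal-weight ties resolve to the
   chain whose first anchor has the smaller A-coordinate. Overlapping
   neighbours are trimmed.
3. **Gap closure** — inter-anchor gaps up to `max_gap_fill` (default
   5000 bp) are aligned globally with affine gaps under the published
   HOXD70 substitution matrix (match 91/100, mismatches −31…−125, gap
   open 400, extend 30), the standard scoring for diverged genomic DNA.
   Larger gaps split the alignment into separate blocks and the
   intervening sequence is classified unaligned — this is what cassette
   insertions produce, and it feeds the strain-specific region logic.

Because equal-length gap segments can never profitably open paired gaps
under these scores (two gap opens cost 860 against at most ~250 for two
mismatches), SNP-only divergence yields mismatch columns at exactly the
substituted positions; this is what makes exact ground-truth recovery a
fair test of the caller rather than of the aligner's tie-breaking.

## Orthologs

Two independent methods, then reconciliation:

- **Synteny**: a gene's interval is mapped through the alignment; it
  pairs with the gene in the other strain whose CDS it overlaps
  reciprocally by ≥50% of each gene's length (one-to-one enforced by
  largest overlap, ties toward the smaller coordinate). The 50%
  reciprocal-overlap rule is this package's operationalization of
  "predicted from the alignment".
- **Reciprocal best hit (RBH)**: exact Smith–Waterman over all protein
  pairs (BLOSUM62, gap open 11, extend 1 — the classic protein-search
  scoring), a pair kept only when each protein is the other's *unique*
  best score. Identical paralog families tie and yield no pair, which is
  the desired conservative behaviour. For proteome pairs larger than
  ~50×50 an exact-scoring shortlist is built first from shared 5-mer
  counts (≥5 shared words), in the spirit of word-seeded search; at the
  ≥98% identity typical of strain pairs the true partner always shares
  hundreds of 5-mers, while unrelated proteins almost never reach five.
- **Reconciliation**: pairs found by both methods are accepted
  unconditionally. Single-method pairs must align over ≥50% of the longer
  protein at ≥30% identity, identity being identical columns over aligned
  columns (the separate coverage criterion is why identity is not
  normalized by length). Conflicts keep the two-method pair, then the
  higher identity. Pseudogenes pair on nucleotide synteny alone.

**Strain-specific regions** are maximal runs of ≥2 consecutive genes with
no accepted ortholog. Borders are classified by scanning the run plus one
flanking gene for transposase/integrase products and the flanking ±500 bp
for tRNA and repeat features; the one-gene/500-bp windows are this
package's choice where the underlying idea ("bordered by or contain") has
no stated distance.

## Variants and effects

One variant per mismatch column; a maximal gap run is a single
insertion/deletion event anchored at its left flank. Sites with N in
either track are masked and tallied, not called.

Coding SNPs are classified under translation table 11 by mutating the
reference-strain codon **at the SNP's position only**, holding the other
two positions at the reference state even if they also differ, and
comparing the translations. This "each position independently" rule is
order-independent, unlike sequential application, which is why the
alternative was rejected. Stop gains/losses count as non-synonymous. SNPs
in codons disrupted by an indel, or in pseudogenes, are `not_classified`.

Per-gene statistics use the full CDS length (stop codon included) as the
per-kb denominator. The heavily-mutated cutoff defaults to the applied
integer value of 12 NS SNP/kb (two population SDs above the ortholog-wide
mean in the regime this pipeline targets; the companion whole-gene cutoff
is 34 SNP/kb); `OutlierThresholds(recompute=True)` switches to
mean + k·SD computed from the data at hand, with the SD taken over **all**
orthologs including zero-SNP genes (population SD; the choice is recorded
in output metadata because reasonable conventions differ).

Genome-wide rates divide SNP counts by the strain-A CDS footprint (union
of CDS intervals) and its complement. Note that strain-specific cassette
DNA enlarges this footprint while carrying no pairwise SNPs, so
strain-relative rates sit slightly below the divergence-process rates;
validation therefore measures rate recovery over the shared (ancestral)
footprint.

## CXXCH census

A pure pattern scan: every occurrence of C-x-x-C-H, overlaps included
(an overlap-free biochemical prior would make the scan annotation-aware;
keeping it a pattern count keeps it reproducible). The longer-spacer
heme motifs (CX₃CH, CX₄CH) are deliberately not matched. Reducing motif
proteins to curated cytochromes requires functional judgement and is
supported only through a user-supplied exclusion list.

## Start-site reconciliation

For homologous genes sharing a stop but not a start, the cascade is:
(1) exactly one candidate has a plausible ribosome-binding site → take
it; (2) otherwise, if signal peptides are detected, take the start that
places the signal peptide nearer the N-terminus; (3) otherwise the longer
ORF. The RBS detector scores the longest contiguous substring of the
Shine–Dalgarno consensus AGGAGG found in the −20..−5 window (threshold
≥4). The signal-peptide detector is a deliberately lightweight stand-in
for SignalP-class tools: the first 8-residue window after the initiator
methionine, within the N-terminal 40 residues, with mean Kyte–Doolittle
hydropathy strictly above 1.5. The precedence of RBS over signal peptide
is one consistent reading of a loosely ordered procedure; both the order
and the thresholds are configuration-exposed.

## EASE enrichment

The EASE score removes one gene from the overlap cell of the 2×2 table
and computes the one-sided Fisher upper tail — equivalently the
hypergeometric tail P(X ≥ h−1) for a draw of (list−1) genes — so a
category supported by a single gene can never appear enriched. No
multiple-testing correction is applied by default (fixed α cutoffs of
0.05/0.01 are the convention this mirrors); Benjamini–Hochberg can be
layered on by the caller. Unannotated genes remain in the background
totals. Test sets below 100 genes trigger a warning, not an error.

## The synthetic-data generator

The generator is the validation instrument: it produces an ancestor and
two descendants with complete ground truth.

**Ancestor.** Genes (lengths ≈ N(900, 225²) bp, codon-multiple, ≥60)
are packed with exponential-length intergenic gaps (≥30 bp) — roughly the
geometric gap-length distribution of gene-dense genomes — to the
requested ~90% coding density. Each CDS has a bacterial start (ATG/GTG/
TTG at 0.80/0.15/0.05), no internal stop, a stop codon, and a planted
AGGAGG in its −15..−5 window. Background composition is i.i.d. at the
requested GC (default 61%); there is no codon-usage model — sufficient
for exercising every downstream operation, but not a basis for
codon-level selection inference. Designated cytochrome genes carry an
exact number of CXXCH motifs (backbone kept C/H-free so the count is
exact); all other proteins are scrubbed of accidental CXXCH so the
planted census is the whole census. tRNAs sit in large gaps; transposase
genes are flagged by product.

**Divergence.** Each descendant independently receives half the
configured pairwise rates, so the A-vs-B comparison recovers them. Key
constructions:

- Substitutions are planted in **disjoint codons between the strains**
  (and at most once per codon position), so every pairwise difference has
  a well-defined effect label; codons hit more than once within one
  strain are re-labelled with the same one-position-at-a-time rule the
  caller uses. Start and stop codons are left untouched, and mutations
  that would create a premature stop or change a protein's local CXXCH
  count are resampled — the generator realizes the regime the analysis
  assumes (readable frames, conserved heme counts) rather than testing
  annotation repair.
- The target effect of each coding SNP is sampled first (synonymous with
  the configured probability) and then realized by choosing among the
  single-base changes with that effect; impossible requests (e.g. no
  synonymous change exists for ATG/TGG at the sampled position) resample
  the site, never mislabel.
- **Heavy genes** (default 3.6% of genes) receive forced non-synonymous
  substitutions until ≥12 NS/kb. These are drawn from, not added on top
  of, the overall coding budget, and the synonymous probability of the
  remaining background is raised so the expected overall silent fraction
  stays at the configured 72% — without this the pairwise rate, the
  silent fraction, and the heavy tail could not hold simultaneously, and
  all three are measured.
- **Cassettes** (default 4 per strain, 2–8 genes) are inserted whole at
  well-separated intergenic anchors; two-thirds carry a border feature
  (transposase : tRNA : repeat at 8 : 3 : 1, the ratio observed among
  bordered islands in this kind of strain pair). A margin of ±60 bp
  around each anchor is kept variant-free so cassette boundaries and
  substitutions cannot interact in the alignment.
- **Indels** (events per kb small, default 0.05; length ≤12) go to
  intergenic DNA except for a 20% share placed in the final 10% of a
  minority of non-cytochrome genes to create frameshift cases. Validation
  of exact SNP coordinates uses `indel_rate=0`, since indel placement
  inside homopolymers is alignment-ambiguous by nature; with indels on,
  event *counts* are the tested contract.

**What passing tests show, and what they do not.** Ground-truth recovery
at 1 Mb / ~0.7% divergence shows the pipeline's bookkeeping is exact in
the regime it targets: no coordinate drift, no effect mislabeling, no
false ortholog pairs, exact heavy-gene and region detection. It does not
exercise: rearrangements/inversions (out of scope by design), repeat
families dense enough to exhaust unique 15-mers, codon-usage or
GC-skew structure, rRNA operons, or the manual curation steps of real
re-annotation (functional exclusion lists, start-site judgement calls).
On real deposited genome pairs, counts will further differ from any
manually refined published alignment for the unaligned-region and
gap-placement reasons above; the pipeline documents this deviation rather
than targeting equality.

## Determinism and problem sizes

Every stochastic step flows from a single integer seed through one
`numpy` generator; identical seeds give byte-identical outputs. The
shipped validation uses a 1 Mb genome with 1000 genes (≈¼ of a typical
small bacterial chromosome) — large enough for three-SD statistical
bands of ±0.26/kb (coding rate) and ±1.7 points (silent fraction), small
enough to run the full pipeline in well under a minute on one core.
Alignment memory is dominated by the two k-mer indexes (~a few hundred
MB at 1 Mb).

## Known limitations

- Forward-strand collinear alignment only; inversions are reported as
  unaligned, not aligned in reverse.
- Single-contig, non-origin-spanning features only.
- The RBH 5-mer shortlist is a heuristic: a true best hit sharing fewer
  than five 5-mers with its partner (< ~40% identity) would be missed;
  such pairs are below the reconciliation identity floor anyway.
- dN/dS with per-site substitution-opportunity normalization is out of
  scope — non-synonymous counts are raw densities.
- The signal-peptide and RBS detectors are screening heuristics, not
  predictors of experimental accuracy.
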
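# straincomp

Comparative genomics of two closely related bacterial strain genomes —
the "same species, different phenotype" setting in which a handful of
substitutions and a few mobile cassettes separate two deposited genomes
and the question is *which genes changed, how much, and in what way*.

Given two annotated genomes (FASTA + GFF3/GenBank), or a simulated pair
with known ground truth, `straincomp` produces:

- a **collinear whole-genome alignment** (unique-*k*-mer anchors, weighted
  longest-increasing-subsequence chaining, HOXD70 affine-gap closure), or
  ingests an external XMFA alignment;
- **orthologs by two independent methods** — synteny (reciprocal ≥50%
  interval overlap through the alignment) and reciprocal best hit (exact
  Smith–Waterman, BLOSUM62, gap 11/1) — reconciled so that single-method
  pairs must cover ≥50% of the longer protein at ≥30% identity;
- **SNPs and small indels** (one variant per mismatch column, one event
  per gap run) with synonymous/non-synonymous classification under
  translation table 11; in a codon carrying several changes each position
  is evaluated independently against the reference-strain codon;
- **per-gene categories** — identical, silent-only, mutated, heavily
  mutated (≥ 12 non-synonymous SNP/kb, i.e. two population SDs above the
  ortholog-wide mean), no ortholog — and per-class summary tables;
- a **c-type cytochrome census**: every CXXCH heme-binding motif per
  protein, and motif-count conservation across ortholog pairs;
- **strain-specific regions**: runs of ≥2 consecutive ortholog-less genes,
  with transposase/integrase, tRNA, and repeat border classification;
- **start-site reconciliation** for homologous genes with discrepant
  starts (ribosome-binding site → signal peptide position → longer ORF);
- **EASE-score enrichment** (the conservative one-sided Fisher variant
  that discounts one overlap gene) of gene sets against a whole-genome
  background.

The `synthetic_data` module is first-class: it generates an ancestral
genome and a diverged pair whose statistics match the regime the analysis
assumes (pairwise 6.8 coding / 10.5 non-coding SNP/kb, 72% silent coding
changes, a 3.6% heavy-gene tail, bordered multi-gene cassettes, motif-
preserving cytochrome divergence), together with complete ground truth
for validation.

## Worked example

```python
from straincomp.synthetic_data import GenomeSpec, DivergenceParams, generate_ancestor, diverge
from straincomp.genome_align import align_genomes
from straincomp import orthology, variants

ancestor = generate_ancestor(GenomeSpec(genome_length=100_000), seed=1)
a, b, truth = diverge(ancestor, DivergenceParams(seed=2, indel_rate=0.0))

blocks = align_genomes(a.sequence, b.sequence)
called, _ = variants.call_variants(blocks, a, b)
variants.classify_variants(called, a, b)

snps = [v for v in called if v.kind == "snp"]
syn = sum(1 for v in snps if v.effect == "synonymous")
coding = sum(1 for v in snps if v.gene_id is not None)
print(len(snps), coding, f"{100 * syn / coding:.1f}%")
```

prints

```
738 613 71.9%
```

— 738 SNPs called between the strains (identical to the planted set), of
which 613 fall in coding sequence, and 71.9% of the coding changes are
silent, matching the configured silent fraction of the divergence
process.

The same analysis from the shell:

```bash
straincomp simulate --seed 1 --genome-length 100000 --out sim/
straincomp align sim/strainA.fasta sim/strainB.fasta -o sim/aln.xmfa
straincomp run config.yaml -o report/   # full pipeline from a YAML config
```

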
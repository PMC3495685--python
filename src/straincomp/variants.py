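"""SNP/indel calling from the alignment and effect classification.

A mismatch column is one SNP; a maximal gap run is one insertion/deletion
event.  Coding SNPs are classified synonymous/non-synonymous under
translation table 11 by mutating the strain-A codon at the SNP's position
only, holding the other two positions at the strain-A state even when they
also differ ("each change in a triplet considered independently") —
sequential application is rejected as order-dependent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .model import (
    CODON_TABLE_11,
    AlignmentBlock,
    AnnotatedGenome,
    GeneModel,
    OrthologTable,
    Variant,
)

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class OutlierThresholds:
    """Cutoffs for the heavily-mutated gene category.

    Defaults are the rounded integers actually applied in practice for a
    strain pair at this divergence (12 NS SNP/kb, 34 SNP/kb, both two
    population SDs above the ortholog-wide mean); ``recompute`` switches to
    the mean + k_sd * SD value computed from the data at hand.
    """

    ns_per_kb_cutoff: float = 12.0
    total_per_kb_cutoff: float = 34.0
    k_sd: float = 2.0
    recompute: bool = False


@dataclass
class GeneVariantSummary:
    gene_id: str
    gene_id_b: str
    length: int
    total_snp: int
    ns_snp: int
    syn_snp: int
    indels: int
    ns_per_kb: float
    protein_identity: float
    category: str  # no_ortholog|identical|silent_only|mutated|heavily_mutated


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

def call_variants(
    blocks: list[AlignmentBlock],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome | None = None,
) -> tuple[list[Variant], int]:
    """One Variant per mismatch column / maximal gap run.

    Returns (variants, n_masked) where n_masked counts columns skipped
    because either track carried an N.  Variants are classified in place
    when ``genome_a`` has gene annotations (see :func:`classify_variants`).
    """
    variants: list[Variant] = []
    n_masked = 0
    for blk in blocks:
        a_pos = blk.a_start - 1  # position of last consumed A base
        b_pos = blk.b_start - 1
        gap_a: list[str] = []  # B-only bases (insertion relative to A)
        gap_b: list[str] = []  # A-only bases (deletion relative to A)
        gap_anchor: tuple[int, int] | None = None
        for ca, cb in zip(blk.a_gapped, blk.b_gapped):
            if ca != "-" and cb != "-":
                if gap_a or gap_b:
                    variants.extend(_flush_gap(gap_a, gap_b, gap_anchor))
                    gap_a, gap_b = [], []
                a_pos += 1
                b_pos += 1
                if ca == "N" or cb == "N":
                    n_masked += 1
                elif ca != cb:
                    variants.append(Variant(a_pos, b_pos, "snp", ca, cb))
            elif ca == "-":
                if not (gap_a or gap_b):
                    gap_anchor = (a_pos, b_pos)
                b_pos += 1
                gap_a.append(cb)
            else:
                if not (gap_a or gap_b):
                    gap_anchor = (a_pos, b_pos)
                a_pos += 1
                gap_b.append(ca)
        if gap_a or gap_b:
            variants.extend(_flush_gap(gap_a, gap_b, gap_anchor))
    variants.sort(key=lambda v: (v.pos_a, v.pos_b))
    return variants, n_masked


def _flush_gap(gap_a: list[str], gap_b: list[str], anchor) -> list[Variant]:
    out = []
    pa, pb = anchor
    if gap_a:  # bases present only in B
        out.append(Variant(pa, pb, "insertion", "", "".join(gap_a), effect="indel"))
    if gap_b:  # bases present only in A
        out.append(Variant(pa, pb + len(gap_a), "deletion", "".join(gap_b), "", effect="indel"))
    return out


def _gene_tree(genome: AnnotatedGenome) -> IntervalTree:
    tree = IntervalTree()
    for g in genome.genes:
        tree[g.start : g.end + 1] = g
    return tree


def classify_variants(
    variants: list[Variant],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
) -> list[Variant]:
    """Assign gene ids and effects to called variants (strain A frame)."""
    tree = _gene_tree(genome_a)
    indel_genes = {
        iv.data.gene_id
        for v in variants
        if v.kind != "snp"
        for iv in tree.overlap(v.pos_a, v.pos_a + max(1, len(v.ref)))
    }
    for v in variants:
        hits = sorted(tree[v.pos_a], key=lambda iv: iv.data.start)
        if v.kind != "snp":
            if hits:
                v.gene_id = hits[0].data.gene_id
            continue
        if not hits:
            v.effect = "noncoding"
            continue
        gene = hits[0].data
        v.gene_id = gene.gene_id
        if gene.pseudo or gene.gene_id in indel_genes:
            v.effect = "not_classified"
            continue
        v.effect = classify_coding_snp(v, gene, genome_a)
    return variants


def classify_codon_change(codon_a: str, pos: int, alt: str) -> str:
    """Effect of substituting ``alt`` at ``pos`` (0-based) of a strain-A codon."""
    mutated = codon_a[:pos] + alt + codon_a[pos + 1 :]
    return (
        "synonymous"
        if CODON_TABLE_11[codon_a] == CODON_TABLE_11[mutated]
        else "nonsynonymous"
    )


def classify_coding_snp(snp: Variant, gene: GeneModel, genome_a: AnnotatedGenome) -> str:
    """Synonymous/non-synonymous call for a SNP inside a non-pseudo CDS.

    Strand-aware: for reverse-strand genes the codon is read off the coding
    strand and the alternate allele is complemented.
    """
    if gene.strand == "+":
        off = snp.pos_a - gene.start
        alt = snp.alt
    else:
        off = gene.end - snp.pos_a
        alt = _COMP[snp.alt]
    codon_idx, codon_pos = divmod(off, 3)
    cds = genome_a.cds_nt(gene)
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    return classify_codon_change(codon, codon_pos, alt)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def outlier_threshold(per_gene_rates: list[float], k_sd: float = 2.0) -> float:
    """mean + k_sd * population SD over all ortholog genes (zeros included)."""
    if len(per_gene_rates) < 2:
        raise ValueError("need at least two genes to estimate an outlier threshold")
    arr = np.asarray(per_gene_rates, dtype=float)
    return float(arr.mean() + k_sd * arr.std(ddof=0))


def summarize_genes(
    variants: list[Variant],
    table: OrthologTable,
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    thresholds: OutlierThresholds | None = None,
) -> list[GeneVariantSummary]:
    """Per-ortholog variant counts and the five-way gene category.

    Categories (mutually exclusive): no_ortholog, identical (0 SNP),
    silent_only (SNPs but no NS), heavily_mutated (NS/kb >= cutoff),
    mutated.  Genes without an ortholog are listed but excluded from SNP
    statistics.
    """
    thresholds = thresholds or OutlierThresholds()
    per_gene: dict[str, list[Variant]] = {}
    for v in variants:
        if v.gene_id is not None:
            per_gene.setdefault(v.gene_id, []).append(v)

    summaries: list[GeneVariantSummary] = []
    rates = []
    rows = []
    for g in sorted(genome_a.genes, key=lambda g: g.start):
        pair = table.by_a.get(g.gene_id)
        vs = per_gene.get(g.gene_id, [])
        snps = [v for v in vs if v.kind == "snp"]
        ns = sum(1 for v in snps if v.effect == "nonsynonymous")
        syn = sum(1 for v in snps if v.effect == "synonymous")
        indels = sum(1 for v in vs if v.kind != "snp")
        ns_per_kb = 1000.0 * ns / g.length
        rows.append((g, pair, len(snps), ns, syn, indels, ns_per_kb))
        if pair is not None:
            rates.append(ns_per_kb)
    cutoff = thresholds.ns_per_kb_cutoff
    if thresholds.recompute:
        cutoff = outlier_threshold(rates, thresholds.k_sd)
    for g, pair, total, ns, syn, indels, ns_per_kb in rows:
        if pair is None:
            category = "no_ortholog"
        elif total == 0:
            category = "identical"
        elif ns == 0:
            category = "silent_only"
        elif ns_per_kb >= cutoff:
            category = "heavily_mutated"
        else:
            category = "mutated"
        summaries.append(
            GeneVariantSummary(
                gene_id=g.gene_id,
                gene_id_b=pair.gene_b if pair else "",
                length=g.length,
                total_snp=total,
                ns_snp=ns,
                syn_snp=syn,
                indels=indels,
                ns_per_kb=ns_per_kb,
                protein_identity=pair.protein_identity if pair else 0.0,
                category=category,
            )
        )
    return summaries


def genome_rates(
    variants: list[Variant], genome_a: AnnotatedGenome
) -> tuple[float | None, float | None, float | None]:
    """(coding SNP/kb, noncoding SNP/kb, intragenic fraction of SNPs).

    Classes are defined by the union of strain-A CDS intervals; each SNP
    counts once for genome-wide statistics even if it falls in two
    overlapping genes.  A zero-length class yields None for its rate.
    """
    spans = sorted((g.start, g.end) for g in genome_a.genes)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    coding_len = sum(e - s + 1 for s, e in merged)
    noncoding_len = genome_a.length - coding_len
    starts = [s for s, _ in merged]
    ends = [e for _, e in merged]
    snps = [v for v in variants if v.kind == "snp"]
    import bisect

    def in_cds(p: int) -> bool:
        i = bisect.bisect_right(starts, p) - 1
        return i >= 0 and p <= ends[i]

    n_in = sum(1 for v in snps if in_cds(v.pos_a))
    n_out = len(snps) - n_in
    coding_rate = 1000.0 * n_in / coding_len if coding_len else None
    noncoding_rate = 1000.0 * n_out / noncoding_len if noncoding_len else None
    frac = n_in / len(snps) if snps else None
    return coding_rate, noncoding_rate, frac
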
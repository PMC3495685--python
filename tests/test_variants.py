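"""Variant calling, effect classification, and per-gene statistics."""
import math

import pytest

from straincomp.model import AlignmentBlock, AnnotatedGenome, GeneModel, OrthologTable, OrthologPair, Variant, revcomp
from straincomp.variants import (
    OutlierThresholds,
    call_variants,
    classify_codon_change,
    classify_coding_snp,
    classify_variants,
    genome_rates,
    outlier_threshold,
    summarize_genes,
)


def _block(sa, sb, a_start=1, b_start=1):
    return AlignmentBlock(
        a_start, a_start + len(sa.replace("-", "")) - 1,
        b_start, b_start + len(sb.replace("-", "")) - 1,
        sa, sb,
    )


def test_identical_sequences_no_variants():
    variants, masked = call_variants([_block("ACGTACGT", "ACGTACGT")], None)
    assert variants == [] and masked == 0


def test_single_mismatch_column():
    variants, _ = call_variants([_block("ACGTACGT", "ACGAACGT")], None)
    assert len(variants) == 1
    v = variants[0]
    assert (v.pos_a, v.pos_b, v.kind, v.ref, v.alt) == (4, 4, "snp", "T", "A")


def test_gap_run_collapses_to_one_event():
    variants, _ = call_variants([_block("ACG---TACGT", "ACGGGGTACGT")], None)
    assert len(variants) == 1
    v = variants[0]
    assert (v.kind, v.pos_a, v.alt) == ("insertion", 3, "GGG")
    variants, _ = call_variants([_block("ACGGGGTACGT", "ACG---TACGT")], None)
    assert len(variants) == 1
    assert (variants[0].kind, variants[0].pos_a, variants[0].ref) == ("deletion", 3, "GGG")


def test_n_columns_masked_not_called():
    variants, masked = call_variants([_block("ACNTACGT", "ACGTACGA")], None)
    assert masked == 1
    assert len(variants) == 1 and variants[0].pos_a == 8


@pytest.mark.parametrize(
    "codon,pos,alt,expect",
    [
        ("GCT", 2, "C", "synonymous"),  # Ala -> Ala
        ("GCT", 0, "C", "nonsynonymous"),  # Ala -> Pro
        ("AAA", 0, "G", "nonsynonymous"),  # Lys -> Glu
        ("AAA", 2, "G", "synonymous"),  # Lys -> Lys
        ("TAC", 2, "A", "nonsynonymous"),  # stop gain counts as nonsynonymous
    ],
)
def test_codon_change_examples(codon, pos, alt, expect):
    assert classify_codon_change(codon, pos, alt) == expect


def test_multi_snp_codon_positions_evaluated_independently():
    # strain A codon AAA vs strain B codon GAG: position 1 is NS, position 3 syn
    genome_a = AnnotatedGenome("A", "ATGAAATAA", [GeneModel("g", 1, 9, "+")])
    snp1 = Variant(4, 4, "snp", "A", "G")
    snp3 = Variant(6, 6, "snp", "A", "G")
    gene = genome_a.genes[0]
    assert classify_coding_snp(snp1, gene, genome_a) == "nonsynonymous"
    assert classify_coding_snp(snp3, gene, genome_a) == "synonymous"


def test_reverse_strand_classification_mirrors_forward():
    fwd = AnnotatedGenome("A", "ATGGCTTAA", [GeneModel("g", 1, 9, "+")])
    snp_f = Variant(6, 6, "snp", "T", "C")  # GCT -> GCC, synonymous
    assert classify_coding_snp(snp_f, fwd.genes[0], fwd) == "synonymous"
    rev = AnnotatedGenome("A", revcomp("ATGGCTTAA"), [GeneModel("g", 1, 9, "-")])
    snp_r = Variant(4, 4, "snp", "A", "G")  # the same change on the mirrored genome
    assert classify_coding_snp(snp_r, rev.genes[0], rev) == "synonymous"


def test_called_snps_equal_truth_exactly(small_sim, small_blocks):
    _, a, b, truth = small_sim
    called, masked = call_variants(small_blocks, a, b)
    classify_variants(called, a, b)
    snps = [v for v in called if v.kind == "snp"]
    assert masked == 0
    assert {(v.pos_a, v.pos_b, v.ref, v.alt) for v in snps} == {
        (v.pos_a, v.pos_b, v.ref, v.alt) for v in truth.snvs
    }
    by_pos = {v.pos_a: v.effect for v in truth.snvs}
    assert all(v.effect == by_pos[v.pos_a] for v in snps)


def test_outlier_threshold_population_sd():
    assert outlier_threshold([0, 0, 2, 4], k_sd=2) == pytest.approx(1.5 + 2 * math.sqrt(11 / 4))
    assert outlier_threshold([0.0, 0.0, 0.0]) == 0.0
    with pytest.raises(ValueError):
        outlier_threshold([1.0])


def test_gene_categories(small_sim, small_blocks, small_table):
    _, a, b, truth = small_sim
    called, _ = call_variants(small_blocks, a, b)
    classify_variants(called, a, b)
    summaries = summarize_genes(called, small_table, a, b)
    by_cat = {}
    for s in summaries:
        by_cat.setdefault(s.category, []).append(s)
    # categories partition the gene set
    assert sum(len(v) for v in by_cat.values()) == len(a.genes)
    assert len(by_cat.get("no_ortholog", [])) == len(a.genes) - len(small_table)
    for s in by_cat.get("identical", []):
        assert s.total_snp == 0
    for s in by_cat.get("silent_only", []):
        assert s.total_snp > 0 and s.ns_snp == 0
    heavy = {s.gene_id for s in by_cat.get("heavily_mutated", [])}
    assert heavy == set(truth.heavy_genes)
    for s in by_cat.get("heavily_mutated", []):
        assert s.ns_per_kb >= 12.0


def test_heavy_cutoff_is_inclusive():
    # a 1000-base gene with exactly 12 NS SNPs sits on the >=12/kb boundary
    genome_a = AnnotatedGenome("A", "A" * 1000, [GeneModel("g1", 1, 1000, "+", pseudo=True)])
    table = OrthologTable([OrthologPair("g1", "h1", frozenset({"rbh"}))])
    variants = [
        Variant(i, i, "snp", "A", "C", gene_id="g1", effect="nonsynonymous")
        for i in range(1, 13)
    ]
    summaries = summarize_genes(variants, table, genome_a, None, OutlierThresholds())
    assert summaries[0].ns_per_kb == pytest.approx(12.0)
    assert summaries[0].category == "heavily_mutated"


def test_genome_rates_arithmetic():
    genome_a = AnnotatedGenome("A", "A" * 4000, [GeneModel("g1", 1, 2000, "+", pseudo=True)])
    snps = [Variant(p, p, "snp", "A", "C") for p in range(1, 2001, 200)]  # 10 coding
    coding, noncoding, frac = genome_rates(snps, genome_a)
    assert coding == pytest.approx(5.0)
    assert noncoding == pytest.approx(0.0)
    assert frac == pytest.approx(1.0)


def test_genome_rates_recovered_on_generator_pair(small_sim, small_blocks):
    # rates are configured for the shared (ancestral) genome; strain-specific
    # cassette DNA carries no pairwise SNPs, so measure over that footprint
    ancestor, a, b, _ = small_sim
    called, _ = call_variants(small_blocks, a, b)
    classify_variants(called, a, b)
    coding_kb = sum(g.length for g in ancestor.genes) / 1000.0
    noncoding_kb = ancestor.length / 1000.0 - coding_kb
    snps = [v for v in called if v.kind == "snp"]
    coding = sum(1 for v in snps if v.gene_id is not None) / coding_kb
    noncoding = sum(1 for v in snps if v.gene_id is None) / noncoding_kb
    assert abs(coding - 6.8) <= 3 * math.sqrt(6.8 * coding_kb) / coding_kb
    assert abs(noncoding - 10.5) <= 3 * math.sqrt(10.5 * noncoding_kb) / noncoding_kb
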
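"""Generator contracts: packing, determinism, planted structure, labels."""
import math

import pytest

from straincomp.model import START_CODONS, STOP_CODONS, translate_cds
from straincomp.motifs import scan_cxxch
from straincomp.synthetic_data import (
    DivergenceParams,
    GenomeSpec,
    SizingError,
    diverge,
    generate_ancestor,
    write_outputs,
)
from straincomp.variants import classify_coding_snp


def test_empty_genome_has_requested_length_and_no_features():
    g = generate_ancestor(GenomeSpec(genome_length=5000, gene_count=0, n_trna=0,
                                     n_cytochrome_genes=0, n_transposase=0), seed=3)
    assert g.length == 5000
    assert g.genes == [] and g.other_features == []


def test_infeasible_packing_raises_sizing_error():
    with pytest.raises(SizingError):
        generate_ancestor(
            GenomeSpec(genome_length=10_000, gene_count=20, mean_gene_length=900,
                       n_cytochrome_genes=0, n_transposase=0, n_trna=0),
            seed=1,
        )


def test_cds_structure(small_sim):
    ancestor = small_sim[0]
    for g in ancestor.genes:
        cds = ancestor.cds_nt(g)
        assert cds[:3] in START_CODONS
        assert cds[-3:] in STOP_CODONS
        assert "*" not in translate_cds(cds)


def test_shine_dalgarno_planted_upstream(small_sim):
    ancestor = small_sim[0]
    found = 0
    for g in ancestor.genes:
        if g.strand == "+":
            window = ancestor.sequence[g.start - 16 : g.start - 5]
        else:
            from straincomp.model import revcomp

            window = revcomp(ancestor.sequence[g.end + 4 : g.end + 15])
        if "AGGAGG" in window:
            found += 1
    assert found / len(ancestor.genes) > 0.9  # edge genes with short gaps may miss


def test_cytochrome_motif_counts_rescan_to_request():
    spec = GenomeSpec(genome_length=40_000, gene_count=30, n_cytochrome_genes=3,
                      motif_count_range=(4, 4), n_trna=0, n_transposase=0)
    g = generate_ancestor(spec, seed=9)
    cyts = [x for x in g.genes if "cytochrome" in x.product]
    assert len(cyts) == 3
    for c in cyts:
        assert len(scan_cxxch(c.protein)) == 4
    for x in g.genes:
        if "cytochrome" not in x.product:
            assert scan_cxxch(x.protein) == []


def test_generation_is_deterministic(tmp_path):
    spec = GenomeSpec(genome_length=50_000, n_cytochrome_genes=2, n_trna=2, n_transposase=1)
    params = DivergenceParams(seed=5, n_unique_regions_a=1, n_unique_regions_b=1)
    outs = []
    for run in ("x", "y"):
        anc = generate_ancestor(spec, seed=4)
        a, b, truth = diverge(anc, params)
        d = tmp_path / run
        write_outputs(d, a, b, truth)
        outs.append({p.name: p.read_bytes() for p in sorted(d.iterdir())})
    assert outs[0] == outs[1]


def test_zero_divergence_yields_identical_strains(small_sim):
    ancestor = small_sim[0]
    params = DivergenceParams(
        seed=1, coding_snp_rate=0, noncoding_snp_rate=0, indel_rate=0,
        heavy_gene_fraction=0, n_unique_regions_a=0, n_unique_regions_b=0,
    )
    a, b, truth = diverge(ancestor, params)
    assert a.sequence == b.sequence == ancestor.sequence
    assert truth.planted_variants == [] and truth.unique_regions == [] and truth.heavy_genes == []
    assert len(truth.ortholog_map) == len(ancestor.genes)


def test_silent_fraction_within_three_binomial_sd():
    anc = generate_ancestor(GenomeSpec(genome_length=300_000), seed=21)
    a, b, truth = diverge(anc, DivergenceParams(seed=22, heavy_gene_fraction=0.0, indel_rate=0.0))
    coding = [v for v in truth.snvs if v.gene_id is not None]
    syn = sum(1 for v in coding if v.effect == "synonymous")
    frac = syn / len(coding)
    sd = math.sqrt(0.72 * 0.28 / len(coding))
    assert abs(frac - 0.72) <= 3 * sd


def test_heavy_genes_reach_twelve_ns_per_kb(small_sim):
    _, a, _, truth = small_sim
    assert truth.heavy_genes
    per_gene = {}
    for v in truth.snvs:
        if v.gene_id and v.effect == "nonsynonymous":
            per_gene[v.gene_id] = per_gene.get(v.gene_id, 0) + 1
    for gid in truth.heavy_genes:
        length = a.gene(gid).length
        assert 1000.0 * per_gene[gid] / length >= 12.0


def test_planted_effects_match_reference_classifier(small_sim):
    """Every planted coding SNP re-classifies to its recorded label."""
    _, a, b, truth = small_sim
    checked = 0
    for v in truth.snvs:
        if v.gene_id is None:
            continue
        gene = a.gene(v.gene_id)
        assert classify_coding_snp(v, gene, a) == v.effect
        checked += 1
    assert checked > 100


def test_unique_region_genes_never_in_ortholog_map(small_sim):
    _, _, _, truth = small_sim
    mapped = {g for pair in truth.ortholog_map for g in pair}
    for region in truth.unique_regions:
        assert len(region.gene_ids) >= 2
        assert not (set(region.gene_ids) & mapped)


def test_poisson_rate_targets_on_planted_variants(small_sim):
    ancestor, _, _, truth = small_sim
    coding_len = sum(g.length for g in ancestor.genes)
    noncoding_len = ancestor.length - coding_len
    n_cod = sum(1 for v in truth.snvs if v.gene_id is not None)
    n_nc = sum(1 for v in truth.snvs if v.gene_id is None)
    for n, rate, span in ((n_cod, 6.8, coding_len), (n_nc, 10.5, noncoding_len)):
        lam = rate * span / 1000.0
        assert abs(n - lam) <= 3 * math.sqrt(lam)
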
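import pytest

from straincomp import orthology
from straincomp.genome_align import align_genomes
from straincomp.synthetic_data import (
    DivergenceParams,
    GenomeSpec,
    diverge,
    generate_ancestor,
)

SMALL_SPEC = GenomeSpec(
    genome_length=120_000,
    n_cytochrome_genes=6,
    motif_count_range=(2, 8),
    n_trna=4,
    n_transposase=3,
)
SMALL_DIV = DivergenceParams(
    seed=11,
    indel_rate=0.0,
    n_unique_regions_a=2,
    n_unique_regions_b=2,
    heavy_gene_fraction=0.05,
)


@pytest.fixture(scope="session")
def small_sim():
    """A 120 kb ancestor diverged into two strains, SNP-only divergence."""
    ancestor = generate_ancestor(SMALL_SPEC, seed=11)
    strain_a, strain_b, truth = diverge(ancestor, SMALL_DIV)
    return ancestor, strain_a, strain_b, truth


@pytest.fixture(scope="session")
def small_blocks(small_sim):
    _, a, b, _ = small_sim
    return align_genomes(a.sequence, b.sequence)


@pytest.fixture(scope="session")
def small_table(small_sim, small_blocks):
    _, a, b, _ = small_sim
    syn = orthology.synteny_orthologs(small_blocks, a, b)
    prot_a = {g.gene_id: g.protein for g in a.genes if not g.pseudo}
    prot_b = {g.gene_id: g.protein for g in b.genes if not g.pseudo}
    rbh = orthology.rbh_orthologs(prot_a, prot_b)
    return orthology.reconcile_orthologs(syn, rbh, a, b)
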
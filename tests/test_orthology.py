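"""Dual-method ortholog calling, reconciliation rules, unique regions."""
import pytest

from straincomp import orthology
from straincomp.genome_align import align_genomes
from straincomp.model import AnnotatedGenome, GeneModel, OrthologPair
from straincomp.orthology import (
    ReconcileThresholds,
    rbh_orthologs,
    reconcile_orthologs,
    synteny_orthologs,
    unique_regions,
)


def _toy_genome(strain_id, genes_spec, length=2000):
    """genes_spec: list of (gene_id, start, end) on a synthetic sequence."""
    import numpy as np

    rng = np.random.default_rng(hash(strain_id) % 2**31)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    genes = [GeneModel(g, s, e, "+") for g, s, e in genes_spec]
    return AnnotatedGenome(strain_id, seq, genes)


def test_identical_genomes_pair_every_gene(small_sim):
    _, a, _, _ = small_sim
    blocks = align_genomes(a.sequence, a.sequence)
    pairs = synteny_orthologs(blocks, a, a)
    assert len(pairs) == len(a.genes)
    assert all(p.gene_a == p.gene_b for p in pairs)


def test_gene_deleted_in_b_is_unpaired(small_sim):
    _, a, _, _ = small_sim
    blocks = align_genomes(a.sequence, a.sequence)
    b_minus = AnnotatedGenome(
        "b", a.sequence, [g for g in a.genes[1:]], a.other_features
    )
    pairs = synteny_orthologs(blocks, a, b_minus)
    paired_a = {p.gene_a for p in pairs}
    assert a.genes[0].gene_id not in paired_a
    assert len(pairs) == len(a.genes) - 1


def test_synteny_recovers_truth_pairs_exactly(small_sim, small_blocks):
    _, a, b, truth = small_sim
    pairs = synteny_orthologs(small_blocks, a, b)
    assert {(p.gene_a, p.gene_b) for p in pairs} == set(truth.ortholog_map)


def test_rbh_single_identical_protein():
    prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    pairs = rbh_orthologs({"a1": prot}, {"b1": prot}, prefilter=False)
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.gene_a, p.gene_b) == ("a1", "b1")
    assert p.protein_identity == 1.0 and p.coverage_of_longer == 1.0
    assert p.identical_protein


def test_rbh_identical_paralogs_tie_yields_no_pair():
    prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    other = "MW" + "G" * 30
    pairs = rbh_orthologs({"a1": prot, "a2": prot}, {"b1": prot, "b2": other}, prefilter=False)
    # b1's reverse best is tied between the identical paralogs: no pair at all
    assert pairs == []


def test_rbh_matches_brute_force_ranking_on_toy_set():
    from straincomp.orthology import protein_alignment_stats

    prots_a = {
        "a1": "MKTAYIAKQRQISFVKSHFSRQ",
        "a2": "MGWWGGWGGWWGLLPLLPLLP",
        "a3": "MHHHHEEEEDDDDKKKKRRRR",
    }
    prots_b = {
        "b1": "MKTAYLAKQRQISFVKSHFSRQ",  # near a1
        "b2": "MGWWGGWGGWWGLLPLLPLLA",  # near a2
        "b3": "MHHHHEEEEDDDNKKKKRRRR",  # near a3
    }
    pairs = rbh_orthologs(prots_a, prots_b, prefilter=False)
    assert {(p.gene_a, p.gene_b) for p in pairs} == {("a1", "b1"), ("a2", "b2"), ("a3", "b3")}
    # oracle: every pair's score is the strict maximum of its row and column
    for p in pairs:
        score, _, _ = protein_alignment_stats(prots_a[p.gene_a], prots_b[p.gene_b])
        for other_b, prot in prots_b.items():
            if other_b != p.gene_b:
                s, _, _ = protein_alignment_stats(prots_a[p.gene_a], prot)
                assert s < score
        for other_a, prot in prots_a.items():
            if other_a != p.gene_a:
                s, _, _ = protein_alignment_stats(prot, prots_b[p.gene_b])
                assert s < score


def test_rbh_is_symmetric(small_sim):
    _, a, b, _ = small_sim
    prot_a = {g.gene_id: g.protein for g in a.genes[:60] if not g.pseudo}
    prot_b = {g.gene_id: g.protein for g in b.genes[:60] if not g.pseudo}
    fwd = {(p.gene_a, p.gene_b) for p in rbh_orthologs(prot_a, prot_b)}
    rev = {(p.gene_b, p.gene_a) for p in rbh_orthologs(prot_b, prot_a)}
    assert fwd == rev


def _two_gene_genomes():
    prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    ga = _toy_genome("A", [("a1", 1, 102), ("a2", 301, 402)])
    gb = _toy_genome("B", [("b1", 1, 102), ("b2", 301, 402)])
    for g in ga.genes + gb.genes:
        g.protein = prot
    return ga, gb


@pytest.mark.parametrize(
    "methods,coverage,identity,expect",
    [
        ({"synteny", "rbh"}, 0.9, 0.2, True),  # agreement overrides thresholds
        ({"rbh"}, 0.49, 0.9, False),  # coverage below 50%
        ({"rbh"}, 0.60, 0.31, True),  # boundary case accepted
        ({"rbh"}, 0.60, 0.29, False),  # identity below 30%
    ],
)
def test_reconcile_threshold_rules(methods, coverage, identity, expect):
    ga, gb = _two_gene_genomes()
    syn = [OrthologPair("a1", "b1", frozenset({"synteny"}))] if "synteny" in methods else []
    rbh = [
        OrthologPair(
            "a1", "b1", frozenset({"rbh"}),
            protein_identity=identity, coverage_of_longer=coverage,
        )
    ]
    table = reconcile_orthologs(syn, rbh, ga, gb, ReconcileThresholds())
    assert (("a1", "b1") in {(p.gene_a, p.gene_b) for p in table}) is expect


def test_reconcile_conflict_prefers_two_method_pair():
    ga, gb = _two_gene_genomes()
    syn = [OrthologPair("a1", "b1", frozenset({"synteny"}))]
    rbh = [
        OrthologPair("a1", "b1", frozenset({"rbh"}), 0.99, 0.99),
        OrthologPair("a2", "b1", frozenset({"rbh"}), 1.0, 1.0),
    ]
    table = reconcile_orthologs(syn, rbh, ga, gb)
    got = {(p.gene_a, p.gene_b) for p in table}
    assert ("a1", "b1") in got and ("a2", "b1") not in got


def test_every_gene_in_at_most_one_pair_and_partition(small_sim, small_table):
    _, a, b, _ = small_sim
    gene_as = [p.gene_a for p in small_table]
    gene_bs = [p.gene_b for p in small_table]
    assert len(gene_as) == len(set(gene_as))
    assert len(gene_bs) == len(set(gene_bs))
    unique_a = {g.gene_id for g in a.genes} - set(gene_as)
    assert len(small_table) + len(unique_a) == len(a.genes)


def test_recovery_and_no_false_pairs(small_sim, small_table):
    _, _, _, truth = small_sim
    got = {(p.gene_a, p.gene_b) for p in small_table}
    tm = set(truth.ortholog_map)
    assert len(got & tm) >= 0.99 * len(tm)
    assert not (got - tm)


def test_single_orphan_gene_is_not_a_region():
    ga = _toy_genome("A", [("a1", 1, 102), ("a2", 301, 402), ("a3", 601, 702)])
    gb = _toy_genome("B", [("b1", 1, 102), ("b3", 601, 702)])
    pairs = [
        OrthologPair("a1", "b1", frozenset({"rbh"})),
        OrthologPair("a3", "b3", frozenset({"rbh"})),
    ]
    from straincomp.model import OrthologTable

    table = OrthologTable(pairs)
    assert unique_regions(ga, table, "A") == []


def test_unique_regions_match_truth_with_borders(small_sim, small_table):
    _, a, b, truth = small_sim
    found = unique_regions(a, small_table, "A") + unique_regions(b, small_table, "B")
    truth_sets = {frozenset(r.gene_ids): r for r in truth.unique_regions}
    found_sets = {frozenset(r.gene_ids): r for r in found}
    assert set(truth_sets) == set(found_sets)
    for key, tr in truth_sets.items():
        assert tr.border <= found_sets[key].border  # planted border always detected


def test_region_with_internal_transposase_flagged():
    ga = _toy_genome(
        "A",
        [("a1", 1, 102), ("u1", 301, 402), ("u2", 501, 602), ("a2", 901, 1002)],
    )
    ga.gene("u2").is_transposase = True
    gb = _toy_genome("B", [("b1", 1, 102), ("b2", 901, 1002)])
    from straincomp.model import OrthologTable

    table = OrthologTable(
        [
            OrthologPair("a1", "b1", frozenset({"rbh"})),
            OrthologPair("a2", "b2", frozenset({"rbh"})),
        ]
    )
    regions = unique_regions(ga, table, "A")
    assert len(regions) == 1
    assert regions[0].gene_ids == ["u1", "u2"]
    assert "transposase_or_integrase" in regions[0].border
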
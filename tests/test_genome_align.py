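"""Anchoring, chaining, and gap closure against brute-force oracles."""
import itertools

import numpy as np
import pytest

from straincomp.genome_align import (
    HOXD70,
    HOXD70_GAP_EXTEND,
    HOXD70_GAP_OPEN,
    AlignerParams,
    align_genomes,
    chain_anchors,
    close_gaps,
    find_anchors,
    unaligned_intervals,
)
from straincomp.model import revcomp


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_identical_sequences_give_one_full_anchor():
    seq = _random_seq(1000, 0)
    assert find_anchors(seq, seq, 15) == [(1, 1, 1000)]


def test_single_snp_recovers_nearly_all_positions():
    seq_a = _random_seq(1000, 1)
    seq_b = seq_a[:499] + ("A" if seq_a[499] != "A" else "C") + seq_a[500:]
    anchors = find_anchors(seq_a, seq_b, 15)
    covered = set()
    for a, _b, ln in anchors:
        covered.update(range(a, a + ln))
    assert len(covered) >= 0.97 * 1000
    assert 500 not in covered
    # oracle: anchors must be exact matches
    for a, b, ln in anchors:
        assert seq_a[a - 1 : a - 1 + ln] == seq_b[b - 1 : b - 1 + ln]


def test_reverse_complement_yields_no_anchors():
    seq = _random_seq(500, 2)
    assert find_anchors(seq, revcomp(seq), 15) == []


def test_collinear_anchors_all_retained():
    anchors = [(i * 100 + 1, i * 100 + 1, 50) for i in range(10)]
    assert chain_anchors(anchors) == anchors


def _brute_force_chain_weight(anchors):
    best = 0
    for r in range(1, len(anchors) + 1):
        for sub in itertools.combinations(anchors, r):
            ok = all(
                s1[0] + s1[2] <= s2[0] and s1[1] + s1[2] <= s2[1]
                for s1, s2 in zip(sub, sub[1:])
            )
            if ok:
                best = max(best, sum(s[2] for s in sub))
    return best


def test_chain_matches_exhaustive_subset_search():
    # anchors on a 50-base grid with length < 50, so anchors never overlap
    # and strict start-ordering equals non-overlap
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(2, 11))
        a_slots = rng.permutation(12)[:n]
        b_slots = rng.permutation(12)[:n]
        anchors = sorted(
            (int(a) * 50 + 1, int(b) * 50 + 1, int(rng.integers(5, 41)))
            for a, b in zip(a_slots, b_slots)
        )
        chain = chain_anchors(anchors)
        for s1, s2 in zip(chain, chain[1:]):
            assert s1[0] + s1[2] <= s2[0] and s1[1] + s1[2] <= s2[1]
        assert sum(c[2] for c in chain) == _brute_force_chain_weight(anchors)


def test_transposed_anchor_dropped():
    anchors = [(i * 100 + 1, i * 100 + 1, 60) for i in range(10)]
    anchors.insert(5, (451, 891, 20))  # off-diagonal interloper
    chain = chain_anchors(sorted(anchors))
    assert (451, 891, 20) not in chain
    assert len(chain) == 10


def test_equal_weight_tie_breaks_to_smaller_a_pos():
    # two incompatible single-anchor chains of equal weight
    assert chain_anchors([(1, 100, 30), (50, 10, 30)]) == [(1, 100, 30)]


def _oracle_global(sa, sb):
    """Affine-gap global alignment score by plain DP (gap len L costs open+extend*L)."""
    NEG = -10**9
    open_, ext = HOXD70_GAP_OPEN + HOXD70_GAP_EXTEND, HOXD70_GAP_EXTEND
    n, m = len(sa), len(sb)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in sb (consume sa)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in sa (consume sb)
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = -open_ - ext * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -open_ - ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = HOXD70[(sa[i - 1], sb[j - 1])]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - ext, Y[i - 1][j] - open_)
            Y[i][j] = max(M[i][j - 1] - open_, Y[i][j - 1] - ext, X[i][j - 1] - open_)
    return max(M[n][m], X[n][m], Y[n][m])


def _block_score(block):
    score = 0
    in_gap = False
    for ca, cb in zip(block.a_gapped, block.b_gapped):
        if ca == "-" or cb == "-":
            score -= HOXD70_GAP_EXTEND + (HOXD70_GAP_OPEN if not in_gap else 0)
            in_gap = True
        else:
            score += HOXD70[(ca, cb)]
            in_gap = False
    return score


def test_gap_closure_with_two_snps_is_all_mismatch_columns():
    rng = np.random.default_rng(3)
    left = _random_seq(40, 4)
    right = _random_seq(40, 5)
    mid_a = _random_seq(30, 6)
    mid_b = list(mid_a)
    for pos in (7, 21):
        mid_b[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mid_b[pos]]
    mid_b = "".join(mid_b)
    seq_a = left + mid_a + right
    seq_b = left + mid_b + right
    chain = [(1, 1, 40), (71, 71, 40)]
    blocks = close_gaps(chain, seq_a, seq_b, AlignerParams())
    assert len(blocks) == 1
    blk = blocks[0]
    assert "-" not in blk.a_gapped and "-" not in blk.b_gapped
    mismatches = sum(1 for x, y in zip(blk.a_gapped, blk.b_gapped) if x != y)
    assert mismatches == 2
    assert _block_score(blk) == _oracle_global(seq_a, seq_b)


def test_gap_closure_insertion_makes_one_gap_run():
    core = _random_seq(80, 8)
    ins = _random_seq(7, 9)
    seq_a = core
    seq_b = core[:40] + ins + core[40:]
    blocks = close_gaps([(1, 1, 40), (41, 48, 40)], seq_a, seq_b, AlignerParams())
    assert len(blocks) == 1
    a_g = blocks[0].a_gapped
    assert a_g.count("-") == 7
    start = a_g.index("-")
    assert a_g[start : start + 7] == "-------"
    assert "-" not in blocks[0].b_gapped


def test_zero_length_gaps_concatenate_anchors_verbatim():
    seq = _random_seq(100, 10)
    blocks = close_gaps([(1, 1, 50), (51, 51, 50)], seq, seq, AlignerParams())
    assert len(blocks) == 1
    assert blocks[0].a_gapped == seq and blocks[0].b_gapped == seq


def test_genome_self_alignment_is_one_clean_block(small_sim):
    _, a, _, _ = small_sim
    seq = a.sequence[:50_000]
    blocks = align_genomes(seq, seq)
    assert len(blocks) == 1
    blk = blocks[0]
    assert (blk.a_start, blk.a_end) == (1, len(seq))
    assert blk.a_gapped == blk.b_gapped == seq


def test_mismatch_columns_equal_planted_snps(small_sim, small_blocks):
    _, a, b, truth = small_sim
    mismatches = sum(
        1
        for blk in small_blocks
        for x, y in zip(blk.a_gapped, blk.b_gapped)
        if x != "-" and y != "-" and x != y
    )
    assert mismatches == len(truth.snvs)
    for blk in small_blocks:
        blk.validate(a.sequence, b.sequence)


def test_cassette_genes_have_no_aligned_counterpart(small_sim, small_blocks):
    from straincomp.model import AlignmentIndex

    _, a, _, truth = small_sim
    index = AlignmentIndex(small_blocks)
    for region in truth.unique_regions:
        if region.strain != "A":
            continue
        for gid in region.gene_ids:
            g = a.gene(gid)
            assert index.map_interval(g.start, g.end) is None
    # sanity: unaligned-interval bookkeeping tiles the genome
    gaps_a = unaligned_intervals(small_blocks, a.length, "a")
    covered = sum(e - s + 1 for s, e in gaps_a) + sum(
        b.a_end - b.a_start + 1 for b in small_blocks
    )
    assert covered == a.length


def test_seed_k_lower_bound():
    with pytest.raises(ValueError):
        AlignerParams(seed_k=7)
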
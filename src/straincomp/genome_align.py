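"""Collinear pairwise whole-genome alignment.

Strategy: seed with k-mers that occur exactly once in each genome, merge
overlapping seeds into maximal exact-match anchors, chain anchors with a
weighted longest-increasing-subsequence, and close the short inter-anchor
gaps with global affine-gap alignment under the HOXD70 nucleotide scoring
matrix.  Forward strand only: the target use case is a pair of syntenic
strain genomes with no large-scale rearrangements or inversions; for
anything else, ingest an externally produced XMFA instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .model import AlignmentBlock

#: HOXD70 substitution scores (Chiaromonte, Yee & Miller 2002), the matrix
#: standardly used for diverged-but-alignable genomic DNA.
HOXD70 = {
    ("A", "A"): 91, ("A", "C"): -114, ("A", "G"): -31, ("A", "T"): -123,
    ("C", "A"): -114, ("C", "C"): 100, ("C", "G"): -125, ("C", "T"): -31,
    ("G", "A"): -31, ("G", "C"): -125, ("G", "G"): 100, ("G", "T"): -114,
    ("T", "A"): -123, ("T", "C"): -31, ("T", "G"): -114, ("T", "T"): 91,
}
HOXD70_GAP_OPEN = 400
HOXD70_GAP_EXTEND = 30


@dataclass
class AlignerParams:
    seed_k: int = 15
    min_chain_anchor_span: int = 0
    max_gap_fill: int = 5000
    gap_open: int = HOXD70_GAP_OPEN
    gap_extend: int = HOXD70_GAP_EXTEND
    scores: dict = field(default_factory=lambda: dict(HOXD70))

    def __post_init__(self) -> None:
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        if self.max_gap_fill <= 0:
            raise ValueError("max_gap_fill must be positive")


Anchor = tuple[int, int, int]  # (a_pos, b_pos, length), 1-based


def _unique_kmer_index(seq: str, k: int) -> dict[str, int]:
    """k-mer -> 0-based position, for k-mers occurring exactly once."""
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dup:
            continue
        if kmer in seen:
            del seen[kmer]
            dup.add(kmer)
        else:
            seen[kmer] = i
    return seen


def find_anchors(seq_a: str, seq_b: str, k: int = 15) -> list[Anchor]:
    """Maximal exact matches seeded by k-mers unique in each genome.

    Seeds on the same diagonal at consecutive offsets are merged into
    maximal runs.  Returns 1-based (a_pos, b_pos, length) triples sorted
    by a_pos.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if k > min(len(seq_a), len(seq_b)):
        raise ValueError("k exceeds sequence length")
    idx_a = _unique_kmer_index(seq_a, k)
    idx_b = _unique_kmer_index(seq_b, k)
    seeds = sorted(
        (pa, idx_b[kmer]) for kmer, pa in idx_a.items() if kmer in idx_b
    )
    anchors: list[Anchor] = []
    run_a = run_b = run_len = -1
    for pa, pb in seeds:
        if run_len >= 0 and pa == run_a + run_len - k + 1 and pb == run_b + run_len - k + 1:
            run_len += 1
        else:
            if run_len >= 0:
                anchors.append((run_a + 1, run_b + 1, run_len))
            run_a, run_b, run_len = pa, pb, k
    if run_len >= 0:
        anchors.append((run_a + 1, run_b + 1, run_len))
    return anchors


def chain_anchors(anchors: list[Anchor]) -> list[Anchor]:
    """Maximum-total-length collinear anchor chain.

    Weighted longest-increasing-subsequence on (a_pos, b_pos); among
    equal-weight chains the one whose first anchor has the smaller a_pos
    wins.  Overlapping neighbours in the winning chain are trimmed so the
    chain is strictly increasing in both coordinates.
    """
    if not anchors:
        return []
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i][0], anchors[i][1]))
    # Fenwick tree over b-rank holding (weight, -first_a, index) maxima
    b_sorted = sorted({anchors[i][1] for i in order})
    rank = {b: r + 1 for r, b in enumerate(b_sorted)}
    size = len(b_sorted)
    NEG = (0, 0, -1)
    tree: list[tuple] = [NEG] * (size + 1)

    def update(pos: int, val: tuple) -> None:
        while pos <= size:
            if val[:2] > tree[pos][:2]:
                tree[pos] = val
            pos += pos & -pos

    def query(pos: int) -> tuple:
        best = NEG
        while pos > 0:
            if tree[pos][:2] > best[:2]:
                best = tree[pos]
            pos -= pos & -pos
        return best

    best_end = NEG
    parent = {}
    chain_info = {}
    for i in order:
        a, b, ln = anchors[i]
        pred = query(rank[b] - 1)
        if pred[2] >= 0:
            w = pred[0] + ln
            first_neg_a = pred[1]
            parent[i] = pred[2]
        else:
            w = ln
            first_neg_a = -a
            parent[i] = -1
        val = (w, first_neg_a, i)
        chain_info[i] = val
        update(rank[b], val)
        if val[:2] > best_end[:2]:
            best_end = val
    chain: list[Anchor] = []
    i = best_end[2]
    while i >= 0:
        chain.append(anchors[i])
        i = parent[i]
    chain.reverse()
    return _trim_overlaps(chain)


def _trim_overlaps(chain: list[Anchor]) -> list[Anchor]:
    out: list[Anchor] = []
    prev_a_end = prev_b_end = 0
    for a, b, ln in chain:
        cut = max(prev_a_end - a + 1, prev_b_end - b + 1, 0)
        if cut >= ln:
            continue
        a, b, ln = a + cut, b + cut, ln - cut
        out.append((a, b, ln))
        prev_a_end, prev_b_end = a + ln - 1, b + ln - 1
    return out


def _hoxd_aligner(params: AlignerParams) -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for (x, y), s in params.scores.items():
        mat[x, y] = s
    for c in alphabet:  # N never rewarded
        mat["N", c] = mat[c, "N"] = min(params.scores.values())
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _align_gap(ga: str, gb: str, aligner: Align.PairwiseAligner) -> tuple[str, str]:
    """Globally align two short inter-anchor segments (either may be '')."""
    if not ga:
        return "-" * len(gb), gb
    if not gb:
        return ga, "-" * len(ga)
    aln = aligner.align(ga, gb)[0]
    return str(aln[0]), str(aln[1])


def close_gaps(
    chain: list[Anchor], seq_a: str, seq_b: str, params: AlignerParams | None = None
) -> list[AlignmentBlock]:
    """Fill inter-anchor gaps and emit contiguous alignment blocks.

    Gaps where either side exceeds ``max_gap_fill`` split the alignment
    into separate blocks; the intervening sequence is left unaligned.
    """
    params = params or AlignerParams()
    if not chain:
        return []
    aligner = _hoxd_aligner(params)
    blocks: list[AlignmentBlock] = []
    # current block state
    cur_a: list[str] = []
    cur_b: list[str] = []
    blk_a_start = blk_b_start = None
    prev_a_end = prev_b_end = None

    def flush() -> None:
        nonlocal cur_a, cur_b, blk_a_start, blk_b_start
        if blk_a_start is not None:
            blocks.append(
                AlignmentBlock(
                    blk_a_start, prev_a_end, blk_b_start, prev_b_end,
                    "".join(cur_a), "".join(cur_b),
                )
            )
        cur_a, cur_b = [], []
        blk_a_start = blk_b_start = None

    for a, b, ln in chain:
        if blk_a_start is None:
            blk_a_start, blk_b_start = a, b
        else:
            ga = seq_a[prev_a_end : a - 1]
            gb = seq_b[prev_b_end : b - 1]
            if max(len(ga), len(gb)) > params.max_gap_fill:
                flush()
                blk_a_start, blk_b_start = a, b
            elif ga or gb:
                ta, tb = _align_gap(ga, gb, aligner)
                cur_a.append(ta)
                cur_b.append(tb)
        cur_a.append(seq_a[a - 1 : a - 1 + ln])
        cur_b.append(seq_b[b - 1 : b - 1 + ln])
        prev_a_end, prev_b_end = a + ln - 1, b + ln - 1
    flush()
    for blk in blocks:
        blk.validate(seq_a, seq_b)
    return blocks


def align_genomes(seq_a: str, seq_b: str, params: AlignerParams | None = None) -> list[AlignmentBlock]:
    """Anchor, chain, and gap-close two genome sequences."""
    params = params or AlignerParams()
    anchors = find_anchors(seq_a, seq_b, params.seed_k)
    if params.min_chain_anchor_span:
        anchors = [a for a in anchors if a[2] >= params.min_chain_anchor_span]
    chain = chain_anchors(anchors)
    return close_gaps(chain, seq_a, seq_b, params)


def unaligned_intervals(blocks: list[AlignmentBlock], length: int, track: str = "a") -> list[tuple[int, int]]:
    """Intervals of one genome absent from every block (candidate strain-specific DNA)."""
    spans = sorted(
        (b.a_start, b.a_end) if track == "a" else (b.b_start, b.b_end) for b in blocks
    )
    out = []
    pos = 1
    for s, e in spans:
        if s > pos:
            out.append((pos, s - 1))
        pos = max(pos, e + 1)
    if pos <= length:
        out.append((pos, length))
    return out
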
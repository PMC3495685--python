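"""Ortholog calling by synteny and by reciprocal best hit, and reconciliation.

Two independent methods mirror the standard practice for closely related
strain pairs: (1) mapping each gene's interval through the whole-genome
alignment and requiring reciprocal >=50% overlap with a gene in the other
strain, and (2) reciprocal best hits in exact all-vs-all Smith-Waterman
protein alignment (BLOSUM62, gap open 11 / extend 1).  Pairs found by both
methods are accepted unconditionally; single-method pairs must align over
at least half the longer protein with at least 30% identity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from intervaltree import IntervalTree

from .model import (
    AlignmentBlock,
    AlignmentIndex,
    AnnotatedGenome,
    OrthologPair,
    OrthologTable,
    StrainRegion,
)

log = logging.getLogger(__name__)


@dataclass
class ReconcileThresholds:
    min_coverage: float = 0.50
    min_identity: float = 0.30

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= 1 and 0 < self.min_identity <= 1):
            raise ValueError("thresholds must be in (0,1]")


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12  # BLAST-style open 11 + extend 1 for the first gap base
    aligner.extend_gap_score = -1
    return aligner


def protein_alignment_stats(prot_a: str, prot_b: str, aligner=None) -> tuple[float, float, float]:
    """(score, identity over aligned columns, coverage of the longer protein)."""
    if not prot_a or not prot_b:
        return 0.0, 0.0, 0.0
    aligner = aligner or _protein_aligner()
    aln = aligner.align(prot_a, prot_b)[0]
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    longer = max(len(prot_a), len(prot_b))
    spans = aln.aligned
    if len(spans[0]):
        span_a = int(spans[0][-1][1] - spans[0][0][0])
        span_b = int(spans[1][-1][1] - spans[1][0][0])
    else:
        span_a = span_b = 0
    coverage = (span_a if len(prot_a) >= len(prot_b) else span_b) / longer
    return float(aln.score), identity, coverage


# ---------------------------------------------------------------------------
# synteny-based orthologs
# ---------------------------------------------------------------------------

def synteny_orthologs(
    blocks: list[AlignmentBlock],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    min_reciprocal_overlap: float = 0.5,
) -> list[OrthologPair]:
    """Pair genes whose intervals correspond through the genome alignment.

    Gene A pairs with gene B when the B-span of A's CDS, mapped through the
    alignment, overlaps B's CDS by at least ``min_reciprocal_overlap`` of
    each gene's length.  One-to-one is enforced by keeping the
    largest-overlap pair (ties broken toward the smaller B coordinate).
    """
    index = AlignmentIndex(blocks)
    btree = IntervalTree()
    for g in genome_b.genes:
        btree[g.start : g.end + 1] = g
    candidates: list[tuple[float, int, str, str]] = []
    for ga in genome_a.genes:
        mapped = index.map_interval(ga.start, ga.end)
        if mapped is None:
            continue
        mlo, mhi = mapped
        for iv in btree.overlap(mlo, mhi + 1):
            gb = iv.data
            ov = min(mhi, gb.end) - max(mlo, gb.start) + 1
            if ov <= 0:
                continue
            if ov / ga.length >= min_reciprocal_overlap and ov / gb.length >= min_reciprocal_overlap:
                candidates.append((ov, gb.start, ga.gene_id, gb.gene_id))
    # greedy one-to-one: largest overlap first, smaller B coordinate on ties
    candidates.sort(key=lambda c: (-c[0], c[1]))
    taken_a: set[str] = set()
    taken_b: set[str] = set()
    pairs: list[OrthologPair] = []
    for ov, _bstart, a_id, b_id in candidates:
        if a_id in taken_a or b_id in taken_b:
            continue
        taken_a.add(a_id)
        taken_b.add(b_id)
        pairs.append(OrthologPair(a_id, b_id, methods=frozenset({"synteny"})))
    pairs.sort(key=lambda p: genome_a.gene(p.gene_a).start)
    return pairs


# ---------------------------------------------------------------------------
# reciprocal best hit
# ---------------------------------------------------------------------------

def _kmer_set(prot: str, k: int = 5) -> set[str]:
    return {prot[i : i + k] for i in range(len(prot) - k + 1)}


def rbh_orthologs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    prefilter: bool | None = None,
    min_shared_kmers: int = 5,
) -> list[OrthologPair]:
    """Reciprocal unique-best-hit pairs in all-vs-all Smith-Waterman.

    For desk-scale proteomes every pair is scored exactly; for large
    proteomes candidate pairs are pre-selected by shared 5-mers (a seeding
    shortcut in the spirit of BLAST's word hits) before exact scoring.
    Families with tied best scores yield no pair and are logged.
    """
    aligner = _protein_aligner()
    ids_a = sorted(proteome_a)
    ids_b = sorted(proteome_b)
    if prefilter is None:
        prefilter = len(ids_a) * len(ids_b) > 2500
    scores: dict[str, list[tuple[float, str]]] = {a: [] for a in ids_a}
    rev_scores: dict[str, list[tuple[float, str]]] = {b: [] for b in ids_b}
    stats: dict[tuple[str, str], tuple[float, float]] = {}

    if prefilter:
        index: dict[str, list[str]] = {}
        for b in ids_b:
            for kmer in _kmer_set(proteome_b[b]):
                index.setdefault(kmer, []).append(b)
        pairs_to_score: dict[str, list[str]] = {}
        for a in ids_a:
            counts: dict[str, int] = {}
            for kmer in _kmer_set(proteome_a[a]):
                for b in index.get(kmer, ()):
                    counts[b] = counts.get(b, 0) + 1
            pairs_to_score[a] = [b for b, c in counts.items() if c >= min_shared_kmers]
    else:
        pairs_to_score = {a: list(ids_b) for a in ids_a}

    for a in ids_a:
        for b in pairs_to_score[a]:
            score, identity, coverage = protein_alignment_stats(
                proteome_a[a], proteome_b[b], aligner
            )
            scores[a].append((score, b))
            rev_scores[b].append((score, a))
            stats[(a, b)] = (identity, coverage)

    def unique_best(cands: list[tuple[float, str]]) -> str | None:
        if not cands:
            return None
        cands = sorted(cands, reverse=True)
        if len(cands) > 1 and cands[0][0] == cands[1][0]:
            return "__tied__"
        return cands[0][1]

    pairs: list[OrthologPair] = []
    for a in ids_a:
        best_b = unique_best(scores[a])
        if best_b is None:
            continue
        if best_b == "__tied__":
            log.info("RBH: tied best hits for %s; no pair emitted", a)
            continue
        best_a = unique_best(rev_scores[best_b])
        if best_a != a:
            continue
        identity, coverage = stats[(a, best_b)]
        pa, pb = proteome_a[a], proteome_b[best_b]
        pairs.append(
            OrthologPair(
                a,
                best_b,
                methods=frozenset({"rbh"}),
                protein_identity=identity,
                coverage_of_longer=coverage,
                identical_protein=pa == pb,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------

def reconcile_orthologs(
    synteny_pairs: list[OrthologPair],
    rbh_pairs: list[OrthologPair],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    thresholds: ReconcileThresholds | None = None,
) -> OrthologTable:
    """Merge the two methods' calls.

    Pairs found by both methods are accepted unconditionally; pairs found
    by one method must cover >=``min_coverage`` of the longer protein at
    >=``min_identity`` identity.  When a gene ends up in two accepted
    pairs, the two-method pair wins, then the higher-identity pair.
    """
    thresholds = thresholds or ReconcileThresholds()
    aligner = _protein_aligner()
    merged: dict[tuple[str, str], OrthologPair] = {}
    for p in synteny_pairs:
        merged[(p.gene_a, p.gene_b)] = OrthologPair(
            p.gene_a, p.gene_b, methods=frozenset({"synteny"}),
            protein_identity=p.protein_identity, coverage_of_longer=p.coverage_of_longer,
        )
    n_agree = 0
    for p in rbh_pairs:
        key = (p.gene_a, p.gene_b)
        if key in merged:
            n_agree += 1
            q = merged[key]
            merged[key] = OrthologPair(
                p.gene_a, p.gene_b, methods=frozenset({"synteny", "rbh"}),
                protein_identity=p.protein_identity,
                coverage_of_longer=p.coverage_of_longer,
                identical_protein=p.identical_protein,
            )
        else:
            merged[key] = p

    accepted: list[OrthologPair] = []
    for key, p in merged.items():
        ga = genome_a.gene(p.gene_a)
        gb = genome_b.gene(p.gene_b)
        if "rbh" not in p.methods:
            # synteny-only: compute protein stats now (pseudogenes pair on
            # nucleotide evidence alone and skip the protein criteria)
            if ga.pseudo or gb.pseudo:
                p.protein_identity = 0.0
                p.coverage_of_longer = 0.0
                p.identical_protein = False
                accepted.append(p)
                continue
            _, identity, coverage = protein_alignment_stats(ga.protein, gb.protein, aligner)
            p.protein_identity = identity
            p.coverage_of_longer = coverage
            p.identical_protein = ga.protein == gb.protein
        if len(p.methods) == 2:
            accepted.append(p)
        elif p.coverage_of_longer >= thresholds.min_coverage and p.protein_identity >= thresholds.min_identity:
            accepted.append(p)

    # resolve conflicts: a gene may appear in only one accepted pair
    def rank(p: OrthologPair):
        return (len(p.methods), p.protein_identity, p.gene_a)

    accepted.sort(key=rank, reverse=True)
    taken_a: set[str] = set()
    taken_b: set[str] = set()
    final: list[OrthologPair] = []
    for p in accepted:
        if p.gene_a in taken_a or p.gene_b in taken_b:
            log.info("ortholog conflict: dropped %s-%s", p.gene_a, p.gene_b)
            continue
        taken_a.add(p.gene_a)
        taken_b.add(p.gene_b)
        if not genome_a.gene(p.gene_a).pseudo and not genome_b.gene(p.gene_b).pseudo:
            p.identical_nucleotide = genome_a.cds_nt(p.gene_a) == genome_b.cds_nt(p.gene_b)
        final.append(p)
    final.sort(key=lambda p: genome_a.gene(p.gene_a).start)
    return OrthologTable(final, n_agree=n_agree)


# ---------------------------------------------------------------------------
# strain-specific regions
# ---------------------------------------------------------------------------

def unique_regions(
    genome: AnnotatedGenome,
    table: OrthologTable,
    strain: str = "A",
    min_run: int = 2,
    flank_bp: int = 500,
) -> list[StrainRegion]:
    """Maximal runs of >=``min_run`` consecutive genes with no ortholog.

    The border is classified by scanning the run's genes plus one flanking
    gene on each side for transposase/integrase products, and the flanking
    DNA +-``flank_bp`` for tRNA and repeat features.
    """
    has_orth = table.by_a if strain == "A" else table.by_b
    genes = sorted(genome.genes, key=lambda g: g.start)
    regions: list[StrainRegion] = []
    i = 0
    while i < len(genes):
        if genes[i].gene_id in has_orth:
            i += 1
            continue
        j = i
        while j < len(genes) and genes[j].gene_id not in has_orth:
            j += 1
        run = genes[i:j]
        if len(run) >= min_run:
            border: set[str] = set()
            scan = run[:]
            if i > 0:
                scan.append(genes[i - 1])
            if j < len(genes):
                scan.append(genes[j])
            if any(g.is_transposase for g in scan):
                border.add("transposase_or_integrase")
            lo = run[0].start - flank_bp
            hi = run[-1].end + flank_bp
            for f in genome.other_features:
                if f.start <= hi and f.end >= lo:
                    border.add("trna" if f.type == "tRNA" else "repeat")
            regions.append(
                StrainRegion(
                    strain=strain,
                    start=run[0].start,
                    end=run[-1].end,
                    gene_ids=[g.gene_id for g in run],
                    border=frozenset(border),
                )
            )
        i = j
    return regions
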
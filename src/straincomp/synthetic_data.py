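"""Synthetic divergent genome pairs with known ground truth.

The generator emulates the statistical structure of a pair of closely
related, syntenic bacterial strain genomes: a gene-dense circular
chromosome, pairwise SNP densities of a few per kb split between coding
and intergenic DNA, a large silent fraction among coding changes, a small
tail of "heavily mutated" genes, strain-specific multi-gene cassettes
bordered by mobile-element markers, and multiheme cytochrome genes whose
CXXCH motif counts are conserved.

Divergence is applied independently to each descendant at half the
configured pairwise rate, from a common ancestor, so the A-vs-B
comparison recovers the configured per-kb rates.  Strain A and strain B
substitutions are planted in disjoint codons so every pairwise difference
carries a well-defined synonymous/non-synonymous label under the
one-position-at-a-time evaluation rule.
"""
from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import numpy as np

from .model import (
    CODON_TABLE_11,
    STOP_CODONS,
    AnnotatedGenome,
    Feature,
    GeneModel,
    GroundTruth,
    StrainRegion,
    Variant,
    revcomp,
    translate_cds,
)

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SD = "AGGAGG"  # Shine-Dalgarno consensus planted upstream of starts
_MIN_GAP = 30
_CASSETTE_MARGIN = 60  # intergenic bases kept variant-free around cassette anchors


class SizingError(ValueError):
    """Requested features do not fit in the requested genome length."""


@dataclass
class GenomeSpec:
    """Shape of the ancestral genome to generate."""

    genome_length: int = 1_000_000
    gene_count: int | None = None  # derived from intergenic_fraction when None
    mean_gene_length: int = 900
    gc_content: float = 0.61
    intergenic_fraction: float = 0.10
    n_cytochrome_genes: int = 36
    motif_count_range: tuple[int, int] = (1, 12)
    n_trna: int = 12
    n_transposase: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if not 0 <= self.intergenic_fraction < 1:
            raise ValueError("intergenic_fraction must be in [0,1)")
        if self.gene_count is None:
            self.gene_count = int(
                self.genome_length * (1 - self.intergenic_fraction) // self.mean_gene_length
            )
        if self.mean_gene_length % 3 or self.mean_gene_length < 60:
            raise ValueError("mean_gene_length must be a codon multiple >= 60")
        lo, hi = self.motif_count_range
        if lo < 0 or hi < lo:
            raise ValueError("motif_count_range must be a non-decreasing pair")
        if self.n_cytochrome_genes + self.n_transposase > self.gene_count:
            raise ValueError("special gene counts exceed gene_count")


@dataclass
class DivergenceParams:
    """Pairwise divergence process parameters (rates are A-vs-B per kb)."""

    coding_snp_rate: float = 6.8
    noncoding_snp_rate: float = 10.5
    silent_fraction: float = 0.72
    indel_rate: float = 0.05
    max_indel_len: int = 12
    heavy_gene_fraction: float = 0.036
    n_unique_regions_a: int = 4
    n_unique_regions_b: int = 4
    unique_region_gene_range: tuple[int, int] = (2, 8)
    border_feature_prob: float = 0.667
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coding_snp_rate", "noncoding_snp_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.silent_fraction <= 1:
            raise ValueError("silent_fraction must be in [0,1]")
        if self.unique_region_gene_range[0] < 2:
            raise ValueError("unique regions must have at least 2 genes")


# ---------------------------------------------------------------------------
# ancestor generation
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _codon_tables(gc: float):
    """(codons, probabilities) for the 61 sense codons, GC-weighted."""
    p = _base_probs(gc)
    codons, probs = [], []
    for i, b1 in enumerate(_BASES):
        for j, b2 in enumerate(_BASES):
            for k, b3 in enumerate(_BASES):
                c = b1 + b2 + b3
                if c in STOP_CODONS:
                    continue
                codons.append(c)
                probs.append(p[i] * p[j] * p[k])
    probs = np.array(probs)
    return codons, probs / probs.sum()


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=_base_probs(gc))]) if n else ""


def _aa_codons() -> dict[str, list[str]]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in CODON_TABLE_11.items():
        if aa != "*":
            by_aa.setdefault(aa, []).append(codon)
    return by_aa


_BY_AA = _aa_codons()


def _gene_dna(rng: np.random.Generator, length: int, gc: float, *, cytochrome_motifs: int = 0) -> str:
    """Random CDS of ``length`` bases: start codon, no internal stop, stop codon.

    Non-cytochrome proteins are scrubbed of accidental CXXCH motifs so the
    planted cytochrome census is exact; cytochrome CDSs carry exactly
    ``cytochrome_motifs`` CXXCH motifs.
    """
    n_codons = length // 3
    if n_codons < 2:
        raise SizingError("gene shorter than start+stop")
    codons, probs = _codon_tables(gc)
    n_internal = n_codons - 2
    start = rng.choice(["ATG", "GTG", "TTG"], p=[0.80, 0.15, 0.05])
    stop = rng.choice(list(STOP_CODONS))
    if cytochrome_motifs:
        picks = [codons[i] for i in rng.choice(len(codons), size=n_internal, p=probs)]
        # backbone free of C and H, then exact motif insertion
        safe = [c for c in codons if CODON_TABLE_11[c] not in "CH"]
        for i, c in enumerate(picks):
            if CODON_TABLE_11[c] in "CH":
                picks[i] = safe[rng.integers(len(safe))]
        slots = n_internal - 4
        if cytochrome_motifs * 5 > n_internal:
            raise SizingError("gene too short for requested CXXCH motifs")
        offsets: list[int] = []
        while len(offsets) < cytochrome_motifs:
            o = int(rng.integers(0, slots))
            if all(abs(o - q) >= 5 for q in offsets):
                offsets.append(o)
        cys = _BY_AA["C"]
        his = _BY_AA["H"]
        for o in offsets:
            picks[o] = cys[rng.integers(len(cys))]
            picks[o + 3] = cys[rng.integers(len(cys))]
            picks[o + 4] = his[rng.integers(len(his))]
    else:
        picks = [codons[i] for i in rng.choice(len(codons), size=n_internal, p=probs)]
        # scrub accidental heme-binding motifs
        while True:
            prot = "M" + "".join(CODON_TABLE_11[c] for c in picks)
            hit = next(
                (
                    i
                    for i in range(len(prot) - 4)
                    if prot[i] == "C" and prot[i + 3] == "C" and prot[i + 4] == "H"
                ),
                None,
            )
            if hit is None:
                break
            safe = [c for c in _BY_AA if c not in "CH*"]
            aa = safe[rng.integers(len(safe))]
            picks[hit + 3] = _BY_AA[aa][rng.integers(len(_BY_AA[aa]))]  # replace the H
    return start + "".join(picks) + stop


def _sample_gene_lengths(rng: np.random.Generator, n: int, mean: int, min_len: int = 60) -> list[int]:
    raw = rng.normal(mean, mean / 4, size=n)
    return [max(min_len, int(round(x / 3)) * 3) for x in raw]


def generate_ancestor(spec: GenomeSpec, seed: int) -> AnnotatedGenome:
    """Generate an annotated ancestral genome per ``spec``.

    Deterministic in (spec, seed).  Raises :class:`SizingError` when the
    requested genes, tRNAs, and minimum intergenic gaps cannot be packed
    into ``genome_length``.
    """
    rng = np.random.default_rng(seed)
    n = spec.gene_count
    if n == 0:
        genome = AnnotatedGenome("ancestor", _random_dna(rng, spec.genome_length, spec.gc_content))
        if spec.n_trna:
            raise SizingError("tRNAs requested in a zero-gene genome are not supported")
        return genome

    lengths = _sample_gene_lengths(rng, n, spec.mean_gene_length)
    # roles: indices for cytochromes and transposases
    special = rng.choice(n, size=spec.n_cytochrome_genes + spec.n_transposase, replace=False)
    cyt_idx = set(special[: spec.n_cytochrome_genes].tolist())
    tpn_idx = set(special[spec.n_cytochrome_genes :].tolist())
    motif_counts = {
        i: int(rng.integers(spec.motif_count_range[0], spec.motif_count_range[1] + 1))
        for i in cyt_idx
    }
    for i in cyt_idx:  # cytochrome CDS must hold its motifs
        need = (motif_counts[i] * 5 + 10) * 3
        if lengths[i] < need:
            lengths[i] = need + (3 - need % 3) % 3

    leftover = spec.genome_length - sum(lengths)
    n_gaps = n + 1
    if leftover < _MIN_GAP * n_gaps:
        raise SizingError(
            f"{n} genes of total {sum(lengths)} bp do not fit in {spec.genome_length} bp "
            f"with {_MIN_GAP} bp minimum intergenic gaps"
        )
    # exponential weights give the roughly geometric intergenic-length
    # distribution of gene-dense genomes (and gaps big enough for tRNAs)
    weights = rng.exponential(1.0, n_gaps)
    extra = rng.multinomial(leftover - _MIN_GAP * n_gaps, weights / weights.sum())
    gaps = [_MIN_GAP + int(e) for e in extra]

    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]
    parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0  # 0-based build cursor
    gap_spans: list[tuple[int, int]] = []  # 1-based inclusive intergenic spans
    for i in range(n):
        gap_seq = list(_random_dna(rng, gaps[i], spec.gc_content))
        # plant an SD hexamer for this gene (if '+') in the -15..-5 window,
        # and for the previous gene (if '-') just downstream of its start codon
        if strands[i] == "+" and gaps[i] >= 15:
            off = gaps[i] - 12  # occupies -12..-7 relative to the start
            gap_seq[off : off + 6] = _SD
        if i > 0 and strands[i - 1] == "-" and gaps[i] >= 15:
            gap_seq[6:12] = revcomp(_SD)
        parts.append("".join(gap_seq))
        gap_spans.append((pos + 1, pos + gaps[i]))
        pos += gaps[i]
        dna = _gene_dna(
            rng,
            lengths[i],
            spec.gc_content,
            cytochrome_motifs=motif_counts.get(i, 0),
        )
        placed = revcomp(dna) if strands[i] == "-" else dna
        start = pos + 1
        end = pos + lengths[i]
        if i in cyt_idx:
            product = "cytochrome c family protein"
        elif i in tpn_idx:
            product = "transposase"
        else:
            product = "hypothetical protein"
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:04d}",
                start=start,
                end=end,
                strand=strands[i],
                product=product,
                is_transposase=i in tpn_idx,
            )
        )
        parts.append(placed)
        pos += lengths[i]
    tail = list(_random_dna(rng, gaps[n], spec.gc_content))
    if strands[n - 1] == "-" and gaps[n] >= 15:
        tail[6:12] = revcomp(_SD)
    parts.append("".join(tail))
    gap_spans.append((pos + 1, pos + gaps[n]))

    genome = AnnotatedGenome("ancestor", "".join(parts), genes)
    # tRNAs in intergenic gaps large enough to hold them clear of SD windows
    if spec.n_trna:
        big = [s for s in gap_spans if s[1] - s[0] + 1 >= 110]
        if len(big) < spec.n_trna:
            raise SizingError("not enough large intergenic gaps for requested tRNAs")
        chosen = rng.choice(len(big), size=spec.n_trna, replace=False)
        for gi in sorted(int(c) for c in chosen):
            s, e = big[gi]
            mid = (s + e) // 2
            genome.other_features.append(Feature("tRNA", mid - 37, mid + 37, "+"))
    for g in genome.genes:
        g.protein = genome.translate_gene(g)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------

class _EventMap:
    """Coordinate map from ancestor to descendant through indel events.

    Events are anchored at the last unaffected ancestor base ``p``:
    an insertion adds bases after ``p``; a deletion removes ancestor bases
    ``p+1..p+len``.
    """

    def __init__(self) -> None:
        self.events: list[tuple[int, int, int]] = []  # (p, ins_len, del_len)

    def add(self, p: int, ins_len: int = 0, del_len: int = 0) -> None:
        self.events.append((p, ins_len, del_len))

    def freeze(self) -> None:
        self.events.sort()
        self._anchors = [e[0] for e in self.events]
        self._cum = []
        c = 0
        for _, ins, dl in self.events:
            c += ins - dl
            self._cum.append(c)

    def map(self, q: int) -> int:
        i = bisect.bisect_right(self._anchors, q - 1) - 1
        # events strictly before q (anchor p affects only positions > p;
        # deletions additionally require q > p + del_len, guaranteed by
        # construction because mapped positions never sit inside deletions)
        delta = 0
        for j in range(i, -1, -1):
            p, ins, dl = self.events[j]
            if q > p:
                delta = self._cum[j]
                if q <= p + dl:
                    raise ValueError(f"position {q} was deleted")
                break
        return q + delta


def _codon_effect(codon: str, pos: int, alt: str) -> str:
    mutated = codon[:pos] + alt + codon[pos + 1 :]
    return "synonymous" if CODON_TABLE_11[codon] == CODON_TABLE_11[mutated] else "nonsynonymous"


def _motif_safe(protein: str, res_idx: int, new_aa: str) -> bool:
    """Would replacing residue ``res_idx`` (0-based) preserve local CXXCH count?"""
    lo = max(0, res_idx - 4)
    hi = min(len(protein), res_idx + 5)
    window_old = protein[lo:hi]
    window_new = protein[lo:res_idx] + new_aa + protein[res_idx + 1 : hi]
    return _scan_cxxch_window(window_old) == _scan_cxxch_window(window_new)


def _scan_cxxch_window(w: str) -> int:
    return sum(
        1 for i in range(len(w) - 4) if w[i] == "C" and w[i + 3] == "C" and w[i + 4] == "H"
    )


@dataclass
class _PlantedSnp:
    gene_i: int | None  # index into ancestor.genes, None = intergenic
    anc_pos: int  # ancestor genome coordinate (1-based)
    strain: str  # 'A' or 'B'
    ref: str  # ancestor base at anc_pos (genome strand)
    alt: str  # descendant base (genome strand)
    effect: str
    codon_idx: int = -1
    codon_pos: int = -1


def diverge(
    ancestor: AnnotatedGenome, params: DivergenceParams
) -> tuple[AnnotatedGenome, AnnotatedGenome, GroundTruth]:
    """Derive two descendant strains from ``ancestor`` with full ground truth."""
    rng = np.random.default_rng(params.seed)
    L = ancestor.length
    genes = ancestor.genes
    coding_len = sum(g.length for g in genes)
    intergenic_len = L - coding_len

    # --- choose cassette insertion anchors first: variants keep clear of them
    gap_spans = _intergenic_spans(ancestor)
    cassettes = _build_cassettes(rng, ancestor, params, gap_spans)
    blocked = set()
    for strain, anchor, seg, *_ in cassettes:
        for q in range(anchor - _CASSETTE_MARGIN, anchor + _CASSETTE_MARGIN + 1):
            blocked.add(q)

    # --- coding SNPs -------------------------------------------------------
    n_cod = int(rng.poisson(params.coding_snp_rate * coding_len / 1000.0)) if coding_len else 0
    heavy_ids = _pick_heavy(rng, genes, params)
    forced: list[tuple[int, int]] = []  # (gene_i, n_forced)
    for gi in heavy_ids:
        t = math.ceil(12 * genes[gi].length / 1000)
        forced.append((gi, t))
    n_forced = sum(t for _, t in forced)
    if n_cod and n_forced > 0.8 * n_cod:
        raise ValueError(
            "heavy-gene NS quota exceeds 80% of the coding SNP budget; "
            "raise coding_snp_rate or lower heavy_gene_fraction"
        )
    p_syn_bg = 0.0
    if n_cod > n_forced:
        p_syn_bg = min(1.0, params.silent_fraction * n_cod / (n_cod - n_forced))

    base_cds = {i: ancestor.cds_nt(g) for i, g in enumerate(genes) if not g.pseudo}
    cds_cache = {"A": dict(base_cds), "B": dict(base_cds)}
    prot_cache = {
        "A": {i: translate_cds(c) for i, c in base_cds.items()},
        "B": {i: translate_cds(c) for i, c in base_cds.items()},
    }
    mutable: list[tuple[int, int]] = []  # (gene_i, codon_idx), start/stop excluded
    for i, cds in base_cds.items():
        n_codons = len(cds) // 3
        mutable.extend((i, ci) for ci in range(1, n_codons - 1))
    used_codon: dict[tuple[int, int], str] = {}  # (gene_i, codon_idx) -> strain
    used_pos: set[tuple[int, int, int]] = set()  # (gene_i, codon_idx, pos_in_codon)
    snps: list[_PlantedSnp] = []

    def plant_coding(gene_i: int, codon_idx: int, strain: str, effect: str) -> bool:
        cds = cds_cache[strain][gene_i]
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        prot = prot_cache[strain][gene_i]
        options = []
        for pos in range(3):
            if (gene_i, codon_idx, pos) in used_pos:
                continue  # one substitution per codon position
            for alt in _BASES:
                if alt == codon[pos]:
                    continue
                mutated = codon[:pos] + alt + codon[pos + 1 :]
                if mutated in STOP_CODONS:
                    continue  # no premature stops: keeps genes non-pseudo
                if _codon_effect(codon, pos, alt) != effect:
                    continue
                if effect == "nonsynonymous" and not _motif_safe(
                    prot, codon_idx, CODON_TABLE_11[mutated]
                ):
                    continue
                options.append((pos, alt, mutated))
        if not options:
            return False
        pos, alt, mutated = options[rng.integers(len(options))]
        g = genes[gene_i]
        if g.strand == "+":
            anc_pos = g.start + codon_idx * 3 + pos
            ref_g, alt_g = codon[pos], alt
        else:
            anc_pos = g.end - (codon_idx * 3 + pos)
            ref_g, alt_g = _COMP[codon[pos]], _COMP[alt]
        # update this strain's caches so later SNPs see the new state
        cds_cache[strain][gene_i] = cds[: codon_idx * 3] + mutated + cds[codon_idx * 3 + 3 :]
        prot_cache[strain][gene_i] = (
            prot[:codon_idx] + CODON_TABLE_11[mutated] + prot[codon_idx + 1 :]
        )
        snps.append(
            _PlantedSnp(gene_i, anc_pos, strain, ref_g, alt_g, effect, codon_idx, pos)
        )
        used_codon[(gene_i, codon_idx)] = strain
        used_pos.add((gene_i, codon_idx, pos))
        return True

    # forced heavy-gene NS substitutions, then the background
    for gene_i, t in forced:
        n_codons = genes[gene_i].length // 3
        pool = [ci for ci in range(1, n_codons - 1) if (gene_i, ci) not in used_codon]
        if t > len(pool):
            raise ValueError(f"gene {genes[gene_i].gene_id} too short to force 12 NS/kb")
        take = rng.choice(len(pool), size=t, replace=False)
        for ci in (pool[int(j)] for j in take):
            strain = "A" if rng.random() < 0.5 else "B"
            if not plant_coding(gene_i, ci, strain, "nonsynonymous"):
                # fall back to another codon of the same gene
                for ci2 in rng.permutation([c for c in pool if (gene_i, c) not in used_codon]):
                    if plant_coding(gene_i, int(ci2), strain, "nonsynonymous"):
                        break
    n_background = n_cod - len(snps)
    for _ in range(n_background):
        # the target effect is fixed first; an impossible site (e.g. no
        # synonymous change for ATG/TGG) resamples the codon, never the
        # effect, so the realized silent fraction stays unbiased
        effect = "synonymous" if rng.random() < p_syn_bg else "nonsynonymous"
        for _attempt in range(500):
            gene_i, ci = mutable[int(rng.integers(len(mutable)))]
            strain = "A" if rng.random() < 0.5 else "B"
            prev = used_codon.get((gene_i, ci))
            if prev is not None and prev != strain:
                continue  # strains never touch the same codon
            if plant_coding(gene_i, ci, strain, effect):
                break
        else:
            raise ValueError("could not place a coding SNP after 500 site draws")

    # codons hit twice within one strain: the final pairwise label follows
    # the one-position-at-a-time rule, which can flip a forced NS to
    # synonymous; relabel now and top heavy genes back up in fresh codons
    _relabel_multihit(ancestor, snps)
    for gene_i, t in forced:
        while sum(
            1 for s in snps if s.gene_i == gene_i and s.effect == "nonsynonymous"
        ) < t:
            n_codons = genes[gene_i].length // 3
            pool = [ci for ci in range(1, n_codons - 1) if (gene_i, ci) not in used_codon]
            if not pool:
                raise ValueError(
                    f"gene {genes[gene_i].gene_id} exhausted while forcing 12 NS/kb"
                )
            ci = pool[int(rng.integers(len(pool)))]
            strain = "A" if rng.random() < 0.5 else "B"
            plant_coding(gene_i, ci, strain, "nonsynonymous")

    # --- intergenic SNPs ---------------------------------------------------
    n_nc = int(rng.poisson(params.noncoding_snp_rate * intergenic_len / 1000.0)) if intergenic_len else 0
    intergenic_pos = _intergenic_positions(gap_spans)
    ok = [p for p in intergenic_pos if p not in blocked and 100 < p < L - 100]
    if n_nc > len(ok):
        n_nc = len(ok)
    chosen = rng.choice(len(ok), size=n_nc, replace=False) if n_nc else []
    for j in chosen:
        p = ok[int(j)]
        strain = "A" if rng.random() < 0.5 else "B"
        ref = ancestor.sequence[p - 1]
        alt = _BASES[int(rng.integers(4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(4))]
        snps.append(_PlantedSnp(None, p, strain, ref, alt, "noncoding"))

    # --- indels ------------------------------------------------------------
    indels = _plan_indels(rng, ancestor, params, gap_spans, blocked, snps)

    # --- assemble descendants ---------------------------------------------
    strain_a, map_a = _build_strain(rng, ancestor, "A", snps, indels, cassettes, params)
    strain_b, map_b = _build_strain(rng, ancestor, "B", snps, indels, cassettes, params)

    truth = _ground_truth(ancestor, snps, indels, cassettes, map_a, map_b, heavy_ids)
    return strain_a, strain_b, truth


def _pick_heavy(rng, genes, params) -> list[int]:
    eligible = [i for i, g in enumerate(genes) if not g.pseudo and g.length >= 300]
    n = int(round(params.heavy_gene_fraction * len(genes)))
    if n == 0:
        return []
    if n > len(eligible):
        raise ValueError("not enough eligible genes for requested heavy fraction")
    return sorted(int(i) for i in rng.choice(eligible, size=n, replace=False))


def _intergenic_spans(genome: AnnotatedGenome) -> list[tuple[int, int]]:
    spans = []
    pos = 1
    for g in sorted(genome.genes, key=lambda g: g.start):
        if g.start > pos:
            spans.append((pos, g.start - 1))
        pos = max(pos, g.end + 1)
    if pos <= genome.length:
        spans.append((pos, genome.length))
    return spans


def _intergenic_positions(spans: list[tuple[int, int]]) -> list[int]:
    out: list[int] = []
    for s, e in spans:
        out.extend(range(s, e + 1))
    return out


def _build_cassettes(rng, ancestor, params, gap_spans):
    """Plan strain-specific cassettes: (strain, anchor, segment, genes, features, border)."""
    plans = []
    feat_spans = [(f.start, f.end) for f in ancestor.other_features]
    big_gaps = [
        s
        for s in gap_spans
        if s[1] - s[0] + 1 >= _MIN_GAP * 2
        and not any(fs <= s[1] and fe >= s[0] for fs, fe in feat_spans)
    ]
    anchors_used: list[int] = []
    want = [("A", params.n_unique_regions_a), ("B", params.n_unique_regions_b)]
    n_total = params.n_unique_regions_a + params.n_unique_regions_b
    # cassette spacing scales with the genome so small test genomes pack
    min_sep = min(20_000, max(2_000, ancestor.length // (4 * max(n_total, 1))))
    for strain, count in want:
        for _ in range(count):
            anchor = _pick_anchor(rng, big_gaps, anchors_used, min_sep)
            anchors_used.append(anchor)
            seg, seg_genes, seg_feats, border = _cassette_segment(rng, params)
            plans.append((strain, anchor, seg, seg_genes, seg_feats, border))
    return plans


def _pick_anchor(rng, big_gaps, used, min_sep: int) -> int:
    for _ in range(1000):
        s, e = big_gaps[int(rng.integers(len(big_gaps)))]
        anchor = (s + e) // 2
        if all(abs(anchor - u) >= min_sep for u in used):
            return anchor
    raise SizingError("cannot place unique-region cassettes with adequate separation")


def _cassette_segment(rng, params):
    """One strain-specific cassette: genes, optional border feature, sequence."""
    lo, hi = params.unique_region_gene_range
    n_genes = int(rng.integers(lo, hi + 1))
    border: frozenset[str] = frozenset()
    border_kind = None
    if rng.random() < params.border_feature_prob:
        border_kind = ["transposase_or_integrase"] * 8 + ["trna"] * 3 + ["repeat"]
        border_kind = border_kind[int(rng.integers(12))]
        border = frozenset({border_kind})
    parts: list[str] = []
    seg_genes: list[tuple[int, int, str, str, bool]] = []  # (start, end, strand, product, is_tpn)
    seg_feats: list[tuple[str, int, int]] = []
    pos = 0
    lead = int(rng.integers(40, 120))
    if border_kind == "trna":
        parts.append(_random_dna(rng, 10, 0.5))
        seg_feats.append(("tRNA", 11, 85))
        parts.append(_random_dna(rng, 75, 0.5))
        parts.append(_random_dna(rng, 10, 0.5))
        pos = 95
    elif border_kind == "repeat":
        rep = _random_dna(rng, 60, 0.5)
        seg_feats.append(("repeat", 1, 60))
        parts.append(rep)
        pos = 60
    tpn_gene = int(rng.integers(n_genes)) if border_kind == "transposase_or_integrase" else -1
    for i in range(n_genes):
        parts.append(_random_dna(rng, lead, 0.5))
        pos += lead
        glen = max(60, int(round(rng.normal(800, 150) / 3)) * 3)
        dna = _gene_dna(rng, glen, 0.5)
        strand = "+" if rng.random() < 0.5 else "-"
        product = "integrase/transposase family protein" if i == tpn_gene else "hypothetical protein"
        seg_genes.append((pos + 1, pos + glen, strand, product, i == tpn_gene))
        parts.append(revcomp(dna) if strand == "-" else dna)
        pos += glen
        lead = int(rng.integers(40, 120))
    parts.append(_random_dna(rng, int(rng.integers(40, 120)), 0.5))
    return "".join(parts), seg_genes, seg_feats, border


def _plan_indels(rng, ancestor, params, gap_spans, blocked, snps):
    """Small indels: mostly intergenic, some in the final 10% of a minority of genes."""
    L = ancestor.length
    n = int(rng.poisson(params.indel_rate * L / 1000.0)) if params.indel_rate > 0 else 0
    if n == 0:
        return []
    snp_pos = {s.anc_pos for s in snps}
    # frameshifts stay out of cytochromes so the planted motif census is exact
    genes = [g for g in ancestor.genes if g.length >= 150 and "cytochrome" not in g.product]
    fs_genes = (
        [int(i) for i in rng.choice(len(genes), size=max(1, len(genes) // 10), replace=False)]
        if genes
        else []
    )
    intergenic = [
        p
        for p in _intergenic_positions(gap_spans)
        if p not in blocked and 100 < p < L - 100
    ]
    out = []  # (strain, anchor_p, ins_seq, del_len, gene_i or None)
    taken: list[int] = []
    for _ in range(n):
        strain = "A" if rng.random() < 0.5 else "B"
        length = int(rng.integers(1, params.max_indel_len + 1))
        is_ins = rng.random() < 0.5
        in_gene = fs_genes and rng.random() < 0.2
        for _try in range(200):
            if in_gene:
                gi = fs_genes[int(rng.integers(len(fs_genes)))]
                g = genes[gi]
                tail_lo = g.start + int(g.length * 0.9)
                p = int(rng.integers(tail_lo, g.end - 3 - length))
                gene_i = ancestor.genes.index(g)
            else:
                p = intergenic[int(rng.integers(len(intergenic)))]
                gene_i = None
            span = range(p - params.max_indel_len - 2, p + length + params.max_indel_len + 2)
            if any(abs(p - t) < 2 * params.max_indel_len + 4 for t in taken):
                continue
            if any(q in snp_pos for q in span):
                continue
            if not in_gene and any(q in blocked for q in span):
                continue
            taken.append(p)
            ins_seq = _random_dna(rng, length, 0.5) if is_ins else ""
            del_len = 0 if is_ins else length
            out.append((strain, p, ins_seq, del_len, gene_i))
            break
    return out


def _build_strain(rng, ancestor, strain, snps, indels, cassettes, params):
    """Apply this strain's SNPs and events to the ancestor sequence."""
    seq = list(ancestor.sequence)
    for s in snps:
        if s.strain == strain:
            assert seq[s.anc_pos - 1] == s.ref
            seq[s.anc_pos - 1] = s.alt
    emap = _EventMap()
    segments: list[tuple[int, str, list, list]] = []  # (anchor, seg, genes, feats)
    for st, anchor, seg, seg_genes, seg_feats, _border in cassettes:
        if st == strain:
            emap.add(anchor, ins_len=len(seg))
            segments.append((anchor, seg, seg_genes, seg_feats))
    for st, p, ins_seq, del_len, _gene_i in indels:
        if st == strain:
            emap.add(p, ins_len=len(ins_seq), del_len=del_len)
    emap.freeze()
    segments.sort(key=lambda s: s[0])
    # stitch sequence
    pieces = []
    cursor = 0  # 0-based, exclusive end of what is emitted
    for p, ins, dl in emap.events:
        pieces.append("".join(seq[cursor:p]))
        seg_text = next((s for a, s, _, _ in segments if a == p), None)
        if seg_text is not None:
            pieces.append(seg_text)
        else:
            for st, q, ins_seq, del_len, _g in indels:
                if st == strain and q == p and ins_seq:
                    pieces.append(ins_seq)
                    break
        cursor = p + dl
    pieces.append("".join(seq[cursor:]))
    new_seq = "".join(pieces)

    new_genes = []
    for g in ancestor.genes:
        new_genes.append(
            GeneModel(
                gene_id=f"{strain}_{g.gene_id}",
                start=emap.map(g.start),
                end=emap.map(g.end),
                strand=g.strand,
                product=g.product,
                is_transposase=g.is_transposase,
            )
        )
    new_feats = [
        Feature(f.type, emap.map(f.start), emap.map(f.end), f.strand)
        for f in ancestor.other_features
    ]
    for ci, (anchor, seg, seg_genes, seg_feats) in enumerate(segments):
        base = emap.map(anchor)
        for gi, (s, e, strand_g, product, is_tpn) in enumerate(seg_genes):
            new_genes.append(
                GeneModel(
                    gene_id=f"{strain}_c{ci + 1:02d}g{gi + 1}",
                    start=base + s,
                    end=base + e,
                    strand=strand_g,
                    product=product,
                    is_transposase=is_tpn,
                )
            )
        for ftype, s, e in seg_feats:
            new_feats.append(Feature(ftype, base + s, base + e, "+"))
    new_genes.sort(key=lambda g: g.start)
    genome = AnnotatedGenome(f"strain{strain}", new_seq, new_genes, new_feats)
    for g in genome.genes:
        if g.length % 3 == 0:
            prot = genome.translate_gene(g)
            if "*" in prot:
                g.pseudo = True
            else:
                g.protein = prot
        else:
            g.pseudo = True
    genome.validate()
    return genome, emap


def _ground_truth(ancestor, snps, indels, cassettes, map_a, map_b, heavy_ids) -> GroundTruth:
    genes = ancestor.genes
    truth = GroundTruth()
    truth.ortholog_map = [(f"A_{g.gene_id}", f"B_{g.gene_id}") for g in genes]
    truth.heavy_genes = [f"A_{genes[i].gene_id}" for i in heavy_ids]

    variants: list[Variant] = []
    for s in snps:
        pa, pb = map_a.map(s.anc_pos), map_b.map(s.anc_pos)
        if s.strain == "A":
            ref, alt = s.alt, s.ref
        else:
            ref, alt = s.ref, s.alt
        variants.append(
            Variant(
                pos_a=pa,
                pos_b=pb,
                kind="snp",
                ref=ref,
                alt=alt,
                gene_id=f"A_{genes[s.gene_i].gene_id}" if s.gene_i is not None else None,
                effect=s.effect,
            )
        )
    for st, p, ins_seq, del_len, gene_i in indels:
        run = ins_seq if ins_seq else ancestor.sequence[p : p + del_len]
        # planted in A: A gained/lost bases; express relative to A as reference
        if (st == "A") == bool(ins_seq):
            kind, ref, alt = "deletion", run, ""  # present in A, absent in B
        else:
            kind, ref, alt = "insertion", "", run
        variants.append(
            Variant(
                pos_a=map_a.map(p),
                pos_b=map_b.map(p),
                kind=kind,
                ref=ref,
                alt=alt,
                gene_id=f"A_{genes[gene_i].gene_id}" if gene_i is not None else None,
                effect="indel",
            )
        )
    variants.sort(key=lambda v: v.pos_a)
    truth.planted_variants = variants

    for st, anchor, seg, seg_genes, seg_feats, border in cassettes:
        emap = map_a if st == "A" else map_b
        base = emap.map(anchor)
        ci = sum(
            1
            for st2, a2, *_ in cassettes
            if st2 == st and a2 <= anchor
        )
        gene_ids = [f"{st}_c{ci:02d}g{gi + 1}" for gi in range(len(seg_genes))]
        truth.unique_regions.append(
            StrainRegion(
                strain=st,
                start=base + seg_genes[0][0],
                end=base + seg_genes[-1][1],
                gene_ids=gene_ids,
                border=border,
            )
        )
    return truth


def _relabel_multihit(ancestor, snps) -> None:
    """Re-label SNPs in codons hit more than once with the pairwise rule.

    The analysis evaluates each position independently: mutate the strain-A
    codon at that position to the strain-B base, holding other positions at
    the strain-A state.
    """
    from collections import Counter

    hit = Counter((s.gene_i, s.codon_idx) for s in snps if s.gene_i is not None)
    multi = {k for k, c in hit.items() if c > 1 and k[1] >= 0}
    if not multi:
        return
    for s in snps:
        if s.gene_i is None or (s.gene_i, s.codon_idx) not in multi:
            continue
        g = ancestor.genes[s.gene_i]
        # reconstruct both strains' codons from planted SNPs
        anc_cds = ancestor.cds_nt(g)
        codon = list(anc_cds[s.codon_idx * 3 : s.codon_idx * 3 + 3])
        codon_a, codon_b = codon[:], codon[:]
        for s2 in snps:
            if s2.gene_i == s.gene_i and s2.codon_idx == s.codon_idx:
                base = s2.alt if g.strand == "+" else _COMP[s2.alt]
                (codon_a if s2.strain == "A" else codon_b)[s2.codon_pos] = base
        a = "".join(codon_a)
        mutated = codon_a[:]
        mutated[s.codon_pos] = codon_b[s.codon_pos]
        m = "".join(mutated)
        s.effect = (
            "synonymous" if CODON_TABLE_11[a] == CODON_TABLE_11[m] else "nonsynonymous"
        )


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_outputs(outdir, strain_a, strain_b, truth) -> dict[str, str]:
    """Write FASTA/GFF3 for both strains and the three ground-truth tables."""
    import pandas as pd
    from pathlib import Path

    from .io_formats import write_fasta, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, genome in (("strainA", strain_a), ("strainB", strain_b)):
        write_fasta(outdir / f"{name}.fasta", genome.strain_id, genome.sequence)
        write_gff3(outdir / f"{name}.gff3", genome)
        paths[f"{name}.fasta"] = str(outdir / f"{name}.fasta")
        paths[f"{name}.gff3"] = str(outdir / f"{name}.gff3")
    pd.DataFrame(truth.ortholog_map, columns=["gene_id_a", "gene_id_b"]).to_csv(
        outdir / "truth_orthologs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "pos_a": v.pos_a,
                "pos_b": v.pos_b,
                "kind": v.kind,
                "ref": v.ref,
                "alt": v.alt,
                "gene_id": v.gene_id or "",
                "effect": v.effect,
            }
            for v in truth.planted_variants
        ]
    ).to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "strain": r.strain,
                "start": r.start,
                "end": r.end,
                "gene_ids": ",".join(r.gene_ids),
                "border": ",".join(sorted(r.border)) or "none",
            }
            for r in truth.unique_regions
        ]
    ).to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
    paths["truth_orthologs.tsv"] = str(outdir / "truth_orthologs.tsv")
    paths["truth_variants.tsv"] = str(outdir / "truth_variants.tsv")
    paths["truth_regions.tsv"] = str(outdir / "truth_regions.tsv")
    return paths
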
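"""Core data model shared by all pipeline stages.

Coordinates are 1-based inclusive throughout (the GenBank/GFF convention);
algorithms convert to 0-based internally where needed.  Genomes are single
circular bacterial chromosomes represented as linear strings; features never
span the origin.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from Bio.Data import CodonTable

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_T11 = CodonTable.unambiguous_dna_by_id[11]
#: codon -> amino acid for the bacterial/archaeal/plastid code; stops map to '*'
CODON_TABLE_11: dict[str, str] = dict(_T11.forward_table)
CODON_TABLE_11.update({c: "*" for c in _T11.stop_codons})
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = tuple(_T11.stop_codons)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate_cds(nt: str, *, as_start: bool = True) -> str:
    """Translate an in-frame CDS with translation table 11.

    The initiator codon is rendered as M when it is a valid bacterial start
    (``as_start``); a trailing stop codon is stripped.  Internal stops are
    rendered as ``*`` so callers can detect pseudogenes.
    """
    if len(nt) % 3:
        raise ValueError("CDS length not divisible by 3")
    aas = [CODON_TABLE_11[nt[i : i + 3]] for i in range(0, len(nt), 3)]
    if aas and aas[-1] == "*":
        aas.pop()
    if as_start and aas and nt[:3] in START_CODONS:
        aas[0] = "M"
    return "".join(aas)


@dataclass
class GeneModel:
    """A protein-coding gene on one strain's chromosome."""

    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    product: str = ""
    is_transposase: bool = False
    is_trna_adjacent: bool = False
    pseudo: bool = False
    protein: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Feature:
    """A non-CDS feature (tRNA, repeat)."""

    type: str  # 'tRNA' | 'repeat'
    start: int
    end: int
    strand: str = "+"


@dataclass
class AnnotatedGenome:
    """One strain: chromosome sequence plus gene models and other features."""

    strain_id: str
    sequence: str
    genes: list[GeneModel] = field(default_factory=list)
    other_features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id: dict[str, GeneModel] | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene(self, gene_id: str) -> GeneModel:
        if self._by_id is None or len(self._by_id) != len(self.genes):
            self._by_id = {g.gene_id: g for g in self.genes}
        return self._by_id[gene_id]

    def cds_nt(self, gene: GeneModel | str) -> str:
        """Coding-strand nucleotide sequence of a gene (5'->3')."""
        if isinstance(gene, str):
            gene = self.gene(gene)
        s = self.sequence[gene.start - 1 : gene.end]
        return revcomp(s) if gene.strand == "-" else s

    def translate_gene(self, gene: GeneModel | str) -> str:
        return translate_cds(self.cds_nt(gene))

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if not (1 <= g.start <= g.end <= self.length):
                raise ValueError(f"gene {g.gene_id} outside sequence")
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
        for f in self.other_features:
            if not (1 <= f.start <= f.end <= self.length):
                raise ValueError(f"{f.type} feature outside sequence")


@dataclass
class AlignmentBlock:
    """A collinear aligned segment of two genomes.

    ``a_gapped``/``b_gapped`` are equal-length strings over {A,C,G,T,N,-};
    no column is a gap in both tracks.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    a_gapped: str
    b_gapped: str

    def __len__(self) -> int:
        return len(self.a_gapped)

    def validate(self, seq_a: str | None = None, seq_b: str | None = None) -> None:
        if len(self.a_gapped) != len(self.b_gapped):
            raise ValueError("gapped tracks differ in length")
        ua = self.a_gapped.replace("-", "")
        ub = self.b_gapped.replace("-", "")
        if len(ua) != self.a_end - self.a_start + 1:
            raise ValueError("A coordinates inconsistent with ungapped length")
        if len(ub) != self.b_end - self.b_start + 1:
            raise ValueError("B coordinates inconsistent with ungapped length")
        if seq_a is not None and ua != seq_a[self.a_start - 1 : self.a_end]:
            raise ValueError("A track does not match genome slice")
        if seq_b is not None and ub != seq_b[self.b_start - 1 : self.b_end]:
            raise ValueError("B track does not match genome slice")
        for ca, cb in zip(self.a_gapped, self.b_gapped):
            if ca == "-" and cb == "-":
                raise ValueError("column gapped in both tracks")


class AlignmentIndex:
    """Position map between two genomes built from alignment blocks.

    Maps strain-A coordinates to strain-B coordinates for every aligned
    (non-gap) column; used by synteny orthology and variant calling.
    """

    def __init__(self, blocks: list[AlignmentBlock]):
        self.blocks = sorted(blocks, key=lambda b: b.a_start)
        self._starts = [b.a_start for b in self.blocks]
        # per block: list of (a_pos, b_pos) runs for matched columns
        self._maps: list[list[tuple[int, int, int]]] = []  # (a_from, b_from, run)
        for b in self.blocks:
            runs: list[tuple[int, int, int]] = []
            ap, bp = b.a_start, b.b_start
            run_a = run_b = run_len = 0
            for ca, cb in zip(b.a_gapped, b.b_gapped):
                if ca != "-" and cb != "-":
                    if run_len and ap == run_a + run_len and bp == run_b + run_len:
                        run_len += 1
                    else:
                        if run_len:
                            runs.append((run_a, run_b, run_len))
                        run_a, run_b, run_len = ap, bp, 1
                if ca != "-":
                    ap += 1
                if cb != "-":
                    bp += 1
            if run_len:
                runs.append((run_a, run_b, run_len))
            self._maps.append(runs)

    def map_interval(self, a_start: int, a_end: int) -> tuple[int, int] | None:
        """B-coordinate span aligned to A interval, or None if unaligned."""
        lo: int | None = None
        hi: int | None = None
        last = bisect.bisect_right(self._starts, a_end)  # blocks starting at/before a_end
        for j in range(last):
            if self.blocks[j].a_end < a_start:
                continue
            for ra, rb, n in self._maps[j]:
                s = max(ra, a_start)
                e = min(ra + n - 1, a_end)
                if s <= e:
                    b_lo = rb + (s - ra)
                    b_hi = rb + (e - ra)
                    lo = b_lo if lo is None else min(lo, b_lo)
                    hi = b_hi if hi is None else max(hi, b_hi)
        if lo is None:
            return None
        return lo, hi


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    methods: frozenset[str]  # subset of {'synteny', 'rbh'}
    protein_identity: float = 0.0
    coverage_of_longer: float = 0.0
    identical_protein: bool = False
    identical_nucleotide: bool = False


class OrthologTable:
    """Final one-to-one ortholog set with method provenance."""

    def __init__(self, pairs: list[OrthologPair], n_agree: int = 0):
        self.pairs = pairs
        self.n_agree = n_agree
        self.by_a = {p.gene_a: p for p in pairs}
        self.by_b = {p.gene_b: p for p in pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class Variant:
    """A single difference between the strains, strain A as reference.

    ``pos_a``/``pos_b`` are 1-based; indels are anchored at the last shared
    base on the left flank, and a gap run of length n is one event.
    """

    pos_a: int
    pos_b: int
    kind: str  # 'snp' | 'insertion' | 'deletion'
    ref: str
    alt: str
    gene_id: str | None = None
    effect: str = "not_classified"  # synonymous|nonsynonymous|noncoding|indel|not_classified


@dataclass
class StrainRegion:
    """A run of >=2 consecutive genes with no ortholog in the other strain."""

    strain: str
    start: int
    end: int
    gene_ids: list[str]
    border: frozenset[str]  # subset of {transposase_or_integrase, trna, repeat}


@dataclass
class GroundTruth:
    """Everything the generator planted, for validating the pipeline."""

    ortholog_map: list[tuple[str, str]] = field(default_factory=list)
    planted_variants: list[Variant] = field(default_factory=list)
    unique_regions: list[StrainRegion] = field(default_factory=list)
    heavy_genes: list[str] = field(default_factory=list)

    @property
    def snvs(self) -> list[Variant]:
        return [v for v in self.planted_variants if v.kind == "snp"]
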
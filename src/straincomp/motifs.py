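"""c-type cytochrome heme-binding motif (CXXCH) census.

The heme of a c-type cytochrome is covalently attached at a C-X-X-C-H
sequence motif.  The scan is a pure pattern count: all occurrences are
reported, including overlapping ones, and the longer-spacer variants
(CX3CH, CX4CH) are deliberately not matched.  Reduction of the motif
census to curated cytochromes requires functional judgement and is only
reproducible through a user-supplied exclusion list.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .model import AnnotatedGenome, OrthologTable

log = logging.getLogger(__name__)


@dataclass
class MotifHit:
    gene_id: str
    offset: int  # 1-based residue position of the motif's first C
    matched: str


def scan_cxxch(protein: str, gene_id: str = "") -> list[MotifHit]:
    """All CXXCH occurrences in a protein, in order, overlaps included.

    X is any residue; an ambiguity character 'X' in the protein never
    satisfies the C or H slots.
    """
    hits = []
    for i in range(len(protein) - 4):
        if protein[i] == "C" and protein[i + 3] == "C" and protein[i + 4] == "H":
            hits.append(MotifHit(gene_id, i + 1, protein[i : i + 5]))
    return hits


def cytochrome_census(
    genome: AnnotatedGenome, exclusion_list: set[str] | None = None
) -> tuple[int, list[str], dict[str, int]]:
    """(n proteins with >=1 motif, candidate cytochromes, per-protein counts).

    ``exclusion_list`` carries the ids of motif-bearing proteins excluded
    on functional/localization grounds (manual curation, not computable);
    candidates are the motif proteins minus the exclusions.
    """
    exclusion_list = exclusion_list or set()
    counts: dict[str, int] = {}
    for g in genome.genes:
        if g.pseudo or not g.protein:
            continue
        n = len(scan_cxxch(g.protein, g.gene_id))
        if n:
            counts[g.gene_id] = n
    missing = exclusion_list - {g.gene_id for g in genome.genes}
    if missing:
        log.warning("%d exclusion ids absent from proteome: %s", len(missing), sorted(missing)[:5])
    candidates = sorted(gid for gid in counts if gid not in exclusion_list)
    return len(counts), candidates, counts


def compare_motif_counts(
    table: OrthologTable, census_a: dict[str, int], census_b: dict[str, int]
) -> pd.DataFrame:
    """Motif-count conservation across ortholog pairs.

    One row per ortholog pair in which either strain has >=1 motif;
    columns: gene_a, gene_b, n_motifs_a, n_motifs_b, equal.
    """
    rows = []
    for p in table:
        na = census_a.get(p.gene_a, 0)
        nb = census_b.get(p.gene_b, 0)
        if na == 0 and nb == 0:
            continue
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "n_motifs_a": na,
                "n_motifs_b": nb,
                "equal": na == nb,
            }
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_motifs_a", "n_motifs_b", "equal"])


def read_exclusions(path) -> set[str]:
    """Exclusion file: one gene id per line, '#' comments allowed."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
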
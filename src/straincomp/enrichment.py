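"""Gene-set functional enrichment with the EASE score.

The EASE score is a conservative variant of the one-sided Fisher's exact
test in which one gene is removed from the overlap cell of the 2x2 table
before computing the upper-tail probability; a category supported by a
single list gene can therefore never score below 1.  The background
population is the whole gene complement, including unannotated genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

log = logging.getLogger(__name__)

MIN_LIST_SIZE = 100  # smaller test sets are allowed but warned about


@dataclass
class EnrichmentResult:
    category: str
    list_hits: int
    list_size: int
    background_hits: int
    background_size: int
    ease_p: float
    significant: bool


def fisher_score(list_hits: int, list_size: int, background_hits: int, background_size: int) -> float:
    """Plain one-sided (upper tail) Fisher's exact p for the 2x2 table."""
    table = _table(list_hits, list_size, background_hits, background_size)
    return float(stats.fisher_exact(table, alternative="greater")[1])


def ease_score(list_hits: int, list_size: int, background_hits: int, background_size: int) -> float:
    """EASE-penalized one-sided Fisher's exact p.

    The overlap cell is decremented by one (one list gene in the category
    discounted) and the upper-tail probability recomputed; tables with
    ``list_hits`` <= 1 return 1.0 by construction.
    """
    _check(list_hits, list_size, background_hits, background_size)
    if list_hits <= 1:
        return 1.0
    # upper tail of the penalized table: draw list_size-1 genes from the
    # background, at least list_hits-1 of them category members
    return float(
        stats.hypergeom.sf(
            list_hits - 2, background_size, background_hits, list_size - 1
        )
    )


def _check(lh: int, ls: int, bh: int, bs: int) -> None:
    if min(lh, ls, bh, bs) < 0:
        raise ValueError("counts must be non-negative")
    if lh > ls or lh > bh or ls > bs or bh > bs or bh - lh > bs - ls:
        raise ValueError("counts do not form a valid contingency table")


def _table(lh: int, ls: int, bh: int, bs: int):
    # rows: in list / not in list; columns: in category / not in category
    return [[lh, ls - lh], [bh - lh, (bs - ls) - (bh - lh)]]


def enrich(
    gene_set: set[str],
    category_map: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """EASE enrichment of ``gene_set`` against ``background``.

    ``category_map`` maps gene id -> categories (genes may carry several;
    unannotated genes still count in the background totals).  One result
    per category with at least one list hit, sorted by ascending p then
    category id.
    """
    if not background:
        raise ValueError("background gene set is empty")
    stray = gene_set - background
    if stray:
        raise ValueError(f"{len(stray)} gene-set ids missing from background")
    if len(gene_set) < MIN_LIST_SIZE:
        log.warning("test set has only %d genes (< %d); p-values may be unstable", len(gene_set), MIN_LIST_SIZE)
    by_cat: dict[str, set[str]] = {}
    for gene, cats in category_map.items():
        if gene not in background:
            continue
        for c in cats:
            by_cat.setdefault(c, set()).add(gene)
    results = []
    for cat, members in by_cat.items():
        lh = len(gene_set & members)
        if lh == 0:
            continue
        p = ease_score(lh, len(gene_set), len(members), len(background))
        results.append(
            EnrichmentResult(
                category=cat,
                list_hits=lh,
                list_size=len(gene_set),
                background_hits=len(members),
                background_size=len(background),
                ease_p=p,
                significant=p <= alpha,
            )
        )
    results.sort(key=lambda r: (r.ease_p, r.category))
    return results


def read_category_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, category_id); repeated lines allowed."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected two tab-separated columns")
            out.setdefault(parts[0], set()).add(parts[1])
    return out
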
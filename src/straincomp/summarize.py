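"""Class-level summary tables and end-to-end pipeline composition.

Reproduces the two summary-table styles of a strain-pair comparison:
per-strain genome characteristics (size, ORF count, G+C), and per-class
SNP statistics (all genes, or user-supplied gene classes such as central
metabolism or cytochromes) with derived percentage/rate cells rounded
half-up to one decimal.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), as printed summary tables use."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClassSummaryRow:
    """One row of the per-class SNP summary table.

    Derived cells recompute exactly from the count cells under half-up
    rounding to one decimal; a zero denominator renders as None (an empty
    cell in the printed table).
    """

    class_name: str
    total_genes: int
    orthologs: int
    total_snp: int
    ns_snp: int
    genes_with_snp: int
    genes_with_ns_snp: int
    heavy_genes: int
    pct_with_orthologs: float | None = None
    pct_ns_snp: float | None = None
    pct_genes_with_snp: float | None = None
    pct_genes_with_ns_snp: float | None = None
    snp_per_gene: float | None = None
    ns_snp_per_gene: float | None = None
    snp_per_snped_gene: float | None = None
    ns_snp_per_snped_gene: float | None = None
    pct_heavy: float | None = None

    @classmethod
    def from_counts(
        cls,
        class_name: str,
        total_genes: int,
        orthologs: int,
        total_snp: int,
        ns_snp: int,
        genes_with_snp: int,
        genes_with_ns_snp: int,
        heavy_genes: int,
    ) -> "ClassSummaryRow":
        def ratio(num, den, pct=False):
            if den == 0:
                return None
            return round_half_up(100.0 * num / den if pct else num / den)

        return cls(
            class_name=class_name,
            total_genes=total_genes,
            orthologs=orthologs,
            total_snp=total_snp,
            ns_snp=ns_snp,
            genes_with_snp=genes_with_snp,
            genes_with_ns_snp=genes_with_ns_snp,
            heavy_genes=heavy_genes,
            pct_with_orthologs=ratio(orthologs, total_genes, pct=True),
            pct_ns_snp=ratio(ns_snp, total_snp, pct=True),
            pct_genes_with_snp=ratio(genes_with_snp, orthologs, pct=True),
            pct_genes_with_ns_snp=ratio(genes_with_ns_snp, orthologs, pct=True),
            snp_per_gene=ratio(total_snp, orthologs),
            ns_snp_per_gene=ratio(ns_snp, orthologs),
            snp_per_snped_gene=ratio(total_snp, genes_with_snp),
            ns_snp_per_snped_gene=ratio(ns_snp, genes_with_snp),
            pct_heavy=ratio(heavy_genes, orthologs, pct=True),
        )


def class_summary(gene_summaries, class_gene_ids, class_name: str) -> ClassSummaryRow:
    """Aggregate per-gene variant summaries over one gene class.

    ``class_gene_ids`` is an iterable of strain-A gene ids (None = all
    genes); ids absent from the summaries are skipped with a warning.
    """
    by_id = {s.gene_id: s for s in gene_summaries}
    if class_gene_ids is None:
        members = list(by_id.values())
    else:
        members = []
        for gid in class_gene_ids:
            s = by_id.get(gid)
            if s is None:
                log.warning("class %s: gene id %s not found; skipped", class_name, gid)
            else:
                members.append(s)
    orth = [s for s in members if s.category != "no_ortholog"]
    return ClassSummaryRow.from_counts(
        class_name=class_name,
        total_genes=len(members),
        orthologs=len(orth),
        total_snp=sum(s.total_snp for s in orth),
        ns_snp=sum(s.ns_snp for s in orth),
        genes_with_snp=sum(1 for s in orth if s.total_snp > 0),
        genes_with_ns_snp=sum(1 for s in orth if s.ns_snp > 0),
        heavy_genes=sum(1 for s in orth if s.category == "heavily_mutated"),
    )


def genome_table(genome_a, genome_b) -> pd.DataFrame:
    """Per-strain genome characteristics: size, ORF count, G+C% (2 decimals)."""
    rows = {}
    for genome in (genome_a, genome_b):
        seq = genome.sequence
        gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0
        rows[genome.strain_id] = {
            "genome_size_bp": len(seq),
            "open_reading_frames": len(genome.genes),
            "gc_percent": round_half_up(gc, 2),
        }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    pass


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the full comparison: align -> orthologs -> variants -> motifs
    -> regions -> summaries -> (optional) enrichment.

    ``config`` is a dict or a YAML path with either a ``simulate`` stanza
    or ``genome_a``/``genome_b`` (each with fasta/annotation paths), plus
    optional stage parameters.  Returns the report directory, which holds
    every stage's TSV/VCF/XMFA output and a JSON manifest of parameters,
    seeds, and output paths.
    """
    from . import __version__, genome_align, io_formats, motifs, orthology, variants
    from .synthetic_data import DivergenceParams, GenomeSpec, diverge, generate_ancestor, write_outputs

    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(outdir or config.get("outdir", "straincomp_report"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}, "config": _jsonable(config)}

    stage = "load"
    try:
        if "simulate" in config:
            sim = dict(config["simulate"])
            seed = int(sim.pop("seed", 0))
            div = {k: sim.pop(k) for k in list(sim) if k in DivergenceParams.__dataclass_fields__}
            spec = GenomeSpec(**sim)
            ancestor = generate_ancestor(spec, seed)
            genome_a, genome_b, truth = diverge(ancestor, DivergenceParams(seed=seed, **div))
            write_outputs(outdir, genome_a, genome_b, truth)
            manifest["stages"]["simulate"] = {"seed": seed, "genes": len(ancestor.genes)}
        elif "genome_a" in config and "genome_b" in config:
            genome_a = io_formats.read_genome(config["genome_a"]["fasta"], config["genome_a"]["annotation"])
            genome_b = io_formats.read_genome(config["genome_b"]["fasta"], config["genome_b"]["annotation"])
        else:
            raise ConfigError("config needs either a 'simulate' stanza or genome_a/genome_b paths")

        stage = "align"
        if "xmfa" in config:
            blocks = io_formats.read_xmfa(config["xmfa"])
            manifest["stages"]["align"] = {"alignment": "external", "blocks": len(blocks)}
        else:
            params = genome_align.AlignerParams(**config.get("aligner", {}))
            blocks = genome_align.align_genomes(genome_a.sequence, genome_b.sequence, params)
            io_formats.write_xmfa(outdir / "alignment.xmfa", blocks, genome_a.strain_id, genome_b.strain_id)
            manifest["stages"]["align"] = {"alignment": "internal", "blocks": len(blocks)}
        log.info("align: %d blocks", len(blocks))

        stage = "orthologs"
        syn_pairs = orthology.synteny_orthologs(blocks, genome_a, genome_b)
        prot_a = {g.gene_id: g.protein for g in genome_a.genes if not g.pseudo}
        prot_b = {g.gene_id: g.protein for g in genome_b.genes if not g.pseudo}
        rbh_pairs = orthology.rbh_orthologs(prot_a, prot_b)
        thresholds = orthology.ReconcileThresholds(**config.get("reconcile", {}))
        table = orthology.reconcile_orthologs(syn_pairs, rbh_pairs, genome_a, genome_b, thresholds)
        _write_orthologs(outdir, table)
        manifest["stages"]["orthologs"] = {
            "synteny": len(syn_pairs), "rbh": len(rbh_pairs),
            "accepted": len(table), "agree": table.n_agree,
        }
        log.info("orthologs: %d accepted (%d agree)", len(table), table.n_agree)

        stage = "variants"
        called, n_masked = variants.call_variants(blocks, genome_a, genome_b)
        variants.classify_variants(called, genome_a, genome_b)
        io_formats.write_variants_vcf(outdir / "variants.vcf", called, genome_a.strain_id)
        _write_variants_tsv(outdir / "variants.tsv", called)
        vt = variants.OutlierThresholds(**config.get("outliers", {}))
        summaries = variants.summarize_genes(called, table, genome_a, genome_b, vt)
        pd.DataFrame([asdict(s) for s in summaries]).to_csv(outdir / "gene_summary.tsv", sep="\t", index=False)
        coding_rate, noncoding_rate, intragenic = variants.genome_rates(called, genome_a)
        manifest["stages"]["variants"] = {
            "snps": sum(1 for v in called if v.kind == "snp"),
            "indels": sum(1 for v in called if v.kind != "snp"),
            "masked_sites": n_masked,
            "coding_rate_per_kb": coding_rate,
            "noncoding_rate_per_kb": noncoding_rate,
            "intragenic_fraction": intragenic,
        }

        stage = "motifs"
        exclusions = set()
        if "cytochrome_exclusions" in config:
            exclusions = motifs.read_exclusions(config["cytochrome_exclusions"])
        n_a, cand_a, census_a = motifs.cytochrome_census(genome_a, exclusions)
        n_b, cand_b, census_b = motifs.cytochrome_census(genome_b, exclusions)
        conservation = motifs.compare_motif_counts(table, census_a, census_b)
        conservation.to_csv(outdir / "motifs.tsv", sep="\t", index=False)
        manifest["stages"]["motifs"] = {
            "motif_proteins_a": n_a, "motif_proteins_b": n_b,
            "orthologous_motif_pairs": int(len(conservation)),
            "equal_counts": int(conservation["equal"].sum()) if len(conservation) else 0,
        }

        stage = "regions"
        regions_a = orthology.unique_regions(genome_a, table, strain="A")
        regions_b = orthology.unique_regions(genome_b, table, strain="B")
        _write_regions(outdir, regions_a + regions_b)
        manifest["stages"]["regions"] = {"a": len(regions_a), "b": len(regions_b)}

        stage = "summaries"
        rows = [class_summary(summaries, None, "genes")]
        for name, path in config.get("gene_classes", {}).items():
            ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
            rows.append(class_summary(summaries, ids, name))
        pd.DataFrame([asdict(r) for r in rows]).to_csv(outdir / "class_summary.tsv", sep="\t", index=False)
        genome_table(genome_a, genome_b).to_csv(outdir / "genome_table.tsv", sep="\t")

        if "enrichment" in config:
            stage = "enrichment"
            from . import enrichment as enr

            cat_map = enr.read_category_map(config["enrichment"]["category_map"])
            alpha = float(config["enrichment"].get("alpha", 0.05))
            background = set(g.gene_id for g in genome_a.genes)
            gene_set = {
                s.gene_id for s in summaries if s.category in ("mutated", "heavily_mutated")
            }
            results = enr.enrich(gene_set, cat_map, background, alpha)
            pd.DataFrame([asdict(r) for r in results]).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {"categories_tested": len(results)}
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _write_orthologs(outdir: Path, table) -> None:
    pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "methods": "+".join(sorted(p.methods)),
                "identity": round(p.protein_identity, 4),
                "coverage": round(p.coverage_of_longer, 4),
                "identical_protein": p.identical_protein,
                "identical_nucleotide": p.identical_nucleotide,
            }
            for p in table
        ]
    ).to_csv(outdir / "orthologs.tsv", sep="\t", index=False)


def _write_variants_tsv(path: Path, called) -> None:
    pd.DataFrame(
        [
            {
                "pos_a": v.pos_a, "pos_b": v.pos_b, "kind": v.kind,
                "ref": v.ref, "alt": v.alt, "gene_id": v.gene_id or "",
                "effect": v.effect,
            }
            for v in called
        ]
    ).to_csv(path, sep="\t", index=False)


def _write_regions(outdir: Path, regions) -> None:
    pd.DataFrame(
        [
            {
                "strain": r.strain, "start": r.start, "end": r.end,
                "n_genes": len(r.gene_ids), "gene_ids": ",".join(r.gene_ids),
                "border": ",".join(sorted(r.border)) or "none",
            }
            for r in regions
        ]
    ).to_csv(outdir / "regions.tsv", sep="\t", index=False)
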
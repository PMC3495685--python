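"""Reading and writing the standard formats the pipeline touches.

FASTA and GenBank go through Bio.SeqIO, XMFA (Mauve dialect) through
Bio.AlignIO's ``mauve`` codec, and GFF3 through gffutils.  Everything is
normalized into the :mod:`straincomp.model` data model with 1-based
inclusive coordinates.
"""
from __future__ import annotations

import logging
import os
import urllib.parse
from pathlib import Path

import gffutils
from Bio import AlignIO, SeqIO

from .model import AlignmentBlock, AnnotatedGenome, Feature, GeneModel

log = logging.getLogger(__name__)

GFF_VERSION = "3.1.23"
_MOBILE_WORDS = ("transposase", "integrase")


def _is_transposase(product: str) -> bool:
    p = product.lower()
    return any(w in p for w in _MOBILE_WORDS)


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Single-record FASTA -> (record id, uppercase sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def write_fasta(path: str | Path, seq_id: str, sequence: str) -> None:
    """Write a single-record FASTA with 70-column wrapping."""
    lines = [f">{seq_id}"]
    lines += [sequence[i : i + 70] for i in range(0, len(sequence), 70)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_genome(fasta_path: str | Path, annotation_path: str | Path) -> AnnotatedGenome:
    """Load one strain from FASTA plus GFF3 or GenBank annotation.

    Every CDS is translated with translation table 11 (reverse-strand CDSs
    reverse-complemented first).  CDSs whose length is not a multiple of 3,
    or whose translation has an internal stop, are loaded with the pseudo
    flag and excluded from codon-level analyses.
    """
    seq_id, sequence = read_fasta(fasta_path)
    suffix = Path(annotation_path).suffix.lower()
    if suffix in {".gb", ".gbk", ".gbff", ".genbank"}:
        genome = _read_genbank_features(annotation_path, seq_id, sequence)
    else:
        genome = _read_gff3_features(annotation_path, seq_id, sequence)
    _finalize(genome)
    return genome


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Load a self-contained GenBank flat file (sequence + features)."""
    rec = SeqIO.read(str(path), "genbank")
    genome = AnnotatedGenome(strain_id=rec.id, sequence=str(rec.seq).upper())
    _collect_seqrecord_features(rec, genome)
    _finalize(genome)
    return genome


def _read_genbank_features(path: str | Path, seq_id: str, sequence: str) -> AnnotatedGenome:
    rec = SeqIO.read(str(path), "genbank")
    genome = AnnotatedGenome(strain_id=seq_id, sequence=sequence)
    _collect_seqrecord_features(rec, genome)
    return genome


def _collect_seqrecord_features(rec, genome: AnnotatedGenome) -> None:
    n_auto = 0
    for feat in rec.features:
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        if feat.type == "CDS":
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or quals.get("protein_id", [None])[0]
            )
            if gene_id is None:
                n_auto += 1
                gene_id = f"cds{n_auto:05d}"
            product = quals.get("product", [""])[0]
            pseudo = "pseudo" in quals or "pseudogene" in quals
            genome.genes.append(
                GeneModel(
                    gene_id=gene_id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=product,
                    is_transposase=_is_transposase(product),
                    pseudo=pseudo,
                )
            )
        elif feat.type == "tRNA":
            genome.other_features.append(Feature("tRNA", start, end, strand))
        elif feat.type in {"repeat_region", "repeat"}:
            genome.other_features.append(Feature("repeat", start, end, strand))


def _read_gff3_features(path: str | Path, seq_id: str, sequence: str) -> AnnotatedGenome:
    genome = AnnotatedGenome(strain_id=seq_id, sequence=sequence)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype == "CDS":
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            product = urllib.parse.unquote(feat.attributes.get("product", [""])[0])
            pseudo = feat.attributes.get("pseudo", ["false"])[0].lower() == "true"
            genome.genes.append(
                GeneModel(
                    gene_id=gene_id,
                    start=feat.start,
                    end=feat.end,
                    strand="-" if feat.strand == "-" else "+",
                    product=product,
                    is_transposase=_is_transposase(product),
                    pseudo=pseudo,
                )
            )
        elif feat.featuretype == "tRNA":
            genome.other_features.append(
                Feature("tRNA", feat.start, feat.end, "-" if feat.strand == "-" else "+")
            )
        elif feat.featuretype in {"repeat_region", "repeat"}:
            genome.other_features.append(
                Feature("repeat", feat.start, feat.end, "-" if feat.strand == "-" else "+")
            )
    return genome


def _finalize(genome: AnnotatedGenome) -> None:
    """Validate coordinates, translate CDSs, set computed flags."""
    genome.validate()
    trna_spans = [(f.start, f.end) for f in genome.other_features if f.type == "tRNA"]
    for g in genome.genes:
        if g.length % 3 != 0:
            if not g.pseudo:
                log.warning("CDS %s length %d not divisible by 3; flagged pseudo", g.gene_id, g.length)
            g.pseudo = True
            g.protein = ""
        else:
            prot = genome.translate_gene(g)
            if "*" in prot:
                if not g.pseudo:
                    log.warning("CDS %s has internal stop; flagged pseudo", g.gene_id)
                g.pseudo = True
            g.protein = prot if not g.pseudo else ""
        g.is_trna_adjacent = any(
            s <= g.end + 500 and e >= g.start - 500 for s, e in trna_spans
        )


def write_gff3(path: str | Path, genome: AnnotatedGenome) -> None:
    lines = [f"##gff-version {GFF_VERSION}", f"##sequence-region {genome.strain_id} 1 {genome.length}"]
    feats: list[tuple[int, str]] = []
    for g in genome.genes:
        attrs = [f"ID={g.gene_id}"]
        if g.product:
            attrs.append(f"product={urllib.parse.quote(g.product, safe=' ')}")
        if g.pseudo:
            attrs.append("pseudo=true")
        feats.append(
            (
                g.start,
                "\t".join(
                    [genome.strain_id, "straincomp", "CDS", str(g.start), str(g.end), ".", g.strand, "0", ";".join(attrs)]
                ),
            )
        )
    for i, f in enumerate(genome.other_features):
        ftype = "tRNA" if f.type == "tRNA" else "repeat_region"
        feats.append(
            (
                f.start,
                "\t".join(
                    [genome.strain_id, "straincomp", ftype, str(f.start), str(f.end), ".", f.strand, ".", f"ID={f.type}{i + 1:04d}"]
                ),
            )
        )
    feats.sort(key=lambda x: x[0])
    lines += [line for _, line in feats]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XMFA (Mauve dialect)
# ---------------------------------------------------------------------------

def read_xmfa(path: str | Path) -> list[AlignmentBlock]:
    """Parse a two-track Mauve XMFA file into alignment blocks.

    Blocks with a number of tracks other than two are skipped with a
    warning.  Reverse-strand tracks are mapped to the forward-strand
    convention (coordinates stay forward; the gapped text is
    reverse-complemented so both tracks read 5'->3' on the forward strand
    of their own genome).
    """
    from .model import revcomp

    blocks: list[AlignmentBlock] = []
    if os.path.getsize(path) == 0:
        return blocks
    with open(path) as fh:
        for aln in AlignIO.parse(fh, "mauve"):
            if len(aln) != 2:
                log.warning("XMFA block with %d tracks skipped", len(aln))
                continue
            tracks = []
            for rec in aln:
                start0 = int(rec.annotations["start"])  # 0-based
                end = int(rec.annotations["end"])
                strand = rec.annotations.get("strand", 1)
                text = str(rec.seq).upper()
                if strand == -1:
                    text = revcomp(text)
                tracks.append((start0 + 1, end, text))
            (a_s, a_e, a_g), (b_s, b_e, b_g) = tracks
            blocks.append(AlignmentBlock(a_s, a_e, b_s, b_e, a_g, b_g))
    return blocks


def write_xmfa(path: str | Path, blocks: list[AlignmentBlock], name_a: str = "1", name_b: str = "2") -> None:
    """Write alignment blocks as two-track Mauve XMFA (forward strand)."""
    lines = ["#FormatVersion Mauve1", f"#Sequence1File\t{name_a}", f"#Sequence2File\t{name_b}"]
    for blk in blocks:
        lines.append(f"> 1:{blk.a_start}-{blk.a_end} + {name_a}")
        lines += _wrap(blk.a_gapped)
        lines.append(f"> 2:{blk.b_start}-{blk.b_end} + {name_b}")
        lines += _wrap(blk.b_gapped)
        lines.append("=")
    Path(path).write_text("\n".join(lines) + "\n")


def _wrap(text: str, width: int = 80) -> list[str]:
    return [text[i : i + width] for i in range(0, len(text), width)]


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

def write_variants_vcf(path: str | Path, variants, ref_name: str) -> None:
    """Write variants as minimal VCF 4.2, strain A as the reference."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref_name}>",
        '##INFO=<ID=TYPE,Number=1,Type=String,Description="snp/insertion/deletion">',
        '##INFO=<ID=EFF,Number=1,Type=String,Description="synonymous/nonsynonymous/noncoding/indel/not_classified">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="strain-A gene id">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in variants:
        info = f"TYPE={v.kind};EFF={v.effect}"
        if v.gene_id:
            info += f";GENE={v.gene_id}"
        ref, alt = v.ref, v.alt
        if not ref:
            ref, alt = ".", alt  # insertion relative to A, anchored left
        lines.append(f"{ref_name}\t{v.pos_a}\t.\t{ref or '.'}\t{alt or '.'}\t.\t.\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")
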
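"""Readers and writers for annotated genomes, newick trees and matrices.

Genomes arrive either as nucleotide FASTA + GFF3 (CDS features with ID and
product attributes) or as pre-translated multi-protein FASTA with headers
``genome_id|gene_id``.  GFF3 1-based inclusive coordinates are converted to
the package-internal 0-based half-open convention on read and back on write.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
from Bio.Seq import Seq
from skbio import TreeNode

from .records import GeneRecord, Genome

logger = logging.getLogger("phagepan")

TRANSLATION_TABLE = 11


def translate_cds(nt: str, gene_id: str = "?") -> str | None:
    """Translate a CDS with the bacterial code; None (with a warning) when
    the record must be rejected (length not a multiple of 3, internal stop)."""
    if len(nt) % 3 != 0:
        logger.warning("%s: CDS length %d not divisible by 3, rejected", gene_id, len(nt))
        return None
    aa = str(Seq(nt).translate(table=TRANSLATION_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        logger.warning("%s: internal stop codon, rejected", gene_id)
        return None
    if not aa:
        logger.warning("%s: empty translation, rejected", gene_id)
        return None
    return aa


def _read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def read_genome(fasta_path, gff_path, genome_id: str | None = None) -> Genome:
    """Read an annotated genome from nucleotide FASTA + GFF3.

    One GeneRecord per CDS feature, in (contig, start) order; records whose
    CDS cannot be translated cleanly are dropped with a logged warning.  A
    feature on a contig absent from the FASTA is a format error.
    """
    if genome_id is None:
        genome_id = Path(fasta_path).stem
    contigs = _read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    features = sorted(
        db.features_of_type("CDS"), key=lambda f: (f.seqid, f.start, f.end)
    )
    for feat in features:
        if feat.seqid not in contigs:
            raise ValueError(
                f"{gff_path}: feature on unknown contig {feat.seqid!r}"
            )
        gene_id = feat.attributes.get("ID", [f"{genome_id}_{feat.start}"])[0]
        product = feat.attributes.get("product", ["hypothetical protein"])[0]
        start0, end0 = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        nt = contigs[feat.seqid][start0:end0]
        if feat.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        aa = translate_cds(nt, gene_id)
        if aa is None:
            continue
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                gene_id=gene_id,
                contig=feat.seqid,
                start=start0,
                end=end0,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                product=product,
                protein=aa,
            )
        )
    return Genome(genome_id=genome_id, genes=genes, contigs=contigs)


def write_genome(genome: Genome, fasta_path, gff_path) -> None:
    """Write nucleotide FASTA + GFF3 (converting back to 1-based inclusive)."""
    with open(fasta_path, "w") as fh:
        for contig, seq in genome.contigs.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, seq in genome.contigs.items():
            fh.write(f"##sequence-region {contig} 1 {len(seq)}\n")
        for g in genome.genes:
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        "phagepan",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        f"ID={g.gene_id};product={g.product}",
                    ]
                )
                + "\n"
            )


def read_protein_fasta(path) -> list[Genome]:
    """Pre-translated path: headers ``genome_id|gene_id``, one file, many
    genomes.  Coordinates are synthesised (genes laid end to end) since only
    the proteins matter downstream."""
    seqs = _read_fasta(path)
    genomes: dict[str, Genome] = {}
    offsets: dict[str, int] = {}
    for header, aa in seqs.items():
        if "|" not in header:
            raise ValueError(f"{path}: header {header!r} is not genome_id|gene_id")
        genome_id, gene_id = header.split("|", 1)
        genome = genomes.setdefault(genome_id, Genome(genome_id=genome_id))
        off = offsets.get(genome_id, 0)
        nt_len = 3 * (len(aa) + 1)
        genome.genes.append(
            GeneRecord(
                genome_id=genome_id,
                gene_id=gene_id,
                contig=genome_id,
                start=off,
                end=off + nt_len,
                strand="+",
                product="hypothetical protein",
                protein=aa,
            )
        )
        offsets[genome_id] = off + nt_len
    return [genomes[k] for k in sorted(genomes)]


def write_protein_fasta(genomes: list[Genome], path) -> None:
    with open(path, "w") as fh:
        for genome in genomes:
            for g in genome.genes:
                fh.write(f">{genome.genome_id}|{g.gene_id}\n{g.protein}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _newick_str(node: TreeNode) -> str:
    if node.is_tip():
        label = node.name or ""
    else:
        inner = ",".join(_newick_str(c) for c in node.children)
        label = f"({inner}){node.name or ''}"
    if node.length is not None:
        label += f":{node.length:.6g}"
    return label


def write_newick(tree: TreeNode, path) -> None:
    """Serialize with branch lengths to 6 significant digits."""
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate leaf labels")
    with open(path, "w") as fh:
        fh.write(_newick_str(tree) + ";\n")


def read_newick(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate leaf labels")
    return tree
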
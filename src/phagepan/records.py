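"""Core record types shared across the pipeline.

Coordinates are 0-based half-open throughout the package; GFF3 readers and
writers convert from/to the 1-based inclusive convention at the boundary.
Protein sequences are the unit of all downstream comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS with coordinates, strand, product and translation.

    ``start``/``end`` delimit the CDS on ``contig`` as a 0-based half-open
    interval on the forward strand; ``strand`` is ``'+'`` or ``'-'``.
    ``protein`` is the translated sequence with the trailing stop removed.
    """

    genome_id: str
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str
    protein: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """An annotated genome: named contigs plus CDS records in coordinate order.

    ``contigs`` may be empty when the genome was supplied as a pre-translated
    multi-protein FASTA; all pipeline stages only consume :meth:`proteome`.
    """

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    contigs: dict[str, str] = field(default_factory=dict)

    def proteome(self) -> dict[str, str]:
        """Mapping gene_id -> protein sequence."""
        return {g.gene_id: g.protein for g in self.genes}

    def genes_by_product(self, product: str, substring: bool = False) -> list[GeneRecord]:
        """Genes whose product annotation equals (or contains) ``product``.

        Matching is case-insensitive; ``substring=True`` relaxes equality to
        containment, which is how receptor-binding proteins are picked up.
        """
        needle = product.lower()
        if substring:
            return [g for g in self.genes if needle in g.product.lower()]
        return [g for g in self.genes if g.product.lower() == needle]

    def __len__(self) -> int:
        return len(self.genes)
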
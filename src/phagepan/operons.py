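"""eps/rgp operon extraction and host-strain genotype typing.

The polysaccharide operons are located by their flanking marker genes —
epsA and a predicted membrane protein (TMS6) for *eps*, radC and a
bactoprenol glucosyl transferase for *rgp*.  Markers are recognised either
by their product annotation (exact, case-insensitive) or by homology to
user-supplied marker proteins.  Genes strictly between the two markers make
up the cluster; when the markers sit on two contigs (draft assemblies) the
partial gene lists from each marker towards its contig end are combined and
the cluster is flagged incomplete.

Genotype letters come from clustering strains on operon gene content: a
BBH orthology at the relaxed 40% identity / 80% coverage preset (the operon
genes are frequently horizontally transferred, so homologs are more distant
than the genome average), Jaccard + UPGMA, and a cut at a height or into k
clusters.  Letters A, B, ... are assigned in decreasing cluster size.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import pandas as pd

from .align import DEFAULT_SCORING, ScoringParams, global_align
from .cluster import Dendrogram
from .orthology import OPERON_PRESET, OrthologyParams, find_orthologs
from .pangenome import PangenomeMatrix, build_matrix, cluster_genomes
from .records import GeneRecord, Genome
from .simulate import (
    EPS_LEFT_PRODUCT,
    EPS_RIGHT_PRODUCT,
    RGP_LEFT_PRODUCT,
    RGP_RIGHT_PRODUCT,
)

logger = logging.getLogger("phagepan")

#: Jaccard-distance height of the default genotype cut (dendrogram units
#: are half the merge distance, so 0.25 == Jaccard distance 0.5)
DEFAULT_GENOTYPE_CUT_HEIGHT = 0.25


@dataclass(frozen=True)
class MarkerPair:
    name: str  # "eps" or "rgp"
    left_product: str
    right_product: str

    def __post_init__(self) -> None:
        if not self.left_product or not self.right_product:
            raise ValueError("marker products must be non-empty")


EPS_MARKERS = MarkerPair("eps", EPS_LEFT_PRODUCT, EPS_RIGHT_PRODUCT)
RGP_MARKERS = MarkerPair("rgp", RGP_LEFT_PRODUCT, RGP_RIGHT_PRODUCT)


class MarkerNotFoundError(ValueError):
    """A flanking marker gene could not be located in the strain genome."""


class AmbiguousMarkerError(ValueError):
    """A flanking marker matched more than one gene."""


@dataclass
class OperonCluster:
    """The genes of one eps or rgp cluster in one strain (markers excluded)."""

    strain: str
    kind: str
    genes: list[GeneRecord]
    complete: bool
    n_contigs: int

    def proteome(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes}


def _find_marker(
    genome: Genome,
    product: str,
    marker_seq: str | None,
    min_identity: float,
    params: ScoringParams,
) -> GeneRecord:
    if marker_seq is None:
        matches = genome.genes_by_product(product)
    else:
        matches = [
            g
            for g in genome.genes
            if global_align(g.protein, marker_seq, params).identity >= min_identity
        ]
    if not matches:
        raise MarkerNotFoundError(
            f"{genome.genome_id}: marker {product!r} not found"
        )
    if len(matches) > 1:
        raise AmbiguousMarkerError(
            f"{genome.genome_id}: marker {product!r} matched "
            f"{[g.gene_id for g in matches]}"
        )
    return matches[0]


def locate_cluster(
    genome: Genome,
    markers: MarkerPair,
    marker_seqs: dict[str, str] | None = None,
    min_marker_identity: float = 0.5,
    params: ScoringParams = DEFAULT_SCORING,
) -> OperonCluster:
    """Extract the genes between the two flanking markers.

    ``marker_seqs`` (mapping product -> protein) switches to the homology
    path: a gene is a marker when its global identity to the supplied
    protein is >= ``min_marker_identity``.  With both markers on one contig
    the genes strictly between them (either orientation) are returned and
    the cluster is complete; with markers on two contigs, each marker
    contributes the genes from itself to its contig end in its reading
    direction (downstream of the left marker, upstream of the right one)
    and the cluster is flagged incomplete.
    """
    seqs = marker_seqs or {}
    left = _find_marker(
        genome, markers.left_product, seqs.get(markers.left_product),
        min_marker_identity, params,
    )
    right = _find_marker(
        genome, markers.right_product, seqs.get(markers.right_product),
        min_marker_identity, params,
    )
    if left.contig == right.contig:
        contig_genes = [g for g in genome.genes if g.contig == left.contig]
        contig_genes.sort(key=lambda g: g.start)
        lo, hi = sorted((left.start, right.start))
        between = [
            g
            for g in contig_genes
            if lo < g.start < hi and g.gene_id not in (left.gene_id, right.gene_id)
        ]
        return OperonCluster(
            strain=genome.genome_id,
            kind=markers.name,
            genes=between,
            complete=True,
            n_contigs=1,
        )
    logger.warning(
        "%s: %s markers on two contigs; typing on partial gene content",
        genome.genome_id,
        markers.name,
    )

    def towards_end(marker: GeneRecord) -> list[GeneRecord]:
        contig_genes = sorted(
            (g for g in genome.genes if g.contig == marker.contig),
            key=lambda g: g.start,
        )
        if marker.strand == "+":
            downstream = [g for g in contig_genes if g.start > marker.start]
        else:
            downstream = [g for g in contig_genes if g.start < marker.start]
        return downstream

    def towards_start(marker: GeneRecord) -> list[GeneRecord]:
        contig_genes = sorted(
            (g for g in genome.genes if g.contig == marker.contig),
            key=lambda g: g.start,
        )
        if marker.strand == "+":
            return [g for g in contig_genes if g.start < marker.start]
        return [g for g in contig_genes if g.start > marker.start]

    partial = towards_end(left) + towards_start(right)
    seen: set[str] = set()
    genes = []
    for g in partial:
        if g.gene_id not in seen and g.gene_id not in (left.gene_id, right.gene_id):
            seen.add(g.gene_id)
            genes.append(g)
    return OperonCluster(
        strain=genome.genome_id,
        kind=markers.name,
        genes=genes,
        complete=False,
        n_contigs=2,
    )


def operon_matrix(
    clusters: list[OperonCluster],
    params: OrthologyParams = OPERON_PRESET,
) -> PangenomeMatrix:
    """Strain x operon-gene-family presence/absence matrix (one kind)."""
    kinds = {c.kind for c in clusters}
    if len(kinds) > 1:
        raise ValueError(f"mixed cluster kinds: {sorted(kinds)}")
    if len(clusters) < 2:
        raise ValueError("need clusters from at least two strains")
    proteomes = {c.strain: c.proteome() for c in clusters}
    if len(proteomes) != len(clusters):
        raise ValueError("duplicate strain in cluster list")
    _hits, groups = find_orthologs(proteomes, params)
    return build_matrix(groups, {s: set(p) for s, p in proteomes.items()})


def assign_genotypes(
    matrix: PangenomeMatrix,
    k: int | None = None,
    height: float | None = None,
) -> tuple[dict[str, str], Dendrogram]:
    """Genotype letters from Jaccard+UPGMA clustering of operon content.

    Cut either into ``k`` clusters or at a dendrogram ``height`` (default:
    height 0.25, i.e. Jaccard distance 0.5).  Letters A, B, ... are assigned
    in decreasing cluster size, ties by smallest strain id.
    """
    if k is not None and height is not None:
        raise ValueError("give only one of k= or height=")
    if k is not None and k > len(matrix.genomes):
        raise ValueError("k exceeds the number of strains")
    if k is None and height is None:
        height = DEFAULT_GENOTYPE_CUT_HEIGHT
    dendro = cluster_genomes(matrix)
    flat = dendro.cut(k=k, height=height)
    clusters: dict[int, list[str]] = {}
    for strain, idx in flat.items():
        clusters.setdefault(idx, []).append(strain)
    ordered = sorted(clusters.values(), key=lambda m: (-len(m), min(m)))
    letters = string.ascii_uppercase
    if len(ordered) > len(letters):
        raise ValueError("more genotype clusters than letters")
    out: dict[str, str] = {}
    for rank, members in enumerate(ordered):
        for strain in members:
            out[strain] = letters[rank]
    return out, dendro


@dataclass
class GenotypeAssignment:
    """Per-strain EPS and RGP letters plus completeness flags and failures."""

    table: pd.DataFrame
    eps_dendrogram: Dendrogram | None = None
    rgp_dendrogram: Dendrogram | None = None
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    def letter(self, strain: str, kind: str) -> str:
        return str(self.table.loc[strain, f"{kind}_genotype"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "strain"
        out.to_csv(path, sep="\t")


def type_host_strains(
    strains: list[Genome],
    eps_k: int | None = None,
    rgp_k: int | None = None,
    height: float | None = None,
    ortho_params: OrthologyParams = OPERON_PRESET,
    marker_seqs: dict[str, str] | None = None,
) -> GenotypeAssignment:
    """Full typing pipeline: locate both operons in every strain, build the
    two content matrices, and assign EPS and RGP genotype letters.

    Strains in which a marker search fails are recorded under ``failures``
    and excluded from the corresponding matrix (non-fatal).
    """
    located: dict[str, dict[str, OperonCluster]] = {}
    failures: list[tuple[str, str, str]] = []
    for strain in strains:
        for markers in (EPS_MARKERS, RGP_MARKERS):
            try:
                cluster = locate_cluster(strain, markers, marker_seqs=marker_seqs)
            except MarkerNotFoundError as exc:
                failures.append((strain.genome_id, markers.name, str(exc)))
                continue
            located.setdefault(strain.genome_id, {})[markers.name] = cluster

    letters: dict[str, dict[str, str]] = {"eps": {}, "rgp": {}}
    complete: dict[str, dict[str, bool]] = {"eps": {}, "rgp": {}}
    dendros: dict[str, Dendrogram | None] = {"eps": None, "rgp": None}
    for kind, k in (("eps", eps_k), ("rgp", rgp_k)):
        clusters = [
            parts[kind] for parts in located.values() if kind in parts
        ]
        if len(clusters) >= 2:
            matrix = operon_matrix(clusters, ortho_params)
            letters[kind], dendros[kind] = assign_genotypes(matrix, k=k, height=height)
            complete[kind] = {c.strain: c.complete for c in clusters}

    strain_ids = sorted(g.genome_id for g in strains)
    table = pd.DataFrame(
        {
            "eps_genotype": [letters["eps"].get(s, "") for s in strain_ids],
            "rgp_genotype": [letters["rgp"].get(s, "") for s in strain_ids],
            "eps_complete": [complete["eps"].get(s, False) for s in strain_ids],
            "rgp_complete": [complete["rgp"].get(s, False) for s in strain_ids],
        },
        index=strain_ids,
    )
    return GenotypeAssignment(
        table=table,
        eps_dendrogram=dendros["eps"],
        rgp_dendrogram=dendros["rgp"],
        failures=failures,
    )
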
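"""Genome x ortholog-group presence/absence analysis.

The pangenome matrix is the boolean genome-by-gene-family table built from
ortholog groups; phage groups are obtained by UPGMA on Jaccard distances
between its rows (the gene-content clustering of the study), and core /
unique / near-core statistics are read off its columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import Dendrogram, cut_dendrogram, upgma  # noqa: F401  (re-export)
from .orthology import OrthologGroup
from .records import Genome


@dataclass
class PangenomeMatrix:
    """Boolean presence/absence matrix, genomes as rows, groups as columns."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.empty:
            raise ValueError("empty pangenome matrix")
        if self.df.index.duplicated().any():
            raise ValueError("duplicated genome id")
        if self.df.columns.duplicated().any():
            raise ValueError("duplicated group id")
        self.df = self.df.astype(bool).sort_index(axis=1)
        zero_rows = self.df.index[~self.df.any(axis=1)].tolist()
        if zero_rows:
            raise ValueError(f"genomes with no gene group at all: {zero_rows}")

    @property
    def genomes(self) -> list[str]:
        return list(self.df.index)

    @property
    def groups(self) -> list[str]:
        return list(self.df.columns)

    def to_tsv(self, path) -> None:
        out = self.df.astype(int)
        out.index.name = "genome"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PangenomeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"non-binary cell in {path}")
        return cls(df.astype(bool))


def build_matrix(
    groups: list[OrthologGroup],
    genomes: list[Genome] | dict[str, set[str] | list[str]],
) -> PangenomeMatrix:
    """cell(g, G) = 1 iff genome g carries at least one member of group G.

    ``genomes`` is either a list of :class:`Genome` objects or a mapping
    genome id -> gene ids.  A group member that belongs to no genome is an
    error.
    """
    if isinstance(genomes, list):
        gene_sets = {g.genome_id: set(g.proteome()) for g in genomes}
    else:
        gene_sets = {gid: set(genes) for gid, genes in genomes.items()}
    gene_to_genome: dict[str, str] = {}
    for genome_id, genes in gene_sets.items():
        for gene in genes:
            gene_to_genome[gene] = genome_id
    genome_ids = sorted(gene_sets)
    data = pd.DataFrame(
        False, index=genome_ids, columns=sorted(g.group_id for g in groups)
    )
    for group in groups:
        for member in group.members:
            genome = gene_to_genome.get(member)
            if genome is None:
                raise ValueError(f"group member {member!r} belongs to no genome")
            data.loc[genome, group.group_id] = True
    return PangenomeMatrix(data)


def jaccard_distances(matrix: PangenomeMatrix) -> tuple[list[str], np.ndarray]:
    """Pairwise Jaccard distances 1 - |intersection| / |union| between rows."""
    rows = matrix.df.to_numpy(dtype=bool)
    n = rows.shape[0]
    if n < 2:
        raise ValueError("need at least two genomes")
    inter = (rows[:, None, :] & rows[None, :, :]).sum(axis=2)
    union = (rows[:, None, :] | rows[None, :, :]).sum(axis=2)
    if (union == 0).any():
        raise ValueError("Jaccard distance undefined for two empty rows")
    dist = 1.0 - inter / union
    np.fill_diagonal(dist, 0.0)
    return matrix.genomes, dist


def cluster_genomes(matrix: PangenomeMatrix) -> Dendrogram:
    """UPGMA dendrogram over Jaccard distances between genome rows."""
    labels, dist = jaccard_distances(matrix)
    return upgma(dist, labels)


@dataclass
class PangenomeStats:
    """Pangenome size and core/unique/near-core breakdown.

    ``core_by_group`` lists, per flat cluster, the gene families present in
    every genome of that cluster.  ``near_core`` lists families missing from
    at most ``max_missing`` genomes of the whole collection (but not from
    zero, i.e. the global core is excluded).
    """

    n_pangenome_groups: int
    n_unique: int
    unique_fraction: float
    core_by_group: dict[object, list[str]]
    near_core: list[tuple[str, int]]


def pangenome_stats(
    matrix: PangenomeMatrix,
    cluster_labels: dict[str, object],
    max_missing: int = 1,
) -> PangenomeStats:
    """Core, unique and near-core gene families of a clustered pangenome."""
    missing_labels = set(matrix.genomes) - set(cluster_labels)
    if missing_labels:
        raise ValueError(f"no cluster label for genomes {sorted(missing_labels)}")
    df = matrix.df
    col_sums = df.sum(axis=0)
    n_groups = df.shape[1]
    n_unique = int((col_sums == 1).sum())
    core_by_group: dict[object, list[str]] = {}
    for label in sorted(set(cluster_labels.values()), key=str):
        members = [g for g in matrix.genomes if cluster_labels[g] == label]
        sub = df.loc[members]
        core_by_group[label] = list(sub.columns[sub.all(axis=0)])
    n_missing = df.shape[0] - col_sums
    near = [
        (col, int(n_missing[col]))
        for col in df.columns
        if 0 < n_missing[col] <= max_missing
    ]
    return PangenomeStats(
        n_pangenome_groups=n_groups,
        n_unique=n_unique,
        unique_fraction=n_unique / n_groups,
        core_by_group=core_by_group,
        near_core=near,
    )
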
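"""Distance-based phylogenies: neighbor joining, bootstrap, RBP lineages.

Trees are built by neighbor joining (Saitou-Nei) on Poisson-corrected
p-distances from protein alignments.  NJ is exactly consistent on additive
distance matrices, which is the property the test suite leans on; branch
support comes from column-resampling bootstrap.  Receptor-binding proteins
(RBPs) are collected by annotation, screened by the <30% pairwise identity
exclusion rule, and assigned to lineages by single-linkage clustering of
patristic distances at a stated threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .align import (
    DEFAULT_SCORING,
    MultipleAlignment,
    ScoringParams,
    distance_matrix,
    global_align,
    pdistance,
    poisson_distance,
    progressive_msa,
)
from .records import Genome

RBP_PRODUCT = "receptor binding protein"


def to_roman(n: int) -> str:
    """1 -> I, 2 -> II, ... (cluster labels)."""
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


# ---------------------------------------------------------------------------
# Core-genome concatenation
# ---------------------------------------------------------------------------


def concatenate_core(
    alignments: dict[str, MultipleAlignment], genomes: list[str]
) -> MultipleAlignment:
    """Concatenate per-core-gene alignments into one row per genome.

    Blocks are joined in lexicographic order of the core-group key; every
    alignment must contain every genome (anything else contradicts coreness).
    """
    if not alignments:
        raise ValueError("no alignments given")
    rows = {g: [] for g in genomes}
    for key in sorted(alignments):
        msa = alignments[key]
        for genome in genomes:
            if genome not in msa.rows:
                raise ValueError(f"genome {genome!r} missing from core alignment {key!r}")
            rows[genome].append(msa.rows[genome])
    return MultipleAlignment({g: "".join(parts) for g, parts in rows.items()})


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(labels: list[str], dist: np.ndarray) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Standard Q-matrix selection with ties broken by the smallest (i, j) pair,
    standard branch-length formulas, negative branch lengths clamped to zero
    with the deficit moved to the sister edge.  Returns an unrooted tree
    represented with a trifurcating root.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")

    nodes: list[TreeNode] = [TreeNode(name=label) for label in labels]
    D = dist.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = (np.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] < best[0] - 1e-12:
                    best = (Q[i, j], i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0.0:
            lj += li
            li = 0.0
        elif lj < 0.0:
            li += lj
            lj = 0.0
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_row[keep]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]

    # terminal 3-taxon star: closed-form branch lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, length in zip(nodes, lengths):
        node.length = max(length, 0.0)
    return TreeNode(children=nodes)


def nj_tree(
    msa: MultipleAlignment, correction: str = "poisson"
) -> TreeNode:
    """NJ tree from the Poisson-corrected p-distances of an alignment."""
    labels, dist = distance_matrix(msa, correction=correction)
    return neighbor_joining(labels, dist)


def patristic_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length distances."""
    dm = tree.tip_tip_distances()
    order = sorted(dm.ids)
    dm = dm.filter(order)
    return list(order), dm.data.copy()


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each normalised to the side that does not
    contain the lexicographically smallest tip."""
    tips = sorted(t.name for t in tree.tips())
    anchor = tips[0]
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        if anchor in side:
            side = frozenset(tips) - side
        out.add(side)
    return out


def bootstrap_support(
    msa: MultipleAlignment,
    n_reps: int = 100,
    seed: int = 0,
    correction: str = "poisson",
) -> TreeNode:
    """NJ tree with column-resampling bootstrap supports.

    ``n_reps`` replicates resample alignment columns with replacement;
    support of an internal edge is the percentage of replicates whose NJ
    tree contains the same bipartition.  Supports are stored both as
    ``node.support`` (float) and as internal node names (integer string),
    which is how they survive newick round-trips.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if msa.length < 2:
        raise ValueError("cannot bootstrap an alignment of < 2 columns")
    labels = sorted(msa.rows)
    tree = nj_tree(msa, correction=correction)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in _bipartitions(tree)}
    rows = np.array([list(msa.rows[label]) for label in labels])
    for _ in range(n_reps):
        cols = rng.integers(0, msa.length, size=msa.length)
        rep_rows = {
            label: "".join(rows[k][cols]) for k, label in enumerate(labels)
        }
        rep_tree = nj_tree(MultipleAlignment(rep_rows), correction=correction)
        for bp in _bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    anchor = labels[0]
    all_tips = frozenset(labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(labels) - 2:
            continue
        if anchor in side:
            side = all_tips - side
        pct = 100.0 * counts[side] / n_reps
        node.support = pct
        node.name = str(int(round(pct)))
    return tree


# ---------------------------------------------------------------------------
# RBP selection and lineage assignment
# ---------------------------------------------------------------------------


@dataclass
class RbpSet:
    """RBPs admitted to the phylogeny, plus exclusions with reasons."""

    included: dict[str, str]
    excluded: list[tuple[str, str]] = field(default_factory=list)


def select_rbps(
    genomes: list[Genome],
    min_similarity: float = 0.30,
    product: str = RBP_PRODUCT,
    params: ScoringParams = DEFAULT_SCORING,
) -> RbpSet:
    """Collect one RBP per genome and apply the low-similarity exclusion.

    The RBP is the first gene (coordinate order) whose product annotation
    contains ``product``.  A sequence is excluded when its best pairwise
    global-alignment identity against every other collected RBP falls below
    ``min_similarity`` (the boundary itself is included); genomes without an
    RBP annotation are recorded as excluded with reason "not found".  With
    fewer than two sequences collected no comparison is possible and all are
    kept.
    """
    found: dict[str, str] = {}
    excluded: list[tuple[str, str]] = []
    for genome in genomes:
        matches = genome.genes_by_product(product, substring=True)
        if not matches:
            excluded.append((genome.genome_id, "not found"))
        else:
            found[genome.genome_id] = matches[0].protein
    ids = sorted(found)
    if len(ids) < 2:
        return RbpSet(included=dict(found), excluded=excluded)
    n = len(ids)
    ident = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(found[ids[i]], found[ids[j]], params)
            ident[i, j] = ident[j, i] = res.identity
    included: dict[str, str] = {}
    for i, phage in enumerate(ids):
        best = float(ident[i].max())
        if best >= min_similarity:
            included[phage] = found[phage]
        else:
            excluded.append((phage, f"max identity {best:.3f} < {min_similarity:.2f}"))
    return RbpSet(included=included, excluded=excluded)


def tree_clusters(tree: TreeNode, threshold: float = 0.30) -> dict[str, str]:
    """Single-linkage leaf clusters on patristic distances.

    Two leaves share a cluster iff they are connected by a chain of leaves
    with consecutive patristic distances <= threshold.  Cluster labels are
    roman numerals I, II, ... ordered by each cluster's smallest leaf label.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels, dist = patristic_distances(tree)
    n = len(labels)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[str]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(labels[i])
    ordered = sorted(clusters.values(), key=min)
    out: dict[str, str] = {}
    for rank, members in enumerate(ordered, start=1):
        for leaf in members:
            out[leaf] = to_roman(rank)
    return out


def rbp_lineages(
    genomes: list[Genome],
    min_similarity: float = 0.30,
    threshold: float = 0.30,
    product: str = RBP_PRODUCT,
    params: ScoringParams = DEFAULT_SCORING,
) -> tuple[dict[str, str], TreeNode, RbpSet]:
    """Full RBP pipeline: select, align, build the NJ tree, cut lineages.

    Returns (phage -> lineage label, tree, RbpSet).
    """
    rbps = select_rbps(genomes, min_similarity=min_similarity, product=product, params=params)
    if len(rbps.included) < 3:
        raise ValueError("need at least 3 admitted RBPs for a phylogeny")
    msa = progressive_msa(rbps.included, params)
    tree = nj_tree(msa)
    return tree_clusters(tree, threshold=threshold), tree, rbps
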
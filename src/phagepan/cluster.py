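"""Agglomerative clustering: UPGMA dendrograms and dendrogram cutting.

UPGMA (average linkage) is the clustering behind both the phage pangenome
grouping and the eps/rgp genotype assignment.  The dendrogram records node
heights in ultrametric units: a merge of two clusters whose average pairwise
distance is d happens at height d/2, so the cophenetic distance between two
leaves is twice the height of their lowest common ancestor and reproduces the
input exactly for ultrametric matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Dendrogram:
    """Result of an agglomerative clustering of ``len(labels)`` leaves.

    Leaves are clusters ``0..n-1`` in ``labels`` order; the t-th entry of
    ``merges`` creates cluster ``n+t`` from two existing cluster ids at the
    recorded height.  Heights are non-decreasing.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate leaf labels")
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("a dendrogram over n leaves needs n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    # -- derived views ----------------------------------------------------

    def members(self) -> dict[int, set[int]]:
        """Leaf-index membership of every cluster id (leaves and internal)."""
        n = len(self.labels)
        out: dict[int, set[int]] = {i: {i} for i in range(n)}
        for t, (a, b, _h) in enumerate(self.merges):
            out[n + t] = out[a] | out[b]
        return out

    def cophenetic(self) -> np.ndarray:
        """Matrix of cophenetic distances (2 x height of the joining merge)."""
        n = len(self.labels)
        mem = {i: {i} for i in range(n)}
        out = np.zeros((n, n))
        for t, (a, b, h) in enumerate(self.merges):
            for i in mem[a]:
                for j in mem[b]:
                    out[i, j] = out[j, i] = 2.0 * h
            mem[n + t] = mem.pop(a) | mem.pop(b)
        return out

    def cut(self, k: int | None = None, height: float | None = None) -> dict[str, int]:
        """Cut into flat clusters, by count ``k`` or by maximum merge height.

        Exactly one of ``k``/``height`` must be given.  Returns a mapping
        label -> cluster index, with clusters numbered 0.. in order of their
        lexicographically smallest leaf label.
        """
        n = len(self.labels)
        if (k is None) == (height is None):
            raise ValueError("give exactly one of k= or height=")
        if k is not None:
            if not 1 <= k <= n:
                raise ValueError(f"k must be in [1, {n}]")
            applied = self.merges[: n - k]
        else:
            applied = [m for m in self.merges if m[2] <= height + 1e-12]
        mem: dict[int, set[int]] = {i: {i} for i in range(n)}
        for t, (a, b, _h) in enumerate(applied):
            mem[n + t] = mem.pop(a) | mem.pop(b)
        clusters = sorted(mem.values(), key=lambda s: min(self.labels[i] for i in s))
        out: dict[str, int] = {}
        for idx, leaf_set in enumerate(clusters):
            for leaf in leaf_set:
                out[self.labels[leaf]] = idx
        return out

    def to_tree(self):
        """Ultrametric tree as an ``skbio.TreeNode`` with branch lengths."""
        from skbio import TreeNode

        n = len(self.labels)
        nodes: dict[int, tuple[object, float]] = {
            i: (TreeNode(name=self.labels[i]), 0.0) for i in range(n)
        }
        root = nodes[0][0] if n == 1 else None
        for t, (a, b, h) in enumerate(self.merges):
            ca, ha = nodes.pop(a)
            cb, hb = nodes.pop(b)
            ca.length = h - ha
            cb.length = h - hb
            parent = TreeNode(children=[ca, cb])
            nodes[n + t] = (parent, h)
            root = parent
        return root


def upgma(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Merge height is half the average inter-cluster distance; ties are broken
    by the smallest (i, j) cluster-id pair.  NaN entries, asymmetry or a
    non-zero diagonal are rejected.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if np.isnan(dist).any():
        raise ValueError("NaN distance")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if (dist < -1e-12).any():
        raise ValueError("negative distances")

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = dist[i, j]
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        (i, j), dij = min(D.items(), key=lambda kv: (kv[1], kv[0]))
        si, sj = active.pop(i), active.pop(j)
        for k in list(active):
            a, b = (i, k) if i < k else (k, i)
            c, d = (j, k) if j < k else (k, j)
            dk = (si * D.pop((a, b)) + sj * D.pop((c, d))) / (si + sj)
            D[(k, next_id)] = dk
        del D[(i, j)]
        merges.append((i, j, dij / 2.0))
        active[next_id] = si + sj
        next_id += 1
    return Dendrogram(labels=list(labels), merges=merges)


def cut_dendrogram(
    dendrogram: Dendrogram, k: int | None = None, height: float | None = None
) -> dict[str, int]:
    """Functional alias for :meth:`Dendrogram.cut`."""
    return dendrogram.cut(k=k, height=height)
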
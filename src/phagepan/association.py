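"""Exact sampling-without-replacement statistics for RBP-lineage vs
receptor-genotype associations, and shared-host concordance counting.

All probabilities are computed with exact integer binomial coefficients and
converted to float only at the end: the hypergeometric probability that a
draw of n phages (those in the selected RBP clusters) from a population of N
contains k phages whose host strains carry the designated genotype letters,
given K such phages in the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb


def _check_ranges(N: int, K: int, n: int) -> None:
    if N < 0 or not 0 <= K <= N or not 0 <= n <= N:
        raise ValueError(f"invalid hypergeometric arguments N={N}, K={K}, n={n}")


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """P(exactly k successes in a size-n draw) = C(K,k) C(N-K,n-k) / C(N,n)."""
    _check_ranges(N, K, n)
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if k > K or n - k > N - K:
        return 0.0
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def prob_all_successes(N: int, K: int, n: int) -> float:
    """P(every drawn item is a success) = C(K,n) / C(N,n); 0 when n > K."""
    _check_ranges(N, K, n)
    if n > K:
        return 0.0
    return comb(K, n) / comb(N, n)


def prob_at_least(N: int, K: int, n: int, k_min: int) -> float:
    """Upper-tail P(at least k_min successes), exact integer arithmetic."""
    _check_ranges(N, K, n)
    if not 0 <= k_min <= n:
        raise ValueError(f"k_min={k_min} outside [0, n={n}]")
    total = comb(N, n)
    acc = 0
    for k in range(k_min, min(n, K) + 1):
        if n - k <= N - K:
            acc += comb(K, k) * comb(N - K, n - k)
    return acc / total


@dataclass(frozen=True)
class AssociationTest:
    """Counts and exact probability of one RBP-cluster vs genotype contrast.

    N phages in the analysis set; K of them have hosts carrying only the
    designated genotype letters; n phages fall in the designated RBP
    clusters, k_obs of which are successes.  ``rule`` records which tail was
    used ("all" when every drawn phage was a success, otherwise "at_least"
    or "point").
    """

    N: int
    K: int
    n: int
    k_obs: int
    p: float
    rule: str
    clusters: frozenset[str]
    genotypes: frozenset[str]
    genotype_kind: str

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError("invalid counts")
        if not 0 <= self.k_obs <= min(self.n, self.K):
            raise ValueError("k_obs outside [0, min(n, K)]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("probability outside [0, 1]")


@dataclass
class AssociationInput:
    """Phage cluster labels, phage host ranges, and strain genotype letters."""

    phage_clusters: dict[str, str]
    phage_hosts: dict[str, set[str]]
    strain_genotypes: dict[str, str]


def build_association(
    data: AssociationInput,
    clusters: set[str],
    genotypes: set[str],
    genotype_kind: str = "eps",
    tail: str = "upper",
) -> AssociationTest:
    """Contingency counts and exact probability for a cluster/genotype pair.

    A phage is a success iff *every* listed host strain carries a genotype in
    ``genotypes``.  When all drawn phages are successes the all-successes
    probability C(K,n)/C(N,n) is reported; otherwise the upper tail
    P(X >= k_obs) (``tail="upper"``, default) or the point probability
    (``tail="point"``).
    """
    if tail not in ("upper", "point"):
        raise ValueError("tail must be 'upper' or 'point'")
    phages = sorted(data.phage_clusters)
    missing = [
        (ph, st)
        for ph in phages
        for st in data.phage_hosts.get(ph, set())
        if st not in data.strain_genotypes
    ]
    if missing:
        raise ValueError(f"host strains without a genotype letter: {missing}")
    for ph in phages:
        if not data.phage_hosts.get(ph):
            raise ValueError(f"phage {ph!r} has no host strains")

    def success(ph: str) -> bool:
        return all(
            data.strain_genotypes[st] in genotypes for st in data.phage_hosts[ph]
        )

    N = len(phages)
    K = sum(success(ph) for ph in phages)
    drawn = [ph for ph in phages if data.phage_clusters[ph] in clusters]
    n = len(drawn)
    k_obs = sum(success(ph) for ph in drawn)
    if n == 0:
        p, rule = 1.0, "all"
    elif k_obs == n:
        p, rule = prob_all_successes(N, K, n), "all"
    elif tail == "upper":
        p, rule = prob_at_least(N, K, n, k_obs), "at_least"
    else:
        p, rule = hypergeom_pmf(N, K, n, k_obs), "point"
    return AssociationTest(
        N=N,
        K=K,
        n=n,
        k_obs=k_obs,
        p=p,
        rule=rule,
        clusters=frozenset(clusters),
        genotypes=frozenset(genotypes),
        genotype_kind=genotype_kind,
    )


def shared_host_concordance(
    cluster_labels: dict[str, str],
    host_range: dict[str, set[str]],
    mode: str = "identical-set",
) -> tuple[int, int, list[tuple[frozenset[str], bool]]]:
    """Count shared-host cases and how many are phylogenetically concordant.

    A case is a maximal set of >= 2 phages with an identical host-strain set
    (default) or, with ``mode="overlap"``, a connected component of phages
    sharing at least one strain.  A case is concordant iff all its phages
    carry the same cluster label.  Returns (n_cases, n_concordant, cases).
    """
    unlabelled = set(host_range) - set(cluster_labels)
    if unlabelled:
        raise ValueError(f"phages without cluster labels: {sorted(unlabelled)}")
    if mode == "identical-set":
        by_hosts: dict[frozenset[str], list[str]] = {}
        for phage, hosts in host_range.items():
            by_hosts.setdefault(frozenset(hosts), []).append(phage)
        groups = [v for v in by_hosts.values() if len(v) >= 2]
    elif mode == "overlap":
        import networkx as nx

        graph = nx.Graph()
        graph.add_nodes_from(host_range)
        phage_list = sorted(host_range)
        for i, a in enumerate(phage_list):
            for b in phage_list[i + 1 :]:
                if host_range[a] & host_range[b]:
                    graph.add_edge(a, b)
        groups = [sorted(c) for c in nx.connected_components(graph) if len(c) >= 2]
    else:
        raise ValueError("mode must be 'identical-set' or 'overlap'")
    cases = []
    for members in sorted(groups, key=min):
        concordant = len({cluster_labels[p] for p in members}) == 1
        cases.append((frozenset(members), concordant))
    n_concordant = sum(c for _, c in cases)
    return len(cases), n_concordant, cases
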
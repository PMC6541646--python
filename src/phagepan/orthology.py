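"""Bidirectional-best-hit (BBH) orthology.

All proteins of every genome are compared all-vs-all (excluding self-genome
comparisons); alignments passing identity and coverage thresholds are hits,
the best-scoring hit per (query gene, subject genome) is marked, and genes
that are each other's best hits are joined by an edge.  Ortholog groups are
the connected components of that graph; genes without any edge form
singleton groups ("unique genes").

Two threshold presets mirror the two stages of the analysis: 50% identity /
50% coverage for phage pangenomes, and 40% identity / 80% coverage for the
horizontally transferred eps/rgp operon genes.  The strict "similarity 1.0"
setting is interpreted as: only reciprocal best hits form edges, with no
expansion to near-best hits.

For speed, the quadratic pair space is screened before full alignment:
candidate pairs must share ``max(min_shared_kmers, kmer_frac * min length)``
distinct 4-mers — unrelated random proteins essentially never do, while any
pair above the 40%-identity preset shares many more.  An optional score
floor additionally skips the traceback for pairs below a raw alignment
score.  Both screens can be disabled (``min_shared_kmers=None``,
``score_floor=None``).
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .align import DEFAULT_SCORING, ScoringParams, _aligner, _stats_from_counts


@dataclass(frozen=True)
class OrthologyParams:
    """Thresholds of the BBH search.

    ``coverage_mode`` decides whether the coverage threshold must hold for
    both sequences (default) or for at least one.
    """

    min_identity: float = 0.50
    min_coverage: float = 0.50
    similarity: float = 1.0
    coverage_mode: str = "both"
    kmer_size: int = 4
    min_shared_kmers: int | None = 3
    kmer_frac: float = 0.02
    score_floor: float | None = None
    scoring: ScoringParams = DEFAULT_SCORING

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0.0 < self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.coverage_mode not in ("both", "one"):
            raise ValueError("coverage_mode must be 'both' or 'one'")


PANGENOME_PRESET = OrthologyParams(min_identity=0.50, min_coverage=0.50)
OPERON_PRESET = OrthologyParams(min_identity=0.40, min_coverage=0.80)
#: no thresholds at all -- debugging / inspection only
PERMISSIVE_PRESET = OrthologyParams(
    min_identity=1e-9, min_coverage=1e-9, min_shared_kmers=None, score_floor=None
)

HIT_COLUMNS = ["query", "subject", "identity", "cov_q", "cov_s", "score"]


@dataclass
class HitTable:
    """Retained alignments plus per-(query, subject genome) best hits."""

    hits: pd.DataFrame
    best_hit: dict[tuple[str, str], str]
    gene_genome: dict[str, str]
    params: OrthologyParams = field(default=PANGENOME_PRESET)

    def to_tsv(self, path) -> None:
        self.hits.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class OrthologGroup:
    """A set of genes connected by BBH edges; id = smallest member gene id."""

    group_id: str
    members: frozenset[str]

    @property
    def representative(self) -> str:
        return self.group_id

    def __len__(self) -> int:
        return len(self.members)


def _candidate_pairs(
    genes: list[tuple[str, str, str]], params: OrthologyParams
) -> list[tuple[int, int]]:
    """Unordered cross-genome gene-index pairs passing the k-mer screen."""
    n = len(genes)
    if not params.min_shared_kmers:
        return [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if genes[i][1] != genes[j][1]
        ]
    k = params.kmer_size
    postings: dict[str, list[int]] = defaultdict(list)
    for idx, (_gid, _genome, seq) in enumerate(genes):
        for kmer in {seq[p : p + k] for p in range(len(seq) - k + 1)}:
            postings[kmer].append(idx)
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for members in postings.values():
        if len(members) < 2:
            continue
        for i, j in itertools.combinations(members, 2):
            if genes[i][1] != genes[j][1]:
                counts[(i, j)] += 1
    # a hit at the loosest preset (40% identity over 80% of both sequences)
    # shares on the order of 0.4^4 * 0.8 * L ~ 0.02 L distinct 4-mers, while
    # background collisions between unrelated proteins grow much slower, so
    # the requirement scales with the shorter sequence
    base = params.min_shared_kmers
    frac = params.kmer_frac
    out = []
    for (i, j), c in counts.items():
        need = max(base, int(frac * min(len(genes[i][2]), len(genes[j][2]))))
        if c >= need:
            out.append((i, j))
    return out


def all_vs_all(
    proteomes: dict[str, dict[str, str]],
    params: OrthologyParams = PANGENOME_PRESET,
) -> HitTable:
    """All-vs-all comparison of every genome's proteins against every other.

    ``proteomes`` maps genome id -> {gene id -> protein sequence}; gene ids
    must be globally unique.  Hits below the identity/coverage thresholds are
    discarded; among retained hits the highest score per (query, subject
    genome) is the best hit, ties broken by lexicographic subject id.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two genomes")
    genes: list[tuple[str, str, str]] = []
    for genome, prots in proteomes.items():
        if not prots:
            raise ValueError(f"genome {genome!r} has an empty proteome")
        for gid, seq in prots.items():
            if not seq:
                raise ValueError(f"empty protein sequence for {gid!r}")
            genes.append((gid, genome, seq))
    gene_genome = {gid: genome for gid, genome, _ in genes}
    if len(gene_genome) != len(genes):
        raise ValueError("gene ids are not globally unique")

    aligner = _aligner(params.scoring)
    rows: list[tuple] = []
    for i, j in _candidate_pairs(genes, params):
        gid_i, _genome_i, seq_i = genes[i]
        gid_j, _genome_j, seq_j = genes[j]
        if params.score_floor is not None:
            if aligner.score(seq_i, seq_j) <= params.score_floor:
                continue
        aln = aligner.align(seq_i, seq_j)[0]
        counts = aln.counts()
        identity, cov_i, cov_j = _stats_from_counts(
            counts.identities, counts.mismatches, len(seq_i), len(seq_j)
        )
        if identity < params.min_identity:
            continue
        if params.coverage_mode == "both":
            if cov_i < params.min_coverage or cov_j < params.min_coverage:
                continue
        else:
            if max(cov_i, cov_j) < params.min_coverage:
                continue
        score = float(aln.score)
        rows.append((gid_i, gid_j, identity, cov_i, cov_j, score))
        rows.append((gid_j, gid_i, identity, cov_j, cov_i, score))

    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    best: dict[tuple[str, str], str] = {}
    if not hits.empty:
        hits = hits.sort_values(["query", "subject"], kind="stable").reset_index(drop=True)
        scored: dict[tuple[str, str], tuple[float, str]] = {}
        for row in hits.itertuples(index=False):
            key = (row.query, gene_genome[row.subject])
            incumbent = scored.get(key)
            # on score ties the incumbent wins: hits are sorted by subject
            # id, so the incumbent is the lexicographically smaller subject
            if incumbent is None or row.score > incumbent[0]:
                scored[key] = (row.score, row.subject)
        best = {key: subject for key, (_score, subject) in scored.items()}
    return HitTable(hits=hits, best_hit=best, gene_genome=gene_genome, params=params)


def bbh_edges(table: HitTable) -> set[tuple[str, str]]:
    """Undirected reciprocal-best-hit edges as sorted gene-id tuples."""
    edges: set[tuple[str, str]] = set()
    for (query, _subject_genome), subject in table.best_hit.items():
        back = table.best_hit.get((subject, table.gene_genome[query]))
        if back == query:
            edges.add(tuple(sorted((query, subject))))  # type: ignore[arg-type]
    return edges


def ortholog_groups(
    edges: set[tuple[str, str]], all_genes: list[str] | set[str]
) -> list[OrthologGroup]:
    """Connected components of the BBH graph; edgeless genes are singletons."""
    graph = nx.Graph()
    graph.add_nodes_from(all_genes)
    graph.add_edges_from(edges)
    groups = [
        OrthologGroup(group_id=min(comp), members=frozenset(comp))
        for comp in nx.connected_components(graph)
    ]
    return sorted(groups, key=lambda g: g.group_id)


def find_orthologs(
    proteomes: dict[str, dict[str, str]],
    params: OrthologyParams = PANGENOME_PRESET,
) -> tuple[HitTable, list[OrthologGroup]]:
    """One-call convenience: all-vs-all, BBH edges, connected components."""
    table = all_vs_all(proteomes, params)
    edges = bbh_edges(table)
    all_genes = [g for prots in proteomes.values() for g in prots]
    return table, ortholog_groups(edges, all_genes)


def write_groups(groups: list[OrthologGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tmember\n")
        for group in groups:
            for member in sorted(group.members):
                fh.write(f"{group.group_id}\t{member}\n")
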
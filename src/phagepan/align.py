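"""Pairwise and progressive protein alignment.

This module is the computational substrate for the orthology search and the
phylogenies: exact global (Needleman-Wunsch) alignment with affine gaps and
BLOSUM62 scoring, percent identity and coverage under stated conventions, a
guide-tree progressive multiple aligner, and Poisson-corrected p-distances.

Conventions (fixed, documented here once):

* A gap run of length L costs ``gap_open + gap_extend * L`` (so a length-1
  gap costs 12 under the default 11/1 parameters, matching the common
  BLAST-style affine convention).
* ``identity`` = identical columns / aligned columns that contain no gap in
  either row.
* ``coverage_x`` = columns where both rows are non-gap, divided by the
  ungapped length of x.  Under global alignment this is symmetric in the
  numerator and differs between the two sequences only through the
  denominator.

The optimal-score machinery is delegated to :class:`Bio.Align.PairwiseAligner`
(a C implementation of Gotoh's algorithm); identity/coverage are derived from
its traceback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .cluster import upgma

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class ScoringParams:
    """Scoring scheme for global alignment.

    ``matrix`` names a biopython substitution matrix (default BLOSUM62);
    set it to ``None`` to use flat ``match``/``mismatch`` scores instead.
    ``gap_open``/``gap_extend`` are positive costs; a run of L gap columns
    costs ``gap_open + gap_extend * L``.
    """

    matrix: str | None = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 11.0
    gap_extend: float = 1.0


DEFAULT_SCORING = ScoringParams()


@lru_cache(maxsize=16)
def _aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if params.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    else:
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    # biopython charges open on the first gapped column, extend afterwards
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment with identity/coverage statistics."""

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    coverage_a: float
    coverage_b: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")


def _stats_from_counts(identities: int, mismatches: int, len_a: int, len_b: int):
    aligned_cols = identities + mismatches
    identity = identities / aligned_cols if aligned_cols else 0.0
    return identity, aligned_cols / len_a, aligned_cols / len_b


def global_align(a: str, b: str, params: ScoringParams = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Raises ``ValueError`` on empty input.  The traceback is biopython's
    deterministic first optimal path.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(params)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    identity, cov_a, cov_b = _stats_from_counts(
        counts.identities, counts.mismatches, len(a), len(b)
    )
    return AlignmentResult(
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=float(aln.score),
        identity=identity,
        coverage_a=cov_a,
        coverage_b=cov_b,
    )


def align_stats(
    a: str, b: str, params: ScoringParams = DEFAULT_SCORING
) -> tuple[float, float, float, float]:
    """(score, identity, coverage_a, coverage_b) without building row strings.

    Fast path used by the all-vs-all orthology search.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(params)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    identity, cov_a, cov_b = _stats_from_counts(
        counts.identities, counts.mismatches, len(a), len(b)
    )
    return float(aln.score), identity, cov_a, cov_b


def alignment_score(a: str, b: str, params: ScoringParams = DEFAULT_SCORING) -> float:
    """Optimal global alignment score only (no traceback)."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    return float(_aligner(params).score(a, b))


def kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shared_kmers(a: str, b: str, k: int = 4) -> int:
    """Number of distinct k-mers occurring in both sequences."""
    return len(kmer_set(a, k) & kmer_set(b, k))


# ---------------------------------------------------------------------------
# Multiple alignment
# ---------------------------------------------------------------------------


@dataclass
class MultipleAlignment:
    """Gapped rows keyed by label; all rows share one column count."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def labels(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, label: str) -> str:
        return self.rows[label].replace(GAP, "")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, row in self.rows.items():
                fh.write(f">{label}\n{row}\n")

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        rows: dict[str, str] = {}
        label, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if label is not None:
                        rows[label] = "".join(chunks)
                    label, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        if label is not None:
            rows[label] = "".join(chunks)
        return cls(rows)


_SYMBOLS = AMINO_ACIDS + GAP
_SYM_INDEX = {c: i for i, c in enumerate(_SYMBOLS)}


@lru_cache(maxsize=4)
def _profile_score_matrix(matrix_name: str, gap_vs_residue: float) -> np.ndarray:
    """Substitution matrix extended with a gap symbol for profile scoring."""
    sub = substitution_matrices.load(matrix_name)
    n = len(_SYMBOLS)
    S = np.zeros((n, n))
    for i, x in enumerate(AMINO_ACIDS):
        for j, y in enumerate(AMINO_ACIDS):
            S[i, j] = sub[x][y]
    S[:-1, -1] = S[-1, :-1] = gap_vs_residue
    S[-1, -1] = 0.0
    return S


def _profile(rows: list[str]) -> np.ndarray:
    """(columns x symbols) frequency profile of a sub-alignment."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
    idx = np.empty(arr.shape, dtype=np.int64)
    for sym, i in _SYM_INDEX.items():
        idx[arr == ord(sym)] = i
    ncol = len(rows[0])
    prof = np.zeros((ncol, len(_SYMBOLS)))
    flat = idx.reshape(len(rows), ncol)
    for r in flat:
        prof[np.arange(ncol), r] += 1.0
    return prof / len(rows)


def _profile_align(
    rows_a: list[str], rows_b: list[str], S: np.ndarray, gap: float
) -> tuple[list[str], list[str]]:
    """Align two sub-alignments with linear gap cost; returns padded rows.

    Row-wise DP: the in-row dependency is removed with the running-maximum
    identity  F[i,j] = gap*j + max_{k<=j} (cand[k] - gap*k).
    """
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    M = pa @ S @ pb.T
    F = np.empty((la + 1, lb + 1))
    F[0] = gap * np.arange(lb + 1)
    js = np.arange(lb + 1)
    for i in range(1, la + 1):
        cand = np.empty(lb + 1)
        cand[0] = F[i - 1, 0] + gap
        cand[1:] = np.maximum(F[i - 1, :-1] + M[i - 1], F[i - 1, 1:] + gap)
        F[i] = gap * js + np.maximum.accumulate(cand - gap * js)
    # traceback, diagonal > up > left on ties
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = la, lb
    tol = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(F[i, j] - (F[i - 1, j - 1] + M[i - 1, j - 1])) <= tol:
            i, j = i - 1, j - 1
            for r, row in zip(out_a, rows_a):
                r.append(row[i])
            for r, row in zip(out_b, rows_b):
                r.append(row[j])
        elif i > 0 and abs(F[i, j] - (F[i - 1, j] + gap)) <= tol:
            i -= 1
            for r, row in zip(out_a, rows_a):
                r.append(row[i])
            for r in out_b:
                r.append(GAP)
        else:
            j -= 1
            for r in out_a:
                r.append(GAP)
            for r, row in zip(out_b, rows_b):
                r.append(row[j])
    return ["".join(reversed(r)) for r in out_a], ["".join(reversed(r)) for r in out_b]


def progressive_msa(
    seqs: dict[str, str],
    params: ScoringParams = DEFAULT_SCORING,
    gap_column_cost: float = 8.0,
) -> MultipleAlignment:
    """Guide-tree progressive multiple alignment.

    The guide tree is UPGMA on pairwise identity distances (1 - identity of
    the optimal global alignment); sub-alignments are merged leaf-to-root by
    profile-profile dynamic programming with linear gap costs.  Labels are
    processed in lexicographic order, making the result independent of the
    input ordering.
    """
    if not seqs:
        raise ValueError("no sequences given")
    for label, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence for {label!r}")
    labels = sorted(seqs)
    if len(labels) == 1:
        return MultipleAlignment({labels[0]: seqs[labels[0]]})
    if len(labels) == 2:
        res = global_align(seqs[labels[0]], seqs[labels[1]], params)
        return MultipleAlignment({labels[0]: res.aligned_a, labels[1]: res.aligned_b})

    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(seqs[labels[i]], seqs[labels[j]], params)
            dist[i, j] = dist[j, i] = 1.0 - res.identity
    dendro = upgma(dist, labels)

    matrix_name = params.matrix or "BLOSUM62"
    S = _profile_score_matrix(matrix_name, -gap_column_cost / 2.0)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([labels[i]], [seqs[labels[i]]]) for i in range(n)
    }
    next_id = n
    for a, b, _h in dendro.merges:
        la, ra = clusters.pop(a)
        lb, rb = clusters.pop(b)
        new_a, new_b = _profile_align(ra, rb, S, -gap_column_cost)
        clusters[next_id] = (la + lb, new_a + new_b)
        next_id += 1
    (final_labels, final_rows), = clusters.values()
    rows = dict(sorted(zip(final_labels, final_rows)))
    return MultipleAlignment(rows)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

P_DISTANCE_CAP = 0.95


def pdistance(msa: MultipleAlignment, i: str, j: str) -> float:
    """Proportion of mismatched columns among columns gap-free in both rows."""
    row_i, row_j = msa.rows[i], msa.rows[j]
    compared = mismatched = 0
    for x, y in zip(row_i, row_j):
        if x != GAP and y != GAP:
            compared += 1
            if x != y:
                mismatched += 1
    if compared == 0:
        raise ValueError(f"no comparable columns between {i!r} and {j!r}")
    return mismatched / compared


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance -ln(1-p), with p capped at 0.95."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return -math.log(1.0 - min(p, P_DISTANCE_CAP))


def distance_matrix(msa: MultipleAlignment, correction: str = "poisson"):
    """Pairwise distances between all rows of an alignment.

    Returns (labels, square numpy array).  ``correction`` is ``"poisson"``
    or ``"p"`` (uncorrected).
    """
    labels = sorted(msa.rows)
    n = len(labels)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            p = pdistance(msa, labels[a], labels[b])
            d = poisson_distance(p) if correction == "poisson" else p
            out[a, b] = out[b, a] = d
    return labels, out
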
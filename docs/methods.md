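# Methods

This note documents the models, conventions and design choices behind
`phagepan`, in the order the pipeline runs them.

## Alignment substrate

All sequence comparison is protein-level global alignment
(Needleman–Wunsch with affine gaps, Gotoh recurrences), delegated to
biopython's C `PairwiseAligner`. Conventions, fixed once:

* **Scoring** — BLOSUM62 by default; a gap run of length L costs
  `gap_open + gap_extend · L` (defaults 11 + L, the BLAST-style affine
  convention). End gaps are penalised (true global alignment).
* **Identity** — identical columns divided by aligned columns containing
  no gap in either row. This is one of several BLAST-compatible
  conventions; it is stated rather than inferred.
* **Coverage** — columns where both rows are residues, divided by the
  ungapped length of each sequence separately. The coverage threshold is
  applied to *both* sequences by default (`coverage_mode="both"`): a
  symmetric rule avoids asymmetric ortholog graphs; `"one"` is available.
* **Tie-breaking** — the aligner's traceback is deterministic; among
  co-optimal alignments the reported identity can in principle depend on
  which path is returned, but scores (used for best-hit selection) cannot.
* The optimal score is validated against exhaustive alignment enumeration
  for sequences up to length 8 in the test suite.

The multiple aligner is guide-tree progressive: UPGMA on pairwise identity
distances, profiles merged leaf-to-root by profile–profile dynamic
programming (linear gap columns, gap-vs-residue half the column cost).
It is deliberately simple — downstream consumers only need alignments
adequate for p-distance computation, not phylogeny-aware gap placement.
Labels are processed in lexicographic order, so the result is independent
of input ordering.

Distances from alignments are p-distances (mismatches over gap-free
compared columns) with Poisson correction −ln(1−p); p is capped at 0.95
before the log so saturated pairs stay finite (distance ≈ 3.0) instead of
degenerating to infinity.

## Orthology

Bidirectional best hit (BBH): for every ordered genome pair, alignments
passing identity and coverage thresholds are hits; the highest-scoring hit
per (query, subject genome) is the best hit (ties broken by lexicographic
subject id); reciprocal best hits form edges; ortholog groups are connected
components of the edge graph, with edgeless genes as singleton "unique"
groups. Self-genome comparisons are excluded, so paralogs join a group only
through cross-genome edges. The strict "similarity 1.0" setting of the
published workflow is interpreted as: no expansion beyond strict reciprocal
best hits, and plain graph components instead of spectral partitioning —
with strict reciprocity the elaborate partitioning is a no-op in the common
case, and components are deterministic and testable.

Two presets: 50% identity / 50% coverage for phage pangenomes; 40% / 80%
for eps/rgp operon genes, which are frequently horizontally transferred and
therefore more divergent than the genome average.

**Pair screening.** The quadratic pair space is screened before alignment:
a candidate pair must share at least `max(min_shared_kmers, kmer_frac ·
min(len))` distinct 4-mers (defaults 3 and 0.02). The rationale: a genuine
hit at the loosest preset (40% identity over ≥80% of both sequences) shares
on the order of 0.4⁴ · 0.8 · L ≈ 0.02 L identical 4-mer windows, while two
unrelated random proteins of length ~250 share ~0.4 on average, so the
screen removes essentially all unrelated pairs and essentially no true
hits. Both the count floor and the length scaling can be disabled
(`min_shared_kmers=None`), as can an optional raw-score floor applied
before traceback (`score_floor`). The permissive preset disables all
screens for debugging.

## Pangenome clustering

Presence/absence matrix: cell(g, F) = 1 iff genome g carries ≥1 member of
family F (paralogs collapse). Jaccard distances between genome rows, UPGMA
(average linkage) agglomeration. Dendrogram node heights are *ultrametric*
heights — a merge of clusters at average distance d happens at height d/2 —
so cophenetic distances (2 × LCA height) reproduce ultrametric inputs
exactly and agree with scipy's average-linkage merge distances. Ties in the
merge queue are broken by the smallest cluster-id pair. Cutting is by
cluster count k or by height; k = 4 is the analysis's grouping cut.

Statistics: per-cluster core = families present in every member; unique =
families present in exactly one genome of the whole collection (the
"singleton column" reading of unique genes — the alternative,
genome-private families with paralogs collapsed, is identical under BBH
grouping since paralogs only enter groups via cross-genome edges);
near-core = families missing from at most `max_missing` genomes (default 1,
excluding the global core itself).

## Phylogeny

Trees are neighbor joining (Saitou–Nei Q-matrix, standard branch-length
formulas) on Poisson-corrected protein distances. Maximum-likelihood
inference and the GTR/GAMMA/WAG substitution models are intentionally out
of scope: NJ is exactly consistent on additive distances, and clade
membership — the quantity the downstream association consumes — is
preserved on well-separated data. Negative branch lengths are clamped to
zero with the deficit moved to the sister edge; Q-matrix ties break on the
smallest index pair. Bootstrap support resamples alignment columns with
replacement and reports the percentage of replicates containing each
internal bipartition; supports live on internal node names so they survive
newick round trips.

RBP handling: one RBP per genome, identified by product annotation
(substring match, configurable); a sequence whose best pairwise identity
against every other RBP falls below 30% is excluded (the boundary itself is
included), mirroring the exclusion rule applied to the real data, with the
maximum observed identity recorded as the reason. Lineages are
single-linkage clusters of leaf patristic distances at a stated threshold
(default 0.30): the published analysis delineated clusters by visual
comparison of tree layouts, which is not reproducible, so an explicit
parameterised rule replaces it; the default cleanly separates
within-lineage distances (≈2 × within-lineage divergence) from
between-lineage distances (≈0.5+) at the generator's defaults. Labels are
roman numerals ordered by each cluster's smallest leaf.

## Operon typing

eps clusters are flanked by *epsA* and a predicted membrane protein (TMS6);
rgp clusters by *radC* and a bactoprenol glucosyl transferase. Markers are
found either by exact (case-insensitive) product-string match — the
synthetic path, where the generator emits fixed marker genes with those
products — or by global-alignment homology (identity ≥0.5) to user-supplied
marker proteins, the real-data path. With both markers on one contig the
genes strictly between them are the cluster, whatever the orientation. With
markers on two contigs (draft assemblies) each marker contributes the genes
from itself towards its contig end in its reading direction (downstream of
the left marker, upstream of the right), the cluster is flagged incomplete,
and typing proceeds on the partial content — matching how incomplete
operons were still typed in practice. A missing marker is a recorded,
non-fatal typing failure; a duplicated marker is an ambiguity error.

Genotype letters: operon gene-content matrix (40%/80% preset) → Jaccard +
UPGMA → cut → letters A, B, … by decreasing cluster size (ties by smallest
strain id). No published rule fixes the cut; the default is a height cut at
Jaccard distance 0.5 (dendrogram height 0.25), with `k` as an override.
For recovery testing the k cut at the planted genotype count is the right
tool: random genotype gene sets can overlap enough to merge below any fixed
height, while the k cut is exact whenever within-genotype distances (≈0)
sit below between-genotype distances.

## Association statistics

Exact hypergeometric probabilities in integer arithmetic
(`math.comb`), converted to float at the end. A phage is a success iff
*every* listed host strain carries one of the designated genotype letters
(no phage with discordant hosts occurs in the packaged table; the all-hosts
rule is the conservative choice). The statistical universe is the full
analysis table (N = 43 phages for the packaged data): with K successes and
n drawn phages, an all-success draw is scored C(K,n)/C(N,n), otherwise the
upper tail P(X ≥ k_obs) by default ("except one" ⇒ k_min = n−1); the point
probability is available via `tail="point"`. No multiple-testing
correction is applied — the analysis reports raw probabilities.

Shared-host concordance: a case is a maximal set of ≥2 phages with an
identical host-strain set (default) or a connected component of phages
sharing ≥1 strain (`mode="overlap"`); a case is concordant iff its phages
share one cluster label. Note that full concordance on synthetic data is
only construction-guaranteed when the lineage→genotype map is injective;
with more lineages than genotypes (the default 7 vs 6, as in the real
data) two lineages share a genotype and can legitimately share hosts.

## Synthetic populations

The generator plants the structure the analysis assumes, at the emulated
study's scale, with every default stated here:

| parameter | default | rationale |
|---|---|---|
| groups / genomes | 4 groups of 20/10/4/4 | two dominant groups plus two small ones, 38 genomes total |
| genes per genome | uniform 40–63 | the observed CDS range (mean ≈50) |
| core families per group | 13 | the core-genome size of the two dominant groups |
| group pool / shared pool | 120 / 20 families | mosaic accessory content; pool ≫ per-genome accessory count |
| protein lengths | uniform 100–400 aa | typical phage ORF lengths |
| RBP | 150 aa conserved N-terminal + 250 aa VR2 | conserved amino-terminus, variable host-recognition region |
| RBP lineages | 7, nested in groups (3/2/1/1) | the seven observed RBP clusters; allocation by greatest-divisor rounds over group sizes |
| between/within-lineage divergence | 0.40 / 0.05 per site | separates lineages (pairwise p ≈ 0.4+) from within-lineage noise (p ≈ 0.1) |
| strains | 23 | the typed host panel |
| EPS / RGP genotypes | 6 / 5, round-robin over strains | the observed genotype letters; 6≠5 guarantees strains sharing an EPS genotype with different RGP genotypes |
| eps / rgp genes per cluster | uniform 13–22 / 14–20 from pools of 40 | observed cluster sizes (means ≈17.7 / 16.8, minima 13 / 14) |
| host range | 1–2 strains of the matched genotype; noise flips a link to a non-matching strain | narrow host ranges; noise 0 by default |

Sequences are uniform random over the 20 amino acids: downstream operators
consume only identity/coverage, and random 100–400-aa proteins concentrate
far below every orthology threshold (checked empirically), so compositional
realism buys nothing. Marker genes are fixed literal sequences independent
of the seed. All randomness flows from one seed through named substreams
(one per genome, strain, family and decision), so outputs are byte-stable
and adding a genome does not perturb the others. Nucleotide contigs are
deterministic reverse-translations with 50-bp random spacers, all genes on
the forward strand (reverse-strand handling is exercised by crafted
fixtures, not the generator).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic recombination breakpoints (accessory
content is an i.i.d. sample, not a mosaic of linked blocks), amino-acid
composition and indel processes, annotation noise (the marker search by
product string cannot fail the way a BLAST search on a draft genome can),
temperate/lytic biology, and intergenic architecture. Recovery at the
defaults demonstrates internal consistency of the pipeline, not its
robustness to real annotation and assembly artefacts.

## Problem sizes

The test suite and the acceptance script run the full pipeline on
populations at the default scale above (38 genomes ≈ 1,950 proteins;
23 strains). Parameter-recovery acceptance uses 20 seeded populations in
the tests and 5 in the acceptance script; each population takes ~20 s on
one CPU, dominated by the ~7,000 surviving candidate alignments of the
all-vs-all stage. Oracle suites (alignment enumeration ≤8 aa, subset
enumeration N ≤ 12, NJ on random additive trees n ≤ 10) are sized to keep
exhaustive checking exact and fast.

## Known limitations

* The `<30%` RBP exclusion reads "similarity" as pairwise global identity;
  a score-ratio reading would differ for length-mismatched pairs.
* Proteinortho's actual coverage convention in the original runs is
  unrecoverable; both-sided coverage is the default here, one-sided is a
  flag.
* Tree-cluster delineation and the genotype-letter cut replace subjective
  published procedures with explicit parameterised rules; defaults are
  stated, intent is not guessed.
* Multi-contig genome ordering is taken as given; the reader does not
  attempt scaffolding.
* The real-data headline counts that require the full 142-genome corpus
  (361 pangenome families, 30% unique, the 16/13 and 12/16 concordance
  counts) are procedure-covered but not numerically reproduced at desk
  scale.
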
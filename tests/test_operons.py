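"""Operon extraction by flanking markers and genotype letter assignment."""

import random

import pytest

from phagepan.align import AMINO_ACIDS, global_align
from phagepan.operons import (
    EPS_MARKERS,
    AmbiguousMarkerError,
    MarkerNotFoundError,
    assign_genotypes,
    locate_cluster,
    operon_matrix,
    type_host_strains,
)
from phagepan.orthology import OrthologyParams
from phagepan.records import GeneRecord, Genome
from phagepan.simulate import (
    EPS_LEFT_PRODUCT,
    EPS_RIGHT_PRODUCT,
    MARKER_PROTEINS,
    mutate_sequence,
)


def rand_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(n))


def build_genome(genome_id: str, entries, contig="c1", start0=0) -> Genome:
    """entries: list of (gene_id, product, protein[, contig])."""
    genes = []
    pos = start0
    for entry in entries:
        gene_id, product, protein = entry[:3]
        ctg = entry[3] if len(entry) > 3 else contig
        length = 3 * (len(protein) + 1)
        genes.append(
            GeneRecord(
                genome_id=genome_id, gene_id=gene_id, contig=ctg,
                start=pos, end=pos + length, strand="+",
                product=product, protein=protein,
            )
        )
        pos += length + 50
    return Genome(genome_id=genome_id, genes=genes)


def flip_genome(genome: Genome) -> Genome:
    """Mirror all coordinates and strands (reverse-complement the contig)."""
    total = max(g.end for g in genome.genes) + 50
    genes = [
        GeneRecord(
            genome_id=genome.genome_id, gene_id=g.gene_id, contig=g.contig,
            start=total - g.end, end=total - g.start,
            strand="-" if g.strand == "+" else "+",
            product=g.product, protein=g.protein,
        )
        for g in reversed(genome.genes)
    ]
    return Genome(genome_id=genome.genome_id, genes=genes)


@pytest.fixture()
def toy_strain():
    rng = random.Random(0)
    entries = [(f"f{i}", "hypothetical protein", rand_protein(rng, 80)) for i in range(5)]
    entries.append(("epsA", EPS_LEFT_PRODUCT, MARKER_PROTEINS[EPS_LEFT_PRODUCT]))
    entries += [
        (f"eps{i}", "eps cluster protein", rand_protein(rng, 100)) for i in range(6)
    ]
    entries.append(("tms6", EPS_RIGHT_PRODUCT, MARKER_PROTEINS[EPS_RIGHT_PRODUCT]))
    entries += [(f"t{i}", "hypothetical protein", rand_protein(rng, 80)) for i in range(2)]
    return build_genome("S1", entries)


class TestLocateCluster:
    def test_genes_between_markers(self, toy_strain):
        cluster = locate_cluster(toy_strain, EPS_MARKERS)
        assert cluster.complete and cluster.n_contigs == 1
        assert [g.gene_id for g in cluster.genes] == [f"eps{i}" for i in range(6)]

    def test_strand_flip_invariance(self, toy_strain):
        forward = locate_cluster(toy_strain, EPS_MARKERS)
        flipped = locate_cluster(flip_genome(toy_strain), EPS_MARKERS)
        assert {g.gene_id for g in flipped.genes} == {g.gene_id for g in forward.genes}
        assert flipped.complete

    def test_markers_on_two_contigs(self):
        rng = random.Random(1)
        entries = [
            ("epsA", EPS_LEFT_PRODUCT, MARKER_PROTEINS[EPS_LEFT_PRODUCT], "c1"),
            ("eps0", "eps cluster protein", rand_protein(rng, 90), "c1"),
            ("eps1", "eps cluster protein", rand_protein(rng, 90), "c1"),
        ]
        genome = build_genome("S2", entries)
        pos = 0
        for gid, prod, prot in [
            ("eps2", "eps cluster protein", rand_protein(rng, 90)),
            ("tms6", EPS_RIGHT_PRODUCT, MARKER_PROTEINS[EPS_RIGHT_PRODUCT]),
            ("after", "hypothetical protein", rand_protein(rng, 90)),
        ]:
            length = 3 * (len(prot) + 1)
            genome.genes.append(
                GeneRecord(
                    genome_id="S2", gene_id=gid, contig="c2",
                    start=pos, end=pos + length, strand="+",
                    product=prod, protein=prot,
                )
            )
            pos += length + 50
        cluster = locate_cluster(genome, EPS_MARKERS)
        assert not cluster.complete and cluster.n_contigs == 2
        assert {g.gene_id for g in cluster.genes} == {"eps0", "eps1", "eps2"}

    def test_missing_marker_raises(self):
        genome = build_genome(
            "S3", [("g0", "hypothetical protein", rand_protein(random.Random(2), 80))]
        )
        with pytest.raises(MarkerNotFoundError):
            locate_cluster(genome, EPS_MARKERS)

    def test_duplicated_marker_ambiguous(self, toy_strain):
        dup = build_genome(
            "S4",
            [("epsA_b", EPS_LEFT_PRODUCT, MARKER_PROTEINS[EPS_LEFT_PRODUCT])],
            start0=10_000,
        )
        toy_strain.genes.extend(dup.genes)
        with pytest.raises(AmbiguousMarkerError):
            locate_cluster(toy_strain, EPS_MARKERS)

    def test_homology_path_finds_markers(self, toy_strain):
        # wipe the products; markers must now be found by sequence
        anonymous = Genome(
            genome_id="S5",
            genes=[
                GeneRecord(
                    genome_id="S5", gene_id=g.gene_id, contig=g.contig,
                    start=g.start, end=g.end, strand=g.strand,
                    product="hypothetical protein", protein=g.protein,
                )
                for g in toy_strain.genes
            ],
        )
        cluster = locate_cluster(
            anonymous, EPS_MARKERS,
            marker_seqs={
                EPS_LEFT_PRODUCT: MARKER_PROTEINS[EPS_LEFT_PRODUCT],
                EPS_RIGHT_PRODUCT: MARKER_PROTEINS[EPS_RIGHT_PRODUCT],
            },
        )
        assert [g.gene_id for g in cluster.genes] == [f"eps{i}" for i in range(6)]


class TestOperonMatrix:
    def test_identical_clusters_identical_rows(self, small_population):
        from phagepan.operons import EPS_MARKERS

        strains = small_population.strains
        truth = small_population.truth
        same = [
            s for s in strains
            if truth.strain_eps_genotype[s.genome_id]
            == truth.strain_eps_genotype[strains[0].genome_id]
        ][:2]
        clusters = [locate_cluster(s, EPS_MARKERS) for s in same]
        matrix = operon_matrix(clusters)
        rows = matrix.df.to_numpy()
        assert (rows[0] == rows[1]).all()

    def test_divergence_straddles_identity_presets(self):
        """Gene pairs near 45% identity: one family at the 40% preset,
        two families at the 50% preset."""
        rng = random.Random(7)
        base = [rand_protein(rng, 200) for _ in range(3)]
        mutated = [mutate_sequence(s, 0.52, 1000 + i) for i, s in enumerate(base)]
        idents = [global_align(a, b).identity for a, b in zip(base, mutated)]
        assert all(0.40 <= x < 0.50 for x in idents), idents
        entries_a = [("epsA", EPS_LEFT_PRODUCT, MARKER_PROTEINS[EPS_LEFT_PRODUCT])]
        entries_a += [(f"a{i}", "eps cluster protein", s) for i, s in enumerate(base)]
        entries_a += [("tms6", EPS_RIGHT_PRODUCT, MARKER_PROTEINS[EPS_RIGHT_PRODUCT])]
        entries_b = [("epsA", EPS_LEFT_PRODUCT, MARKER_PROTEINS[EPS_LEFT_PRODUCT])]
        entries_b += [(f"b{i}", "eps cluster protein", s) for i, s in enumerate(mutated)]
        entries_b += [("tms6", EPS_RIGHT_PRODUCT, MARKER_PROTEINS[EPS_RIGHT_PRODUCT])]
        clusters = [
            locate_cluster(build_genome("SA", entries_a), EPS_MARKERS),
            locate_cluster(build_genome("SB", entries_b), EPS_MARKERS),
        ]
        low = operon_matrix(clusters, OrthologyParams(min_identity=0.40, min_coverage=0.8,
                                                      min_shared_kmers=None))
        high = operon_matrix(clusters, OrthologyParams(min_identity=0.50, min_coverage=0.8,
                                                       min_shared_kmers=None))
        assert len(low.groups) == 3  # merged families
        assert len(high.groups) == 6  # split families

    def test_requires_two_strains(self, toy_strain):
        with pytest.raises(ValueError):
            operon_matrix([locate_cluster(toy_strain, EPS_MARKERS)])


class TestAssignGenotypes:
    def test_all_identical_single_letter(self, small_population):
        strains = small_population.strains
        truth = small_population.truth
        same = [
            s for s in strains
            if truth.strain_eps_genotype[s.genome_id]
            == truth.strain_eps_genotype[strains[0].genome_id]
        ]
        clusters = [locate_cluster(s, EPS_MARKERS) for s in same]
        matrix = operon_matrix(clusters)
        letters, _dendro = assign_genotypes(matrix, k=1)
        assert set(letters.values()) == {"A"}

    def test_k_equal_n_all_distinct(self, small_population):
        clusters = [locate_cluster(s, EPS_MARKERS) for s in small_population.strains[:4]]
        matrix = operon_matrix(clusters)
        letters, _d = assign_genotypes(matrix, k=len(matrix.genomes))
        assert len(set(letters.values())) == len(matrix.genomes)

    def test_k_exceeding_strain_count_rejected(self, small_population):
        clusters = [locate_cluster(s, EPS_MARKERS) for s in small_population.strains[:3]]
        matrix = operon_matrix(clusters)
        with pytest.raises(ValueError):
            assign_genotypes(matrix, k=99)


class TestTypeHostStrains:
    def test_planted_genotypes_recovered(self, small_population, small_config):
        from sklearn.metrics import adjusted_rand_score

        assignment = type_host_strains(
            small_population.strains,
            eps_k=small_config.n_eps_genotypes,
            rgp_k=small_config.n_rgp_genotypes,
        )
        truth = small_population.truth
        idx = sorted(assignment.table.index)
        for kind, planted in (
            ("eps", truth.strain_eps_genotype),
            ("rgp", truth.strain_rgp_genotype),
        ):
            ari = adjusted_rand_score(
                [planted[s] for s in idx], [assignment.letter(s, kind) for s in idx]
            )
            assert ari == 1.0

    def test_eps_and_rgp_letters_are_independent(self, small_population, small_config):
        """The simulator plants strains sharing an EPS genotype but holding
        different RGP genotypes; typing must reproduce that discordance."""
        assignment = type_host_strains(
            small_population.strains,
            eps_k=small_config.n_eps_genotypes,
            rgp_k=small_config.n_rgp_genotypes,
        )
        table = assignment.table
        discordant = [
            (a, b)
            for a in table.index
            for b in table.index
            if a < b
            and table.loc[a, "eps_genotype"] == table.loc[b, "eps_genotype"]
            and table.loc[a, "rgp_genotype"] != table.loc[b, "rgp_genotype"]
        ]
        assert discordant

    def test_marker_failure_recorded_nonfatal(self, small_population):
        broken = Genome(genome_id="BROKEN", genes=[
            GeneRecord(genome_id="BROKEN", gene_id="x", contig="c", start=0, end=33,
                       strand="+", product="hypothetical protein", protein="ACDEFGHIKL")
        ])
        assignment = type_host_strains(small_population.strains[:4] + [broken])
        assert any(s == "BROKEN" for s, _k, _m in assignment.failures)
        assert assignment.table.loc["BROKEN", "eps_genotype"] == ""
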
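"""NJ consistency on additive matrices, bootstrap, RBP selection and lineages."""

import random

import numpy as np
import pytest
from skbio import TreeNode

from phagepan.align import AMINO_ACIDS, MultipleAlignment, global_align
from phagepan.phylogeny import (
    bootstrap_support,
    concatenate_core,
    neighbor_joining,
    patristic_distances,
    rbp_lineages,
    select_rbps,
    to_roman,
    tree_clusters,
)
from phagepan.records import GeneRecord, Genome


def rand_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(n))


def random_binary_tree(rng: np.random.Generator, n: int) -> TreeNode:
    nodes = [TreeNode(name=f"T{i}", length=float(rng.uniform(0.1, 1.0))) for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode(children=[b, a], length=float(rng.uniform(0.1, 1.0)))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    return TreeNode(children=nodes)


class TestConcatenate:
    def test_two_blocks(self):
        a = MultipleAlignment({"X": "AAAAA-AAAA", "Y": "CCCCCCCC-C"})
        b = MultipleAlignment({"X": "DDDDDDDDDD", "Y": "EEEEE-EEEE"})
        cat = concatenate_core({"g2": b, "g1": a}, ["X", "Y"])
        assert cat.length == 20
        assert cat.rows["X"] == a.rows["X"] + b.rows["X"]

    def test_single_block_passthrough(self):
        a = MultipleAlignment({"X": "AAA", "Y": "CCC"})
        assert concatenate_core({"g": a}, ["X", "Y"]).rows == a.rows

    def test_order_independence(self):
        a = MultipleAlignment({"X": "AA", "Y": "CC"})
        b = MultipleAlignment({"X": "DD", "Y": "EE"})
        assert (
            concatenate_core({"g1": a, "g2": b}, ["X", "Y"]).rows
            == concatenate_core({"g2": b, "g1": a}, ["X", "Y"]).rows
        )

    def test_missing_genome_contradicts_coreness(self):
        a = MultipleAlignment({"X": "AA"})
        with pytest.raises(ValueError):
            concatenate_core({"g": a}, ["X", "Y"])


class TestNeighborJoining:
    def test_four_point_additive_oracle(self):
        # tree (A:1,B:2)-3-(C:4,D:5)
        labels = list("ABCD")
        d = np.array(
            [
                [0, 3, 8, 9],
                [3, 0, 9, 10],
                [8, 9, 0, 9],
                [9, 10, 9, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(labels, d)
        got_labels, got = patristic_distances(tree)
        order = [got_labels.index(x) for x in labels]
        assert np.allclose(got[np.ix_(order, order)], d)
        # exact branch lengths: A and B hang off one node at 1 and 2
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)
        assert lengths["D"] == pytest.approx(5.0)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(list("ABC"), d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(["A", "B"], np.zeros((2, 2)))

    def test_recovers_random_additive_trees(self):
        """NJ is exactly consistent: distances from a random tree give back
        the same topology (Robinson-Foulds 0) and reproduce the matrix."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            source = random_binary_tree(rng, n)
            dm = source.tip_tip_distances()
            labels = list(dm.ids)
            tree = neighbor_joining(labels, dm.data)
            assert tree.compare_rfd(source) == 0.0
            got_labels, got = patristic_distances(tree)
            order = [got_labels.index(x) for x in labels]
            assert np.allclose(got[np.ix_(order, order)], dm.data)

    def test_matches_skbio_nj_topology(self):
        from skbio.tree import nj as skbio_nj
        from skbio import DistanceMatrix

        rng = np.random.default_rng(23)
        for _ in range(5):
            source = random_binary_tree(rng, 8)
            dm = source.tip_tip_distances()
            mine = neighbor_joining(list(dm.ids), dm.data)
            theirs = skbio_nj(DistanceMatrix(dm.data, list(dm.ids)))
            assert mine.compare_rfd(theirs) == 0.0


class TestPatristic:
    def test_equals_brute_force_path_sums(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            tree = random_binary_tree(rng, int(rng.integers(4, 13)))
            labels, d = patristic_distances(tree)
            tips = {t.name: t for t in tree.tips()}

            def path_sum(a, b):
                anc_b = {id(x) for x in [b] + list(b.ancestors())}
                common = next(x for x in [a] + list(a.ancestors()) if id(x) in anc_b)
                total = 0.0
                for node in (a, b):
                    while node is not common:
                        total += node.length or 0.0
                        node = node.parent
                return total

            for i, la in enumerate(labels):
                for lb in labels[i + 1 :]:
                    j = labels.index(lb)
                    assert d[i, j] == pytest.approx(path_sum(tips[la], tips[lb]))


class TestBootstrap:
    @staticmethod
    def caterpillar_alignment(n_taxa: int = 6, block: int = 25) -> MultipleAlignment:
        """Zero-homoplasy alignment: block k separates taxa <= k from the rest."""
        rows = {f"t{i}": [] for i in range(n_taxa)}
        for k in range(1, n_taxa - 1):
            for i in range(n_taxa):
                rows[f"t{i}"].append(("A" if i <= k else "C") * block)
        return MultipleAlignment({k: "".join(v) for k, v in rows.items()})

    def test_clean_signal_gives_full_support(self):
        msa = self.caterpillar_alignment()
        tree = bootstrap_support(msa, n_reps=50, seed=0)
        supports = [n.support for n in tree.non_tips(include_self=False) if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_binary(self):
        msa = self.caterpillar_alignment()
        tree = bootstrap_support(msa, n_reps=1, seed=3)
        supports = [n.support for n in tree.non_tips(include_self=False) if hasattr(n, "support")]
        assert supports and set(supports) <= {0.0, 100.0}

    def test_same_seed_reproducible(self):
        msa = self.caterpillar_alignment()
        t1 = bootstrap_support(msa, n_reps=20, seed=9)
        t2 = bootstrap_support(msa, n_reps=20, seed=9)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False) if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False) if hasattr(n, "support"))
        assert s1 == s2

    def test_leaf_order_permutation_invariance(self):
        msa = self.caterpillar_alignment()
        perm = MultipleAlignment(dict(reversed(list(msa.rows.items()))))
        s1 = sorted(
            n.support
            for n in bootstrap_support(msa, 20, seed=5).non_tips(include_self=False)
            if hasattr(n, "support")
        )
        s2 = sorted(
            n.support
            for n in bootstrap_support(perm, 20, seed=5).non_tips(include_self=False)
            if hasattr(n, "support")
        )
        assert s1 == s2

    def test_degenerate_inputs_rejected(self):
        msa = self.caterpillar_alignment()
        with pytest.raises(ValueError):
            bootstrap_support(msa, n_reps=0)
        with pytest.raises(ValueError):
            bootstrap_support(MultipleAlignment({"a": "A", "b": "C", "c": "A", "d": "C"}), 5)


def _genome_with_rbp(genome_id: str, rbp: str | None) -> Genome:
    genes = []
    if rbp is not None:
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                gene_id=f"{genome_id}_rbp",
                contig="c1",
                start=0,
                end=3 * (len(rbp) + 1),
                strand="+",
                product="receptor binding protein",
                protein=rbp,
            )
        )
    return Genome(genome_id=genome_id, genes=genes)


class TestSelectRbps:
    def test_identical_rbps_all_included(self):
        seq = rand_protein(random.Random(1), 150)
        genomes = [_genome_with_rbp(f"P{i}", seq) for i in range(3)]
        rbps = select_rbps(genomes)
        assert set(rbps.included) == {"P0", "P1", "P2"}
        assert rbps.excluded == []

    def test_random_outlier_excluded(self):
        rng = random.Random(2)
        base = rand_protein(rng, 200)
        from phagepan.simulate import mutate_sequence

        genomes = [
            _genome_with_rbp(f"P{i}", mutate_sequence(base, 0.05, i)) for i in range(5)
        ]
        genomes.append(_genome_with_rbp("OUT", rand_protein(rng, 200)))
        rbps = select_rbps(genomes)
        assert "OUT" not in rbps.included
        assert any(p == "OUT" and "max identity" in reason for p, reason in rbps.excluded)

    def test_missing_annotation_nonfatal(self):
        seq = rand_protein(random.Random(3), 150)
        genomes = [_genome_with_rbp("P0", seq), _genome_with_rbp("P1", seq),
                   _genome_with_rbp("NONE", None)]
        rbps = select_rbps(genomes)
        assert ("NONE", "not found") in rbps.excluded
        assert set(rbps.included) == {"P0", "P1"}

    def test_threshold_boundary_is_closed(self):
        """A pair exactly at the threshold identity is included."""
        rng = random.Random(4)
        a = rand_protein(rng, 120)
        from phagepan.simulate import mutate_sequence

        b = mutate_sequence(a, 0.5, 99)
        identity = global_align(a, b).identity
        genomes = [_genome_with_rbp("A", a), _genome_with_rbp("B", b)]
        at = select_rbps(genomes, min_similarity=identity)
        above = select_rbps(genomes, min_similarity=identity + 1e-9)
        assert set(at.included) == {"A", "B"}
        assert above.included == {}


class TestTreeClusters:
    @pytest.fixture()
    def tree(self):
        return TreeNode.read(["((A:0.05,B:0.05):0.5,(C:0.05,D:0.05):0.5,E:1.0);"])

    def test_large_threshold_single_cluster(self, tree):
        labels = tree_clusters(tree, threshold=10.0)
        assert set(labels.values()) == {"I"}

    def test_tiny_threshold_singletons(self, tree):
        labels = tree_clusters(tree, threshold=0.01)
        assert len(set(labels.values())) == 5

    def test_pair_clusters(self, tree):
        labels = tree_clusters(tree, threshold=0.2)
        assert labels["A"] == labels["B"] == "I"
        assert labels["C"] == labels["D"] == "II"
        assert labels["E"] == "III"

    def test_roman_labels(self):
        assert [to_roman(i) for i in (1, 2, 4, 7, 9)] == ["I", "II", "IV", "VII", "IX"]


class TestRbpLineageRecovery:
    def test_planted_lineages_recovered(self, small_population):
        from sklearn.metrics import adjusted_rand_score

        labels, tree, rbps = rbp_lineages(small_population.genomes)
        assert rbps.excluded == []
        truth = small_population.truth
        ids = sorted(labels)
        ari = adjusted_rand_score(
            [truth.rbp_lineage[g] for g in ids], [labels[g] for g in ids]
        )
        assert ari == 1.0
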
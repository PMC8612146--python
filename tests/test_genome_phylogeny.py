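import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from scipy.spatial.distance import jensenshannon

from phagetf import genome_phylogeny as gp
from phagetf.io_formats import GenomeRecord


def _genome(seq, gid="g"):
    return GenomeRecord(genome_id=gid, sequence=seq)


def _profile(gid, freq, k=1):
    return gp.KmerProfile(gid, k, np.asarray(freq, dtype=float))


class TestKmerProfile:
    def test_homopolymer(self):
        prof = gp.kmer_profile(_genome("AAAA"), 2)
        assert prof.freq[0] == 1.0
        assert prof.freq.sum() == pytest.approx(1.0)

    def test_uniform_single_bases(self):
        prof = gp.kmer_profile(_genome("ACGT"), 1)
        assert np.allclose(prof.freq, [0.25, 0.25, 0.25, 0.25])

    def test_windows_with_n_skipped(self):
        # "ACGNA": windows AC, CG counted; GN, NA skipped
        prof = gp.kmer_profile(_genome("ACGNA"), 2)
        idx_ac = 0 * 4 + 1
        idx_cg = 1 * 4 + 2
        assert prof.freq[idx_ac] == pytest.approx(0.5)
        assert prof.freq[idx_cg] == pytest.approx(0.5)
        assert prof.freq.sum() == pytest.approx(1.0)

    def test_canonical_profile_is_strand_symmetric(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 500))
        from phagetf.simulate import revcomp

        fwd = gp.kmer_profile(_genome(seq), 4, canonical=True)
        rev = gp.kmer_profile(_genome(revcomp(seq)), 4, canonical=True)
        assert np.allclose(fwd.freq, rev.freq)

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError):
            gp.kmer_profile(_genome("ACG"), 4)


class TestJSD:
    def test_identity_is_zero(self):
        p = _profile("a", [0.3, 0.2, 0.4, 0.1])
        assert gp.jsd(p, p) == 0.0

    def test_disjoint_supports_reach_one_bit(self):
        p = _profile("a", [1, 0, 0, 0])
        q = _profile("b", [0, 1, 0, 0])
        assert gp.jsd(p, q) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        p = _profile("a", [1.0, 0.0])
        q = _profile("b", [0.5, 0.5])
        assert gp.jsd(p, q) == pytest.approx(0.311278, abs=1e-5)

    def test_matches_scipy_on_random_profiles(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.dirichlet(np.ones(16))
            q = rng.dirichlet(np.ones(16))
            mine = gp.jsd(_profile("a", p), _profile("b", q))
            ref = jensenshannon(p, q, base=2) ** 2
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            gp.jsd(_profile("a", [1, 0, 0, 0], k=1),
                   _profile("b", np.ones(16) / 16, k=2))


class TestJSDMatrix:
    def test_identical_genomes_give_zero_matrix(self):
        g = _genome("ACGTACGTACGT" * 10)
        profs = [gp.kmer_profile(
            GenomeRecord(genome_id=f"g{i}", sequence=g.sequence), 3)
            for i in range(3)]
        dm = gp.jsd_matrix(profs)
        assert np.allclose(dm.d, 0.0)

    def test_entries_match_pairwise_calls_and_symmetry(self):
        rng = np.random.default_rng(3)
        genomes = [
            _genome("".join(rng.choice(list("ACGT"), 300)), f"g{i}")
            for i in range(4)
        ]
        profs = [gp.kmer_profile(g, 3) for g in genomes]
        dm = gp.jsd_matrix(profs, sqrt=False)
        for i in range(4):
            for j in range(4):
                expected = 0.0 if i == j else gp.jsd(profs[i], profs[j])
                assert dm.d[i, j] == pytest.approx(expected)
        assert np.array_equal(dm.d, dm.d.T)
        dm_sqrt = gp.jsd_matrix(profs)  # metric form is the default
        assert np.allclose(dm_sqrt.d, np.sqrt(dm.d))

    def test_duplicate_labels_rejected(self):
        p = gp.kmer_profile(_genome("ACGTACGT", "x"), 2)
        with pytest.raises(ValueError):
            gp.jsd_matrix([p, p, p])


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        dm = gp.DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        tree = gp.neighbor_joining(dm)
        lens = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lens["A"] == pytest.approx(1.0)
        assert lens["B"] == pytest.approx(1.0)
        assert lens["C"] == pytest.approx(3.0)

    def test_additive_five_taxon_recovery(self, rng):
        from conftest import random_additive_tree

        true_tree, labels, dist = random_additive_tree(5, rng)
        dm = gp.DistanceMatrix(labels, dist)
        est = gp.neighbor_joining(dm)
        est2 = dendropy.Tree.get(
            data=est.as_string(schema="newick"), schema="newick",
            taxon_namespace=true_tree.taxon_namespace,
        )
        assert treecompare.symmetric_difference(true_tree, est2) == 0
        pdm = est.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in est.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        dist[i, j], abs=1e-9
                    )

    def test_equal_distances_give_equal_external_branches(self):
        n = 4
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = gp.neighbor_joining(gp.DistanceMatrix(list("ABCD"), d))
        ext = [lf.edge.length for lf in tree.leaf_node_iter()]
        assert np.allclose(ext, ext[0])
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0

    def test_invalid_matrices_rejected(self):
        bad = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            gp.neighbor_joining(gp.DistanceMatrix(["A", "B"], bad))
        asym = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            gp.DistanceMatrix(["A", "B", "C"], asym)
        neg = np.array([[0.0, -1.0, 2.0], [-1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            gp.DistanceMatrix(["A", "B", "C"], neg)

    def test_agrees_with_dendropy_nj_topology(self, rng):
        from conftest import random_additive_tree

        for n in (6, 9):
            true_tree, labels, dist = random_additive_tree(n, rng)
            mine = gp.neighbor_joining(gp.DistanceMatrix(labels, dist))
            csv = "," + ",".join(labels) + "\n" + "\n".join(
                labels[i] + "," + ",".join(str(dist[i, j]) for j in range(n))
                for i in range(n)
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=__import__("io").StringIO(csv),
                taxon_namespace=true_tree.taxon_namespace,
            )
            ref = pdm.nj_tree()
            mine2 = dendropy.Tree.get(
                data=mine.as_string(schema="newick"), schema="newick",
                taxon_namespace=true_tree.taxon_namespace,
            )
            assert treecompare.symmetric_difference(mine2, ref) == 0


class TestClusterConcordance:
    def _meta(self, mapping):
        import pandas as pd

        return pd.DataFrame(
            {"genome_id": list(mapping), "cluster": list(mapping.values())}
        )

    def test_concordant_clusters(self):
        tree = dendropy.Tree.get(
            data="((a1:1,a2:1):1,(b1:1,b2:1):1);", schema="newick"
        )
        rep = gp.cluster_concordance(
            tree, self._meta({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        )
        assert rep["A"] and rep["B"]
        assert rep["fraction"] == 1.0

    def test_interleaved_clusters(self):
        tree = dendropy.Tree.get(
            data="((a1:1,b1:1):1,(a2:1,b2:1):1);", schema="newick"
        )
        rep = gp.cluster_concordance(
            tree, self._meta({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        )
        assert not rep["A"] and not rep["B"]
        assert rep["fraction"] == 0.0

    def test_matches_brute_force_bipartitions(self, rng):
        from conftest import random_additive_tree
        from oracles import bipartition_sides_oracle

        tree, labels, _ = random_additive_tree(12, rng)
        sides = bipartition_sides_oracle(tree)
        # every 2-subset: concordant iff it is an edge side
        import itertools

        for pair in itertools.combinations(labels[:6], 2):
            meta = self._meta(
                {l: ("X" if l in pair else f"s{l}") for l in labels}
            )
            rep = gp.cluster_concordance(tree, meta)
            assert rep["X"] == (frozenset(pair) in sides)
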
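import math
import subprocess
import textwrap

import dendropy
import numpy as np
import pytest

from locusadmix.disttree import (
    DistanceMatrix,
    PairCounts,
    base_frequencies,
    distance_matrix,
    f84_distance,
    nj_build,
    pair_counts,
    path_distance_matrix,
    read_newick,
    tree_bipartitions,
    write_newick,
)
from locusadmix.errors import DataError
from locusadmix.seqio import LocusAlignment

EQ = np.array([0.25, 0.25, 0.25, 0.25])


def _aln(seqs):
    return LocusAlignment("L", [f"s{i}" for i in range(len(seqs))], seqs)


class TestBaseFrequencies:
    @pytest.mark.parametrize("seqs,expected", [
        (["AC", "GT"], [0.25, 0.25, 0.25, 0.25]),
        (["AA", "AA"], [1, 0, 0, 0]),
        (["AACG", "AACN"], [4 / 7, 2 / 7, 1 / 7, 0]),
    ])
    def test_pooled_over_all_sequences(self, seqs, expected):
        np.testing.assert_allclose(base_frequencies(_aln(seqs)), expected)

    def test_no_unambiguous_bases_is_error(self):
        with pytest.raises(DataError, match="unambiguous"):
            base_frequencies(_aln(["NN-", "N--"]))


class TestPairCounts:
    @pytest.mark.parametrize("s1,s2,n,P,Q", [
        ("AAAA", "AAAA", 4, 0.0, 0.0),
        ("AG", "GG", 2, 0.5, 0.0),          # A<->G is a transition
        ("ACGT", "ACCA", 4, 0.0, 0.5),      # G->C, T->A transversions
        ("CT", "TC", 2, 1.0, 0.0),
    ])
    def test_transition_transversion_split(self, s1, s2, n, P, Q):
        pc = pair_counts(s1, s2)
        assert (pc.n, pc.P, pc.Q) == (n, P, Q)

    def test_missing_sites_excluded(self):
        pc = pair_counts("ACGN", "A-GT")
        assert pc.n == 2 and pc.P == 0.0 and pc.Q == 0.0

    def test_global_mask_removes_columns_for_all_pairs(self):
        mask = np.array([True, False, False, False])
        pc = pair_counts("GCGT", "ACGT", deletion="global", global_mask=mask)
        assert pc.n == 3 and pc.P == 0.0

    def test_zero_comparable_sites_is_error(self):
        with pytest.raises(DataError, match="comparable"):
            pair_counts("NN", "AC")

    def test_unequal_lengths_is_error(self):
        with pytest.raises(DataError):
            pair_counts("AAA", "AA")


class TestF84:
    def test_zero_at_identity(self):
        assert f84_distance(PairCounts(4, 0.0, 0.0),
                            np.array([0.3, 0.2, 0.3, 0.2])) == 0.0

    def test_reduces_to_k80_at_equal_frequencies(self):
        for P in np.linspace(0.0, 0.25, 6):
            for Q in np.linspace(0.0, 0.2, 5):
                d = f84_distance(PairCounts(100, P, Q), EQ)
                k80 = (-0.5 * math.log(1 - 2 * P - Q)
                       - 0.25 * math.log(1 - 2 * Q))
                assert d == pytest.approx(k80, abs=1e-12)

    def test_monotone_in_transitions(self):
        freqs = np.array([0.35, 0.15, 0.25, 0.25])
        ds = [f84_distance(PairCounts(100, P, 0.05), freqs)
              for P in np.linspace(0, 0.3, 10)]
        assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_saturation_is_invalid_not_exception(self):
        d = f84_distance(PairCounts(100, 0.7, 0.3), EQ)
        assert math.isnan(d)

    def test_missing_purines_is_error(self):
        with pytest.raises(DataError, match="purine|pyrimidine"):
            f84_distance(PairCounts(4, 0.0, 0.1), np.array([0, 0.5, 0, 0.5]))


class TestDistanceMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        dm = distance_matrix(_aln(["ACGT", "ACGT", "ACGT"]))
        np.testing.assert_array_equal(dm.d, np.zeros((3, 3)))
        assert dm.fully_valid

    @staticmethod
    def _related_seqs(rng, n, L, rate, n_mask=0):
        anc = rng.integers(0, 4, L)
        seqs = []
        for _ in range(n):
            s = anc.copy()
            hit = rng.random(L) < rate
            s[hit] = (s[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
            seqs.append(list("ACGT"[b] for b in s))
        for _ in range(n_mask):
            seqs[rng.integers(n)][rng.integers(L)] = "N"
        return ["".join(s) for s in seqs]

    def test_matches_per_pair_brute_force(self):
        rng = np.random.default_rng(7)
        seqs = self._related_seqs(rng, 5, 80, 0.15, n_mask=6)
        aln = _aln(seqs)
        dm = distance_matrix(aln, deletion="global")
        freqs = base_frequencies(aln)
        mask = np.array([any(c not in "ACGT" for c in col)
                         for col in zip(*seqs)])
        for i in range(5):
            for j in range(i + 1, 5):
                pc = pair_counts(seqs[i], seqs[j], deletion="global",
                                 global_mask=mask)
                assert dm.d[i, j] == pytest.approx(
                    f84_distance(pc, freqs), abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        seqs = self._related_seqs(rng, 4, 60, 0.1)
        aln = _aln(seqs)
        dm = distance_matrix(aln)
        perm = [2, 0, 3, 1]
        aln2 = LocusAlignment("L", [aln.strains[i] for i in perm],
                              [seqs[i] for i in perm])
        dm2 = distance_matrix(aln2)
        np.testing.assert_allclose(dm2.d, dm.d[np.ix_(perm, perm)], atol=1e-14)
        assert (dm.d == dm.d.T).all()

    def test_agrees_with_ape_dist_dna(self, tmp_path):
        """Independent oracle: ape's dist.dna (model F84, complete deletion)."""
        rng = np.random.default_rng(42)
        anc = rng.integers(0, 4, 120)
        rows = []
        for _ in range(6):
            s = anc.copy()
            hit = rng.random(120) < 0.15
            s[hit] = (s[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
            rows.append(s)
        chars = [list("ACGT"[b] for b in s) for s in rows]
        chars[0][5] = "N"
        chars[2][50] = "-"
        chars[4][100] = "N"
        seqs = ["".join(c) for c in chars]
        fa = tmp_path / "t.fa"
        fa.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))
        script = textwrap.dedent(f"""
            library(ape)
            x <- read.dna('{fa}', format='fasta')
            d <- as.matrix(dist.dna(x, model='F84', pairwise.deletion=FALSE))
            cat(sprintf('%.12f', d[upper.tri(d)]), sep='\\n')
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ape_vals = np.array([float(v) for v in out.stdout.split()])
        dm = distance_matrix(_aln(seqs), deletion="global")
        mine = dm.d[np.triu_indices(6, 1)]
        # R fills upper.tri column-by-column, same order as row-major triu
        np.testing.assert_allclose(np.sort(mine), np.sort(ape_vals), atol=1e-9)


def _random_binary_tree(n_tips, rng):
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=rng)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = 0.05 + rng.random() * 0.5
    return tree


class TestNeighborJoining:
    def test_recovers_hand_built_additive_5_tip_tree(self):
        # ((A:0.1,B:0.2):0.15,(C:0.3,D:0.1):0.05,E:0.4)
        tree = read_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.1):0.05,E:0.4);")
        dm = path_distance_matrix(tree)
        out = nj_build(dm)
        assert tree_bipartitions(out) == tree_bipartitions(tree)
        # branch lengths recovered exactly on additive input
        for leaf, expect in [("A", 0.1), ("B", 0.2), ("C", 0.3), ("D", 0.1)]:
            nd = [l for l in out.leaf_node_iter() if l.taxon.label == leaf][0]
            assert nd.edge.length == pytest.approx(expect, abs=1e-12)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]])
        dm = DistanceMatrix(["a", "b", "c"], d, np.ones((3, 3), bool))
        tree = nj_build(dm)
        lengths = {l.taxon.label: l.edge.length
                   for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.4))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.4 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.4 - 0.3))

    def test_deterministic_on_ties(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("abcd"), d, np.ones((4, 4), bool))
        s1 = write_newick(nj_build(dm))
        s2 = write_newick(nj_build(dm))
        assert s1 == s2

    @pytest.mark.parametrize("n_tips", [4, 5, 6, 7, 8])
    def test_consistency_on_random_additive_trees(self, n_tips):
        rng = np.random.default_rng(100 + n_tips)
        import random
        pyrng = random.Random(n_tips)
        for rep in range(8):
            tree = _random_binary_tree(n_tips, pyrng)
            for edge in tree.preorder_edge_iter():
                if edge.head_node.parent_node is not None:
                    edge.length = 0.05 + rng.random() * 0.5
            dm = path_distance_matrix(tree)
            out = nj_build(dm)
            assert tree_bipartitions(out) == tree_bipartitions(tree)

    def test_matches_dendropy_nj_topology(self):
        """Cross-check against dendropy's independent NJ implementation."""
        rng = np.random.default_rng(19)
        import random
        tree = _random_binary_tree(7, random.Random(5))
        dm = path_distance_matrix(tree)
        noise = rng.normal(0, 0.002, dm.d.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        dm.d = np.abs(dm.d + noise)
        out = nj_build(dm)

        csv = "," + ",".join(dm.labels) + "\n"
        for lab, row in zip(dm.labels, dm.d):
            csv += lab + "," + ",".join(str(v) for v in row) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv))
        ddt = pdm.nj_tree()
        assert tree_bipartitions(out) == tree_bipartitions(ddt)

    def test_invalid_entries_abort(self):
        d = np.zeros((3, 3))
        valid = np.ones((3, 3), bool)
        valid[0, 1] = valid[1, 0] = False
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(DataError, match="invalid"):
            nj_build(DistanceMatrix(list("abc"), d, valid))


class TestNewick:
    def test_support_label_parsed(self):
        tree = read_newick("(A:1,B:1,(C:1,D:1)95:0.5);")
        supported = [nd for nd in tree.preorder_node_iter()
                     if getattr(nd, "support", None) is not None]
        assert len(supported) == 1
        tips = {l.taxon.label for l in supported[0].leaf_iter()}
        assert tips == {"C", "D"} and supported[0].support == 95

    def test_round_trip_preserves_topology_lengths_support(self):
        s = "(A:1,B:1,(C:1.25,D:0.3333333333)95:0.5);"
        t1 = read_newick(s)
        t2 = read_newick(write_newick(t1))
        assert tree_bipartitions(t1) == tree_bipartitions(t2)
        l1 = sorted(l.edge.length for l in t1.leaf_node_iter())
        l2 = sorted(l.edge.length for l in t2.leaf_node_iter())
        np.testing.assert_allclose(l1, l2, rtol=1e-9)
        sup = [nd.support for nd in t2.preorder_node_iter()
               if getattr(nd, "support", None) is not None]
        assert sup == [95]

    def test_negative_branch_round_trips(self):
        t = read_newick("(A:-0.01,B:1,(C:1,D:1):0.5);")
        t2 = read_newick(write_newick(t))
        assert min(l.edge.length for l in t2.leaf_node_iter()) == pytest.approx(-0.01)

    def test_malformed_newick_raises(self):
        with pytest.raises(DataError, match="malformed"):
            read_newick("(A:1,B:1,(C:1,D:1;")
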
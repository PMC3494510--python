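import numpy as np
import pytest

from xenoscreen.errors import DataError
from xenoscreen.io_formats import SequenceRecord
from xenoscreen.msa import Alignment
from xenoscreen.tree_inference import (
    MAX_DISTANCE,
    DistanceMatrix,
    bootstrap_trees,
    kimura_distance,
    majority_consensus,
    map_support,
    nj_tree,
    protein_distance,
)
from xenoscreen.trees import SupportTree

from oracles import graph_splits, random_tree_newick


def _aln(rows):
    return Alignment([SequenceRecord(f"t{i}", s) for i, s in enumerate(rows)])


class TestProteinDistance:
    def test_identical_rows_zero(self):
        dm = protein_distance(_aln(["MKVLA", "MKVLA", "MKVLA"]))
        assert np.all(dm.d == 0)

    def test_kimura_point_value(self):
        # p = 0.2 -> -ln(1 - 0.2 - 0.008)
        assert kimura_distance(0.2) == pytest.approx(-np.log(0.792), abs=1e-10)

    def test_saturation_capped(self):
        # the argument 1 - p - p^2/5 hits zero at p ~= 0.8541
        assert kimura_distance(0.8542) == MAX_DISTANCE
        assert kimura_distance(0.99) == MAX_DISTANCE
        assert kimura_distance(0.85) < MAX_DISTANCE  # just below saturation

    def test_gaps_excluded_from_p(self):
        # pair shares 4 ungapped columns, 1 mismatch -> p = 0.25
        dm = protein_distance(_aln(["MKVLA", "MKW-A", "MKVLA"]))
        i, j = 0, 1
        assert dm.d[i, j] == pytest.approx(kimura_distance(0.25))

    def test_no_comparable_columns_errors(self):
        with pytest.raises(DataError, match="ungapped"):
            protein_distance(_aln(["M-", "-M", "MM"]))


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = nj_tree(dm)
        D = tree.path_distance_matrix(["A", "B", "C"])
        # branches a=1, b=1, c=3
        assert D[0, 1] == pytest.approx(2)
        assert D[0, 2] == pytest.approx(4)
        assert D[1, 2] == pytest.approx(4)

    def test_fewer_than_three_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(DataError):
            nj_tree(dm)

    @pytest.mark.parametrize("n_taxa,seed", [(6, 0), (8, 1), (10, 2)])
    def test_additive_matrix_recovery(self, n_taxa, seed):
        """NJ is consistent: additive inputs give back tree and path lengths."""
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(n_taxa)]
        gen = SupportTree.from_newick(random_tree_newick(labels, rng))
        D = gen.path_distance_matrix(labels)
        rec = nj_tree(DistanceMatrix(labels, D))
        assert set(graph_splits(rec)) == set(graph_splits(gen))
        D2 = rec.path_distance_matrix(labels)
        assert np.abs(D - D2).max() <= 1e-9

    def test_label_order_invariance(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(7)]
        gen = SupportTree.from_newick(random_tree_newick(labels, rng))
        D = gen.path_distance_matrix(labels)
        t1 = nj_tree(DistanceMatrix(labels, D))
        perm = [3, 0, 6, 2, 5, 1, 4]
        labels_p = [labels[i] for i in perm]
        Dp = D[np.ix_(perm, perm)]
        t2 = nj_tree(DistanceMatrix(labels_p, Dp))
        assert set(graph_splits(t1)) == set(graph_splits(t2))

    def test_negative_estimates_clamped(self):
        # a matrix engineered to give a negative NJ branch estimate
        d = np.array(
            [[0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 1], [6, 6, 1, 0]], float
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        for node in tree.tree.preorder_node_iter():
            if node.edge.length is not None:
                assert node.edge.length >= 0


class TestBootstrap:
    def test_exactly_n_reps(self):
        rows = ["MKVLAWYHDE" * 3, "MKVLAWYHDG" * 3, "MKVAAWYHDE" * 3, "MKWLAWYHDE" * 3]
        reps = bootstrap_trees(_aln(rows), n_reps=100, seed=5)
        assert len(reps) == 100

    def test_deterministic_under_seed(self):
        rows = ["MKVLAWYHDE" * 3, "MKVLAWYHDG" * 3, "MKVAAWYHDE" * 3, "MKWLAWYHDE" * 3]
        r1 = bootstrap_trees(_aln(rows), n_reps=10, seed=42)
        r2 = bootstrap_trees(_aln(rows), n_reps=10, seed=42)
        assert [t.to_newick() for t in r1] == [t.to_newick() for t in r2]

    def test_identical_rows_degenerate_ok(self):
        rows = ["MKVLA" * 4] * 4
        reps = bootstrap_trees(_aln(rows), n_reps=5, seed=1)
        assert len(reps) == 5
        for t in reps:
            for node in t.tree.preorder_node_iter():
                assert not node.edge.length or node.edge.length == 0


class TestMapSupport:
    def _forest(self, newicks):
        return [SupportTree.from_newick(s) for s in newicks]

    def test_all_identical_gives_100(self):
        best = SupportTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        reps = self._forest(["((a:1,b:1):1,(c:1,d:1):1);"] * 10)
        ann = map_support(best, reps)
        sups = [s.support for s in ann.splits()]
        assert sups == [100]

    def test_fractional_count(self):
        best = SupportTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        reps = self._forest(
            ["((a:1,b:1):1,(c:1,d:1):1);"] * 73 + ["((a:1,c:1):1,(b:1,d:1):1);"] * 27
        )
        ann = map_support(best, reps)
        assert [s.support for s in ann.splits()] == [73]

    def test_leaf_set_mismatch(self):
        best = SupportTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        reps = self._forest(["((a:1,b:1):1,(c:1,e:1):1);"])
        with pytest.raises(DataError):
            map_support(best, reps)

    def test_matches_brute_force_counter(self, rng):
        """Supports equal an independent graph-split counting oracle."""
        labels = [f"t{i}" for i in range(8)]
        best = SupportTree.from_newick(random_tree_newick(labels, rng))
        reps = [
            SupportTree.from_newick(random_tree_newick(labels, rng)) for _ in range(40)
        ]
        ann = map_support(best, reps)
        rep_splitsets = [set(graph_splits(t)) for t in reps]
        for split in ann.splits():
            count = sum(split.side in ss for ss in rep_splitsets)
            assert split.support == int(np.floor(100 * count / 40 + 0.5))

    def test_deep_clades_strongly_supported(self):
        """Structured alignment: true clades get near-perfect support."""
        from xenoscreen.synthetic_data import (
            SimulationConfig,
            evolve_family,
            simulate_species_tree,
            states_to_record,
        )

        cfg = SimulationConfig(
            n_donor_taxa=3, n_recipient_taxa=3, n_close_taxa=2, n_other_taxa=2,
            seq_len=500,
        )
        sp = simulate_species_tree(cfg)
        seqs = evolve_family(sp, cfg.seq_len, seed=8)
        aln = Alignment([states_to_record(k, v) for k, v in sorted(seqs.items())])
        best = nj_tree(protein_distance(aln))
        reps = bootstrap_trees(aln, n_reps=100, seed=8,
                               taxon_namespace=best.tree.taxon_namespace)
        ann = map_support(best, reps)
        sup_of = {s.side: s.support for s in ann.splits()}
        norm = ann.normalise
        for clade in (cfg.donor_taxa, cfg.recipient_taxa):
            side = norm(frozenset(clade))
            assert side in sup_of and sup_of[side] >= 95

    def test_consensus_contains_majority_splits(self):
        reps = self._forest(
            ["((a:1,b:1):1,(c:1,d:1):1);"] * 8 + ["((a:1,c:1):1,(b:1,d:1):1);"] * 2
        )
        cons = majority_consensus(reps)
        norm = cons.normalise
        assert norm(frozenset({"a", "b"})) in cons.split_set()
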
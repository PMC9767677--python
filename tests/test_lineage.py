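"""Burden profiles, mutation matrices, binary distance, NJ and bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import scmutcall as sm
from conftest import (
    enumerate_unrooted_topologies,
    ls_error,
    random_additive_tree,
)


def _call(pos, carriers, patient="P1", gene=None):
    ann = sm.AnnotatedCandidate(
        locus=sm.GenomicLocus("chr1", pos, "C", "T"), patient_id=patient,
        carrier_cells=frozenset(carriers), tri_context="ACA", gene=gene,
    )
    stats = sm.EnrichmentStats("lineage", "x", len(carriers), 0, 0, 50,
                               1e-9, math.inf)
    return sm.MutationCall(annotated=ann, stats=stats)


class TestBurden:
    def _cells(self, n, lineage="tumor", patient="P1"):
        return [sm.CellRecord(f"{lineage}{i}", patient, lineage, "s")
                for i in range(n)]

    def test_proportions_arithmetic(self):
        cells = self._cells(150)
        calls = []
        pos = 100
        # 30 cells carry 1 mutation (one shared call of 30 carriers)
        calls.append(_call(pos, [f"tumor{i}" for i in range(30, 60)]))
        # 10 cells carry 2
        for _ in range(2):
            pos += 10
            calls.append(_call(pos, [f"tumor{i}" for i in range(60, 70)]))
        # 5 cells carry 5 (the >3 bin)
        for _ in range(5):
            pos += 10
            calls.append(_call(pos, [f"tumor{i}" for i in range(70, 75)]))
        prof = sm.burden_profile(calls, cells)
        row = prof.iloc[0]
        assert row.n_cells == 150
        assert row.prop_1 == pytest.approx(0.2)
        assert row.prop_2 == pytest.approx(10 / 150)
        assert row.prop_3 == 0.0
        assert row.prop_gt3 == pytest.approx(5 / 150)

    def test_small_groups_excluded(self):
        cells = self._cells(80) + self._cells(120, lineage="myeloid")
        prof = sm.burden_profile([], cells)
        assert list(prof.lineage) == ["myeloid"]

    def test_proportions_sum_to_one_with_zero_bin(self, default_sim,
                                                  default_result):
        prof = sm.burden_profile(default_result.passed, default_sim.cells)
        total = prof.prop_0 + prof.prop_1 + prof.prop_2 + prof.prop_3 + prof.prop_gt3
        assert np.allclose(total, 1.0)


class TestMutationMatrix:
    def _cells(self):
        return [sm.CellRecord(f"c{i}", "P1", "myeloid", f"s{i % 3}")
                for i in range(9)]

    def test_presence_and_exclusions(self):
        cells = self._cells()
        calls = [
            _call(100, ["c0", "c3"], gene="GDEG"),   # excluded: DEG gene
            _call(200, ["c0"]),                        # subtype s0 only
            _call(300, ["c1", "c2", "c4"]),           # s1 + s2
            _call(400, ["zz"]),                        # carriers outside cells
        ]
        matrix, excluded = sm.build_mutation_matrix(
            calls, cells, {"s0": ["GDEG", "OTHER"]})
        assert list(matrix.columns) == ["s0", "s1", "s2"]
        assert matrix.loc["P1:chr1:200C>T"].tolist() == [1, 0, 0]
        assert matrix.loc["P1:chr1:300C>T"].tolist() == [0, 1, 1]
        assert "P1:chr1:100C>T" in excluded and "P1:chr1:400C>T" in excluded
        assert len(matrix) == 2

    def test_min_carrier_threshold(self):
        cells = self._cells()
        calls = [_call(100, ["c0", "c1"])]  # one carrier in s0, one in s1
        m1, _ = sm.build_mutation_matrix(calls, cells)
        m2, _ = sm.build_mutation_matrix(calls, cells, min_carriers=2)
        assert m1.loc["P1:chr1:100C>T"].sum() == 2
        assert len(m2) == 0

    def test_toy_count(self):
        cells = self._cells()
        calls = ([_call(100 + i * 10, [f"c{i % 9}"]) for i in range(8)]
                 + [_call(500, ["c0"], gene="GD1"), _call(600, ["c1"], gene="GD2")])
        matrix, excluded = sm.build_mutation_matrix(
            calls, cells, {"any": ["GD1", "GD2"]})
        assert len(matrix) == 8 and len(excluded) == 2


class TestBinaryDistance:
    def _matrix(self, cols):
        muts = sorted({m for s in cols.values() for m in s})
        return pd.DataFrame(
            {c: [int(m in cols[c]) for m in muts] for c in cols}, index=muts)

    def test_hand_enumeration(self):
        d = sm.binary_distance(self._matrix(
            {"a": {"m1", "m2", "m3"}, "b": {"m2", "m3", "m4"}}))
        assert d.loc["a", "b"] == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        d = sm.binary_distance(self._matrix(
            {"a": {"m1"}, "b": {"m1"}, "c": {"m2"}}))
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0

    def test_empty_union_is_zero(self):
        m = pd.DataFrame({"a": [1, 0], "b": [0, 0], "c": [0, 0]})
        d = sm.binary_distance(m)
        assert d.loc["b", "c"] == 0.0

    @given(st.integers(0, 2 ** 30 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.integers(0, 2, size=(12, 5)),
                         columns=list("abcde"))
        d = sm.binary_distance(m).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestNeighborJoining:
    def test_four_taxon_split_recovery(self):
        # additive distances from ((A,B),(C,D)): d(A,B)=d(C,D)=2, cross=4
        labels = list("ABCD")
        arr = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
                       dtype=float)
        tree = sm.nj_tree(pd.DataFrame(arr, index=labels, columns=labels))
        assert tree.has_split({"A", "B"})
        assert not tree.has_split({"A", "C"})

    def test_fewer_than_three_taxa_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(sm.ValidationError):
            sm.nj_tree(d)

    def test_degenerate_equal_distances_deterministic(self):
        labels = list("ABCDE")
        d = pd.DataFrame(1.0 - np.eye(5), index=labels, columns=labels)
        t1 = sm.nj_tree(d)
        t2 = sm.nj_tree(d)
        assert t1.newick == t2.newick

    def test_negative_branch_lengths_clamped_and_flagged(self):
        labels = list("ABCD")
        # non-additive distances known to drive one NJ branch negative
        arr = np.array([
            [0.0, 1.725, 1.28, 0.71],
            [1.725, 0.0, 1.175, 0.435],
            [1.28, 1.175, 0.0, 0.235],
            [0.71, 0.435, 0.235, 0.0],
        ])
        tree = sm.nj_tree(pd.DataFrame(arr, index=labels, columns=labels))
        assert tree.n_clamped >= 1
        assert all(v >= 0 for v in tree.bipartitions.values())

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_topology_recovery(self, n_taxa):
        rng = np.random.default_rng(1000 + n_taxa)
        for _ in range(5):
            dist, splits = random_additive_tree(n_taxa, rng)
            tree = sm.nj_tree(dist)
            assert set(tree.bipartitions) == splits

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_exhaustive_least_squares_agreement(self, n_taxa):
        """NJ picks the same topology as exhaustive least-squares search."""
        topologies = enumerate_unrooted_topologies(
            [f"t{i}" for i in range(n_taxa)])
        rng = np.random.default_rng(77 + n_taxa)
        for _ in range(5):
            dist, _ = random_additive_tree(n_taxa, rng)
            errors = {t: ls_error(dist, t) for t in topologies}
            best = min(errors, key=errors.get)
            tree = sm.nj_tree(dist)
            assert frozenset(tree.bipartitions) == best

    def test_agrees_with_skbio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        for _ in range(5):
            dist, _ = random_additive_tree(6, rng)
            # path sums accumulate in different orders for (i,j) vs (j,i);
            # symmetrize exactly for skbio's strict checker
            arr = dist.to_numpy()
            arr = (arr + arr.T) / 2.0
            dist = pd.DataFrame(arr, index=dist.index, columns=dist.columns)
            ours = sm.nj_tree(dist)
            theirs = skbio_nj(DistanceMatrix(arr, ids=list(dist.index)))
            leaves = frozenset(dist.index)
            first = min(leaves)
            their_splits = set()
            for node in theirs.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= len(leaves) - 2:
                    their_splits.add(leaves - side if first in side else side)
            assert set(ours.bipartitions) == their_splits


class TestBootstrap:
    def _two_clade_matrix(self, n_muts=6):
        # two clades with disjoint mutation blocks: every resample that
        # contains any row at all preserves both splits
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        rows = {}
        for i in range(n_muts):
            rows[f"mA{i}"] = [1, 1, 1, 0, 0, 0]
            rows[f"mB{i}"] = [0, 0, 0, 1, 1, 1]
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    def test_concordant_blocks_full_support(self):
        tree = sm.bootstrap_support(self._two_clade_matrix(), n_reps=100, seed=3)
        assert tree.supports and all(v == 100 for v in tree.supports.values())

    def test_fixed_seed_reproducible(self, default_sim, default_result):
        mye = [c for c in default_sim.cells if c.lineage == "myeloid"]
        matrix, _ = sm.build_mutation_matrix(
            default_result.passed, mye, default_sim.masks.deg_genes_by_cluster)
        t1 = sm.bootstrap_support(matrix, n_reps=50, seed=17)
        t2 = sm.bootstrap_support(matrix, n_reps=50, seed=17)
        assert t1.supports == t2.supports and t1.newick == t2.newick

    def test_row_permutation_invariance(self):
        m = self._two_clade_matrix()
        perm = m.iloc[np.random.default_rng(5).permutation(len(m))]
        t1 = sm.bootstrap_support(m, n_reps=40, seed=11)
        t2 = sm.bootstrap_support(perm, n_reps=40, seed=11)
        assert t1.supports == t2.supports

    def test_single_row_replicates_identical(self):
        m = pd.DataFrame({"a": [1], "b": [0], "c": [1], "d": [0]}, index=["m"])
        tree = sm.bootstrap_support(m, n_reps=20, seed=2)
        # every resample of one row is that row: all replicate trees equal
        # the base tree, so each support is either 0 or the replicate count
        assert all(v in (0, 20) for v in tree.supports.values())

    def test_newick_contains_supports(self):
        tree = sm.bootstrap_support(self._two_clade_matrix(), n_reps=10, seed=1)
        assert ")10:" in tree.newick
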
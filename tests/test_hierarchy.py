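"""Dendrogram construction, tree cutting and unique-module enumeration,
cross-checked against a naive agglomeration/enumeration oracle."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import connectocca as cc
from connectocca.hierarchy import restrict_catalog

from conftest import random_symmetric_fc, random_symmetric_sc
from oracles import correlation_distance_matrix, naive_average_linkage, naive_unique_modules


def _two_pair_matrices(r_a=0.9, r_b=0.7, r_cross=-0.8):
    """4 nodes: two internally-correlated pairs, anticorrelated across pairs."""
    s = np.array([1, 1, -1, -1], dtype=float)
    fc = np.outer(s, s) * 0.8
    fc[0, 1] = fc[1, 0] = r_a
    fc[2, 3] = fc[3, 2] = r_b
    np.fill_diagonal(fc, 1.0)
    sc = np.zeros((4, 4))
    return fc, sc


def _cluster_leafsets(dendro):
    """Leaf sets of every internal cluster of a linkage tree."""
    v = dendro.n_leaves
    members = {i: frozenset([i]) for i in range(v)}
    out = []
    for k, (a, b, _h) in enumerate(dendro.merge_list):
        members[v + k] = members[a] | members[b]
        out.append(members[v + k])
    return out


class TestBuildDendrogram:
    def test_identical_profiles_merge_first_at_zero_height(self, rng):
        v = 6
        fc = random_symmetric_fc(rng, v)
        sc = random_symmetric_sc(rng, v).astype(float)
        # duplicate node 1 onto node 0 (their mutual entries must agree too)
        fc[0, 1] = fc[1, 0] = 1.0
        sc[0, 1] = sc[1, 0] = 0.0
        for k in range(2, v):
            fc[1, k] = fc[k, 1] = fc[0, k]
            sc[1, k] = sc[k, 1] = sc[0, k]
        dendro = cc.build_dendrogram(fc, sc)
        a, b, h = dendro.merge_list[0]
        assert {a, b} == {0, 1}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pairs_merge_before_cross_pairs(self):
        # oracle: naive UPGMA on the hand-computed correlation-distance table
        fc, sc = _two_pair_matrices()
        dendro = cc.build_dendrogram(fc, sc)
        clusters = _cluster_leafsets(dendro)
        assert clusters[0] == frozenset({0, 1})
        assert clusters[1] == frozenset({2, 3})
        profiles = np.hstack([
            (fc - fc.mean()) / fc.std(),
            np.zeros_like(sc),  # constant sc contributes nothing
        ])
        merges = naive_average_linkage(correlation_distance_matrix(profiles))
        assert merges[0][0] | merges[0][1] == frozenset({0, 1})
        assert merges[1][0] | merges[1][1] == frozenset({2, 3})

    def test_permutation_equivariance(self, rng):
        v = 9
        fc = random_symmetric_fc(rng, v)
        sc = random_symmetric_sc(rng, v).astype(float)
        perm = rng.permutation(v)
        d1 = cc.build_dendrogram(fc, sc)
        d2 = cc.build_dendrogram(fc[np.ix_(perm, perm)], sc[np.ix_(perm, perm)])
        sets1 = {frozenset(s) for s in _cluster_leafsets(d1)}
        sets2 = {frozenset(int(perm[i]) for i in s) for s in _cluster_leafsets(d2)}
        assert sets1 == sets2

    def test_asymmetric_input_rejected(self, rng):
        fc = random_symmetric_fc(rng, 5)
        bad = fc.copy()
        bad[0, 1] += 0.2
        with pytest.raises(ValueError, match="symmetric"):
            cc.build_dendrogram(bad, np.zeros((5, 5)))

    def test_too_few_nodes_rejected(self):
        m = np.eye(2)
        with pytest.raises(ValueError, match="3 nodes"):
            cc.build_dendrogram(m, np.zeros((2, 2)))


class TestCut:
    def test_extreme_levels(self, rng):
        fc = random_symmetric_fc(rng, 7)
        sc = random_symmetric_sc(rng, 7).astype(float)
        dendro = cc.build_dendrogram(fc, sc)
        assert cc.cut(dendro, 7) == [(i,) for i in range(7)]
        assert cc.cut(dendro, 1) == [tuple(range(7))]
        with pytest.raises(ValueError):
            cc.cut(dendro, 0)
        with pytest.raises(ValueError):
            cc.cut(dendro, 8)

    def test_forced_two_module_cut(self):
        fc, sc = _two_pair_matrices()
        dendro = cc.build_dendrogram(fc, sc)
        assert cc.cut(dendro, 2) == [(0, 1), (2, 3)]

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_cuts_are_nested_refinements(self, seed):
        rng = np.random.default_rng(seed)
        v = int(rng.integers(5, 14))
        dendro = cc.build_dendrogram(random_symmetric_fc(rng, v),
                                     random_symmetric_sc(rng, v).astype(float))
        for m1 in range(1, v):
            part1 = cc.cut(dendro, m1)
            part2 = cc.cut(dendro, m1 + 1)
            for mod in part2:
                parents = [p for p in part1 if set(mod) <= set(p)]
                assert len(parents) == 1


class TestEnumerateUniqueModules:
    def test_single_level_catalog(self):
        fc, sc = _two_pair_matrices()
        dendro = cc.build_dendrogram(fc, sc)
        cat = cc.enumerate_unique_modules(dendro, cc.ScaleGrid(2, 2, 1))
        assert [m.nodes for m in cat.modules] == [(0, 1), (2, 3)]
        assert [m.scales for m in cat.modules] == [[2], [2]]

    def test_dedup_and_singleton_removal_across_levels(self):
        # levels 2,3,4: level 3 keeps {0,1} (the tighter pair) and splits the
        # rest; level 4 is all singletons
        fc, sc = _two_pair_matrices(r_a=0.9, r_b=0.7)
        dendro = cc.build_dendrogram(fc, sc)
        cat = cc.enumerate_unique_modules(dendro, cc.ScaleGrid(2, 4, 1))
        as_dict = {m.nodes: m.scales for m in cat.modules}
        assert as_dict == {(0, 1): [2, 3], (2, 3): [2]}

    def test_catalog_size_bounded_by_level_sum(self, rng):
        v = 12
        dendro = cc.build_dendrogram(random_symmetric_fc(rng, v),
                                     random_symmetric_sc(rng, v).astype(float))
        grid = cc.ScaleGrid(2, 12, 2)
        cat = cc.enumerate_unique_modules(dendro, grid)
        assert len(cat) <= sum(grid.levels)

    def test_grid_beyond_leaf_count_rejected(self, rng):
        dendro = cc.build_dendrogram(random_symmetric_fc(rng, 5),
                                     random_symmetric_sc(rng, 5).astype(float))
        with pytest.raises(ValueError, match="exceeds"):
            cc.enumerate_unique_modules(dendro, cc.ScaleGrid(2, 6, 1))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_catalog_matches_naive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        v = int(rng.integers(5, 13))
        fc = random_symmetric_fc(rng, v)
        sc = random_symmetric_sc(rng, v).astype(float)
        dendro = cc.build_dendrogram(fc, sc)
        grid = cc.ScaleGrid(2, v, 1)
        cat = cc.enumerate_unique_modules(dendro, grid)
        got = {frozenset(m.nodes): set(m.scales) for m in cat.modules}
        sc_t = np.log1p(sc)
        profiles = np.hstack([(fc - fc.mean()) / fc.std(),
                              (sc_t - sc_t.mean()) / sc_t.std()])
        expected = naive_unique_modules(profiles, grid.levels)
        assert got == expected


class TestScaleGrid:
    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            cc.ScaleGrid(1, 10, 1)
        with pytest.raises(ValueError):
            cc.ScaleGrid(2, 11, 2)  # span not divisible by step

    def test_capping_preserves_step_and_origin(self):
        g = cc.ScaleGrid(10, 100, 10).capped(47)
        assert (g.m_min, g.m_max, g.m_step) == (10, 40, 10)
        assert cc.ScaleGrid(10, 40, 10).capped(100) == cc.ScaleGrid(10, 40, 10)


class TestRestrictCatalog:
    def test_reindexing_dropping_and_merging(self):
        grid = cc.ScaleGrid(2, 4, 1)
        cat = cc.ModuleCatalog(modules=[
            cc.hierarchy.Module("mod_0000", (0, 1, 2, 3), [2]),
            cc.hierarchy.Module("mod_0001", (0, 1), [3]),
            cc.hierarchy.Module("mod_0002", (2, 3), [3]),
            cc.hierarchy.Module("mod_0003", (0, 1, 2), [4]),
        ], grid=grid)
        # drop node 3: {0,1,2,3} and {0,1,2} coincide and merge scales;
        # {2,3} shrinks to a singleton and is dropped
        out = restrict_catalog(cat, [0, 1, 2])
        assert {m.nodes: m.scales for m in out.modules} == {
            (0, 1, 2): [2, 4],
            (0, 1): [3],
        }
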
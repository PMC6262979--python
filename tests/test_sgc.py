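"""SGC detector: k-NN graph, DC-SBM model selection, spectral split, refinement."""

import math

import numpy as np
import pytest
from scipy.sparse import csr_matrix

import assemblybench as ab
from assemblybench.detectors.sgc import (
    CorePattern,
    DetectionEmpty,
    PatternGraph,
    build_knn_graph,
    cores_to_assemblies,
    dcsbm_description_length,
    infer_n_communities,
    refine_groups,
    spectral_split,
)


def _planted_patterns(rng, n_groups=4, per_group=30, n_neurons=80, noise=0.02):
    """Binary patterns from disjoint assemblies plus sparse noise."""
    pats = (rng.uniform(size=(n_groups * per_group, n_neurons)) < noise).astype(
        np.uint8
    )
    size = n_neurons // n_groups
    for g in range(n_groups):
        rows = slice(g * per_group, (g + 1) * per_group)
        pats[rows, g * size:(g + 1) * size] = 1
    return pats


def _two_cliques_graph(m=30):
    n = 2 * m
    a = np.zeros((n, n), dtype=np.int8)
    a[:m, :m] = 1
    a[m:, m:] = 1
    np.fill_diagonal(a, 0)
    a[0, m] = a[m, 0] = 1  # bridge
    return PatternGraph(adjacency=csr_matrix(a), k=m - 1)


class TestKnnGraph:
    def test_two_identical_patterns_single_edge(self):
        pats = np.array([[1, 1, 0], [1, 1, 0]], dtype=np.uint8)
        g = build_knn_graph(pats)
        assert g.adjacency.nnz == 2  # one undirected edge
        assert g.k == 1

    def test_initial_k_is_log_count(self, rng):
        pats = (rng.uniform(size=(100, 50)) < 0.3).astype(np.uint8)
        g = build_knn_graph(pats)
        assert g.k >= math.ceil(math.log(100))  # = 5, grown only if needed

    def test_k_grows_until_connected(self, rng):
        # two orthogonal blocks: mutual k-NN is disconnected until k
        # exceeds the block size
        pats = np.zeros((12, 20), dtype=np.uint8)
        pats[:6, :10] = (rng.uniform(size=(6, 10)) < 0.8)
        pats[6:, 10:] = (rng.uniform(size=(6, 10)) < 0.8)
        g = build_knn_graph(pats)
        from scipy.sparse.csgraph import connected_components

        assert connected_components(g.adjacency, directed=False)[0] == 1
        assert g.k >= 6

    def test_single_pattern_rejected(self):
        with pytest.raises(DetectionEmpty):
            build_knn_graph(np.ones((1, 5), dtype=np.uint8))


class TestCommunityCount:
    def test_two_cliques(self):
        assert infer_n_communities(_two_cliques_graph(), rng_seed=0) == 2

    def test_erdos_renyi_is_one_block(self, rng):
        n = 80
        a = (rng.uniform(size=(n, n)) < 0.15).astype(np.int8)
        a = np.triu(a, 1)
        a = a + a.T
        g = PatternGraph(adjacency=csr_matrix(a), k=0)
        assert infer_n_communities(g, rng_seed=1, n_restarts=5) == 1

    def test_planted_blocks_from_patterns(self, rng):
        pats = _planted_patterns(rng)
        g = build_knn_graph(pats)
        assert infer_n_communities(g, rng_seed=2) == 4

    def test_description_length_prefers_truth(self, rng):
        g = _two_cliques_graph()
        truth = np.r_[np.zeros(30, int), np.ones(30, int)]
        dl_truth = dcsbm_description_length(g.adjacency, truth)
        dl_single = dcsbm_description_length(g.adjacency, np.zeros(60, int))
        split = truth.copy()
        split[:15] = 2
        dl_over = dcsbm_description_length(g.adjacency, split)
        assert dl_truth < dl_single
        assert dl_truth < dl_over


class TestSpectralSplit:
    def test_single_community(self):
        g = _two_cliques_graph()
        assert set(spectral_split(g, 1, 0)) == {0}

    def test_two_cliques_exact_split(self):
        g = _two_cliques_graph()
        labels = spectral_split(g, 2, 0)
        assert len(set(labels[:30])) == 1
        assert len(set(labels[30:])) == 1
        assert labels[0] != labels[30]

    def test_node_relabeling_equivariance(self, rng):
        g = _two_cliques_graph()
        perm = rng.permutation(60)
        a_dense = np.asarray(g.adjacency.todense())
        gp = PatternGraph(adjacency=csr_matrix(a_dense[np.ix_(perm, perm)]), k=g.k)
        la = spectral_split(g, 2, 0)
        lb = spectral_split(gp, 2, 0)
        # same partition up to label names
        groups_a = {frozenset(np.flatnonzero(la == c)) for c in set(la)}
        groups_b = {
            frozenset(perm[i] for i in np.flatnonzero(lb == c)) for c in set(lb)
        }
        assert groups_a == groups_b


class TestRefineGroups:
    def test_identical_patterns_fixed_point(self):
        pats = np.tile(np.array([1, 1, 0, 0, 1], dtype=np.uint8), (8, 1))
        cores = refine_groups([np.arange(8)], pats)
        assert len(cores) == 1
        np.testing.assert_array_equal(cores[0].alpha, pats[0])
        assert len(cores[0].member_patterns) == 8

    def test_identical_cores_merged(self):
        pats = np.tile(np.array([1, 0, 1, 0], dtype=np.uint8), (20, 1))
        cores = refine_groups([np.arange(10), np.arange(10, 20)], pats)
        assert len(cores) == 1
        assert len(cores[0].member_patterns) == 20

    def test_tiny_group_rejected(self, rng):
        pats = _planted_patterns(rng, n_groups=2, per_group=50)
        groups = [np.arange(50), np.arange(50, 100), np.array([0, 1, 2])]
        cores = refine_groups(groups, pats)
        assert len(cores) == 2

    def test_never_invents_neurons(self, rng):
        pats = _planted_patterns(rng)
        cores = refine_groups(
            [np.arange(g * 30, (g + 1) * 30) for g in range(4)], pats
        )
        for core in cores:
            active = np.flatnonzero(pats[core.member_patterns].any(axis=0))
            assert set(np.flatnonzero(core.alpha > 0)) <= set(active)


class TestCoresToAssemblies:
    def test_binary_alpha_gives_support(self):
        core = CorePattern(alpha=np.array([0.0, 1.0, 1.0, 0.0]), member_patterns=np.arange(5))
        cfg = cores_to_assemblies([core])
        assert cfg.member_sets() == [frozenset({1, 2})]

    def test_below_threshold_affinity_excluded(self):
        core = CorePattern(alpha=np.array([0.1, 0.9]), member_patterns=np.arange(10))
        cfg = cores_to_assemblies([core], s=0.2)
        assert cfg.member_sets() == [frozenset({1})]

    def test_all_below_threshold_dropped(self):
        core = CorePattern(alpha=np.array([0.1, 0.15]), member_patterns=np.arange(10))
        assert len(cores_to_assemblies([core], s=0.2)) == 0


def test_detect_sgc_recovers_planted_assemblies(desk_dataset):
    cfg = ab.detect_sgc(desk_dataset["dff"], rng_seed=2, n_perm=200)
    assert 9 <= len(cfg) <= 11
    score = ab.best_match_score(desk_dataset["config"], cfg)
    assert score > 0.85


def test_detect_sgc_seeded_determinism(rng):
    pats_dff = rng.standard_normal((30, 400))
    a = ab.detect_sgc(pats_dff, rng_seed=7, n_perm=50)
    b = ab.detect_sgc(pats_dff, rng_seed=7, n_perm=50)
    assert a.member_sets() == b.member_sets()
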
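"""Community detection backends, Jaccard relabeling, consensus, cleanup."""

import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from precisionmap.gray_model import GrayordinateSpace, LabelMap
from precisionmap.infomap_consensus import (CommunitySolution,
                                            ConsensusConfig,
                                            clean_small_clusters,
                                            consensus_across_densities,
                                            detect_communities,
                                            drop_small_networks,
                                            jaccard_index, match_communities)


def clique_edges(nodes):
    return [(i, j, 1.0) for a, i in enumerate(nodes)
            for j in nodes[a + 1:]]


def planted_partition(n_per_block=50, p_in=0.9, p_out=0.01, seed=5):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_block
    truth = np.r_[np.zeros(n_per_block, int), np.ones(n_per_block, int)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if truth[i] == truth[j] else p_out
            if rng.random() < p:
                edges.append((i, j, 1.0))
    return np.array(edges), truth


class TestDetectCommunities:
    def test_two_disconnected_cliques(self):
        edges = np.array(clique_edges([0, 1, 2, 3])
                         + clique_edges([4, 5, 6, 7]))
        sol = detect_communities(edges, 8)
        assert len(np.unique(sol.communities)) == 2
        assert len(set(sol.communities[:4])) == 1
        assert len(set(sol.communities[4:])) == 1

    def test_deterministic_for_same_seed(self):
        edges, _ = planted_partition()
        a = detect_communities(edges, 100, seed=3)
        b = detect_communities(edges, 100, seed=3)
        assert np.array_equal(a.communities, b.communities)

    def test_reference_backend_recovers_planted_partition(self):
        edges, truth = planted_partition()
        sol = detect_communities(edges, 100, backend="reference", seed=0)
        assert normalized_mutual_info_score(truth, sol.communities) >= 0.95

    def test_igraph_infomap_agrees_on_planted_partition(self):
        pytest.importorskip("igraph")
        edges, truth = planted_partition()
        sol = detect_communities(edges, 100, backend="infomap", seed=0)
        assert normalized_mutual_info_score(truth, sol.communities) >= 0.95

    def test_isolated_nodes_stay_unassigned(self):
        edges = np.array(clique_edges([0, 1, 2]))
        sol = detect_communities(edges, 5)
        assert sol.communities[3] == 0 and sol.communities[4] == 0

    def test_backend_failure_names_backend(self):
        with pytest.raises(RuntimeError, match="boom_backend"):
            def boom_backend(edges, n, seed=0):
                raise RuntimeError("nope")
            detect_communities(np.array([(0, 1, 1.0)]), 2,
                               backend=boom_backend)


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_index([1, 2, 3], [1, 2, 3]) == 1.0

    def test_disjoint_sets(self):
        assert jaccard_index([1, 2], [3, 4]) == 0.0

    def test_hand_case_one_third(self):
        assert jaccard_index([1, 2], [2, 3]) == pytest.approx(1 / 3)

    def test_both_empty(self):
        assert jaccard_index([], []) == 0.0


def make_reference(space, blocks):
    """LabelMap with the given list of (start, stop, label)."""
    labels = np.zeros(space.n_gray, dtype=int)
    for start, stop, lab in blocks:
        labels[start:stop] = lab
    return LabelMap(space=space, labels=labels)


class TestMatchCommunities:
    @pytest.fixture()
    def space(self, rng):
        return GrayordinateSpace(
            structure=np.array(["LEFT_CORTEX"] * 200),
            coords=rng.normal(size=(200, 3)) * 40)

    def test_community_equal_to_reference_network(self, space):
        ref = make_reference(space, [(0, 60, 1), (60, 200, 2)])  # DMN, Vis
        comms = np.r_[np.ones(60, int), np.full(140, 2, int)]
        out = match_communities(CommunitySolution(1.0, comms), ref)
        assert (out.labels[:60] == 1).all()
        assert (out.labels[60:] == 2).all()

    def test_low_jaccard_stays_unassigned(self, space):
        ref = make_reference(space, [(0, 100, 1), (100, 200, 2)])
        # community overlapping DMN on 5 of its 100 members only
        comms = np.zeros(200, int)
        comms[95:100] = 1
        out = match_communities(CommunitySolution(1.0, comms), ref)
        assert (out.labels[95:100] == 0).all()

    def test_competing_communities_higher_jaccard_wins(self, space):
        ref = make_reference(space, [(0, 100, 1), (100, 160, 2)])
        comms = np.zeros(200, int)
        comms[:80] = 1          # Jaccard 0.8 with DMN
        comms[80:140] = 2       # overlaps DMN (20) and Vis (40)
        out = match_communities(CommunitySolution(1.0, comms), ref)
        assert (out.labels[:80] == 1).all()          # community 1 wins DMN
        assert (out.labels[80:140] == 2).all()       # falls to Vis

    def test_many_to_one_allowed_for_leftovers(self, space):
        ref = make_reference(space, [(0, 100, 1)])
        # two spatially separate communities, both resembling DMN
        comms = np.zeros(200, int)
        comms[:55] = 1
        comms[55:100] = 2
        out = match_communities(CommunitySolution(1.0, comms), ref)
        assert (out.labels[:100] == 1).all()


class TestConsensus:
    @pytest.fixture()
    def space(self, rng):
        return GrayordinateSpace(structure=np.array(["LEFT_CORTEX"] * 10),
                                 coords=rng.normal(size=(10, 3)) * 40)

    def test_sparsest_assigned_label_wins(self, space):
        lm1 = make_reference(space, [])                      # all 0 at 0.3%
        lm2 = make_reference(space, [(0, 10, 1)])            # DMN at 0.4%
        lm3 = make_reference(space, [(0, 10, 2)])            # Vis at 3%
        out = consensus_across_densities([(0.3, lm1), (0.4, lm2), (3.0, lm3)])
        assert (out.labels == 1).all()

    def test_never_assigned_stays_unassigned(self, space):
        out = consensus_across_densities(
            [(d, make_reference(space, [])) for d in (0.3, 1.0, 3.0)])
        assert (out.labels == 0).all()

    def test_only_densest_assigned(self, space):
        lms = [(0.3, make_reference(space, [])),
               (3.0, make_reference(space, [(2, 5, 3)]))]
        out = consensus_across_densities(lms)
        assert (out.labels[2:5] == 3).all()
        assert (out.labels[:2] == 0).all()

    def test_input_order_irrelevant_after_density_tagging(self, space):
        lm1 = make_reference(space, [(0, 10, 1)])
        lm2 = make_reference(space, [(0, 10, 2)])
        a = consensus_across_densities([(0.3, lm1), (3.0, lm2)])
        b = consensus_across_densities([(3.0, lm2), (0.3, lm1)])
        assert np.array_equal(a.labels, b.labels)


def chain_space(n):
    """Grayordinates on a line, adjacency = nearest neighbours on the line."""
    coords = np.column_stack([np.arange(n, dtype=float) * 5,
                              np.zeros(n), np.zeros(n)])
    return GrayordinateSpace(structure=np.array(["LEFT_CORTEX"] * n),
                             coords=coords, knn_k=2)


class TestCleanSmallClusters:
    def test_island_merged_into_surrounding_network(self):
        space = chain_space(100)
        labels = np.full(100, 2, dtype=int)    # Vis territory
        labels[40:50] = 1                      # 10-grayordinate DMN island
        out = clean_small_clusters(LabelMap(space=space, labels=labels),
                                   min_cluster=30)
        assert (out.labels == 2).all()

    def test_no_small_clusters_is_identity(self):
        space = chain_space(100)
        labels = np.r_[np.ones(50, int), np.full(50, 2, int)]
        out = clean_small_clusters(LabelMap(space=space, labels=labels),
                                   min_cluster=30)
        assert np.array_equal(out.labels, labels)

    def test_larger_neighbor_network_wins(self):
        space = chain_space(120)
        labels = np.r_[np.ones(70, int),          # DMN: 70
                       np.full(10, 3, int),       # small FPN cluster
                       np.full(40, 2, int)]       # Vis: 40
        out = clean_small_clusters(LabelMap(space=space, labels=labels),
                                   min_cluster=30)
        assert (out.labels[70:80] == 1).all()     # merged into larger DMN

    def test_terminates_and_leaves_no_mergeable_small_component(self):
        space = chain_space(90)
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 4, size=90)
        out = clean_small_clusters(LabelMap(space=space, labels=labels),
                                   min_cluster=30)
        # all surviving labeled components with a labeled neighbour are >= 30
        from precisionmap.infomap_consensus import _label_components

        A = space.get_adjacency().tocsr()
        comp_id, comp_label, comp_size = _label_components(out.labels, A)
        for cid in range(len(comp_size)):
            if comp_label[cid] == 0:
                continue
            members = np.flatnonzero(comp_id == cid)
            nbrs = np.unique(A[members].indices)
            has_labeled_nbr = any(out.labels[v] not in (0, comp_label[cid])
                                  for v in nbrs)
            if has_labeled_nbr:
                assert comp_size[cid] >= 30


class TestDropSmallNetworks:
    def test_group_rule_unassigns_small_networks(self):
        space = chain_space(600)
        labels = np.r_[np.ones(500, int), np.full(100, 2, int)]
        out = drop_small_networks(LabelMap(space=space, labels=labels),
                                  min_network_group=400)
        assert (out.labels[:500] == 1).all()
        assert (out.labels[500:] == 0).all()


class TestConsensusConfig:
    def test_densities_must_ascend(self):
        with pytest.raises(ValueError, match="ascending"):
            ConsensusConfig(densities=(1.0, 0.3))
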
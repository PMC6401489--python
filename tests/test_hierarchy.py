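"""Hierarchy scoring, level assignment, and producer concentration."""

from __future__ import annotations

import numpy as np
import pytest

from inhibnet.errors import ConfigurationError
from inhibnet.hierarchy import (
    HierarchyResult,
    assign_levels,
    hierarchy_scores,
    producer_ranking,
    scores_from_adjacency,
    top_k_producer_share,
)
from inhibnet.matrix_io import union_network

from conftest import network_from_edges, random_tensor


def rule_counting_oracle(n: int, edges: set[tuple[int, int]]) -> list[int]:
    """Independent scorer applying the three point rules one by one."""
    scores = []
    for i in range(n):
        score = 0
        for j in range(n):
            if i == j:
                continue
            if (i, j) in edges:
                score += 1  # reward: i inhibits j
            if (j, i) in edges:
                score -= 1  # penalty: j inhibits i
            if (i, j) in edges and (j, i) in edges:
                score -= 1  # extra penalty: reciprocal partner
        scores.append(score)
    return scores


class TestScores:
    def test_single_edge(self):
        result = hierarchy_scores(network_from_edges(3, [(1, 2)]))
        assert result.scores() == {"S01": 1, "S02": -1, "S03": 0}

    def test_reciprocal_pair_scores_below_neutral(self):
        result = hierarchy_scores(network_from_edges(2, [(1, 2), (2, 1)]))
        assert result.scores() == {"S01": -1, "S02": -1}
        assert list(result.penalty_reciprocal) == [1, 1]

    def test_linear_order(self):
        result = hierarchy_scores(
            network_from_edges(3, [(1, 2), (1, 3), (2, 3)]))
        assert result.scores() == {"S01": 2, "S02": 0, "S03": -2}
        assert int(result.score.sum()) == 0

    def test_multi_condition_support_counts_once(self):
        net = network_from_edges(
            2, {(1, 2): {"c1", "c2", "c3"}}, conditions=("c1", "c2", "c3"))
        assert hierarchy_scores(net).scores() == {"S01": 1, "S02": -1}

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_exhaustive_oracle_equivalence_small(self, n):
        """Every edge set over up to four strains, against the
        rule-counting oracle (the five-strain sweep runs in the acceptance
        suite)."""
        cells = [(i, j) for i in range(n) for j in range(n) if i != j]
        for mask in range(1 << len(cells)):
            edges = {c for b, c in enumerate(cells) if mask >> b & 1}
            adj = np.zeros((n, n), dtype=bool)
            for i, j in edges:
                adj[i, j] = True
            *_, score = scores_from_adjacency(adj)
            assert list(score) == rule_counting_oracle(n, edges)

    @pytest.mark.parametrize("seed", range(20))
    def test_score_total_conservation(self, seed):
        net = union_network(random_tensor(np.random.default_rng(seed)))
        result = hierarchy_scores(net)
        n_recip_pairs = int(result.penalty_reciprocal.sum()) // 2
        assert int(result.score.sum()) == -2 * n_recip_pairs
        assert int(result.reward.sum()) == net.n_edges
        assert int(result.penalty_in.sum()) == net.n_edges

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(4)
        net = union_network(random_tensor(rng, n=6))
        result = hierarchy_scores(net)
        perm = rng.permutation(6)
        relabeled = network_from_edges(
            6,
            {(int(perm[net.strains.index(p)]) + 1,
              int(perm[net.strains.index(r)]) + 1): s
             for (p, r), s in net.edges.items()},
            conditions=net.conditions,
        )
        remapped = hierarchy_scores(relabeled)
        for s in net.strains.ids:
            target = relabeled.strains.ids[int(perm[net.strains.index(s)])]
            assert result.score_of(s) == remapped.score_of(target)


class TestLevels:
    @staticmethod
    def result_with_scores(scores):
        n = len(scores)
        arr = np.asarray(scores, dtype=np.int64)
        zeros = np.zeros(n, dtype=np.int64)
        return HierarchyResult(
            strains=tuple(f"S{i:02d}" for i in range(1, n + 1)),
            reward=zeros, penalty_in=zeros, penalty_reciprocal=zeros,
            score=arr)

    def test_even_tertile_split(self):
        result = self.result_with_scores([9, 8, 1, 0, -3, -7])
        levels = assign_levels(result)
        assert [levels[s] for s in result.strains] == [
            "high", "high", "medium", "medium", "low", "low"]

    def test_all_equal_scores_all_high(self):
        result = self.result_with_scores([2, 2, 2, 2])
        assert set(assign_levels(result).values()) == {"high"}

    def test_boundary_ties_take_higher_level(self):
        result = self.result_with_scores([5, 3, 3, 3, 1, 0])
        levels = assign_levels(result)
        # the three tied at 3 straddle the high/medium cut and all promote;
        # the remaining strains keep their tertile positions (4 and 5 = low)
        assert [levels[s] for s in result.strains] == [
            "high", "high", "high", "high", "low", "low"]

    def test_explicit_thresholds(self):
        result = self.result_with_scores([6, 2, -1])
        levels = assign_levels(result, (5, 0))
        assert [levels[s] for s in result.strains] == [
            "high", "medium", "low"]

    def test_nondecreasing_thresholds_rejected(self):
        result = self.result_with_scores([1, 2])
        with pytest.raises(ConfigurationError, match="decreasing"):
            assign_levels(result, (0, 5))


class TestTopProducerShare:
    def test_full_k_covers_everything(self):
        net = union_network(random_tensor(np.random.default_rng(7), n=6))
        share = top_k_producer_share(net, k=6)
        assert share.edge_count == net.n_edges
        assert share.share_percent == 100

    def test_single_edge_top_one(self):
        share = top_k_producer_share(network_from_edges(2, [(1, 2)]), k=1)
        assert (share.edge_count, share.share_percent) == (1, 100)
        assert share.producers == ("S01",)

    def test_k_out_of_bounds(self):
        net = network_from_edges(3, [(1, 2)])
        for k in (0, 4):
            with pytest.raises(ConfigurationError, match="out of range"):
                top_k_producer_share(net, k=k)

    def test_deterministic_tie_break_by_reward_then_id(self):
        # S02, S04, S05 all score -1: S02 outranks them on reward (1 vs 0),
        # and S04 precedes S05 on the id tie-break
        net = network_from_edges(
            5, [(1, 2), (1, 3), (2, 4), (3, 5), (3, 2)])
        ranking = producer_ranking(hierarchy_scores(net))
        assert ranking == ["S01", "S03", "S02", "S04", "S05"]
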
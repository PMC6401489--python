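"""Hierarchy scoring of a union inhibition network.

Each strain earns one *reward* point per distinct strain it inhibits, one
*penalty* point per distinct strain that inhibits it, and one additional
penalty point per reciprocal partner (a pair where each inhibits the other):

    score(i) = |targets(i)| - |sources(i)| - |reciprocal partners(i)|

Scoring always operates on the union network, so an interaction detected on
all media still contributes a single point.  Because every directed edge
hands exactly one reward to its producer and one in-penalty to its receiver,
rewards and in-penalties cancel over the whole network and the score total
equals minus twice the number of reciprocal pairs — a checkable conservation
law.

Strains are then binned into high / medium / low levels (score tertiles by
default, with ties promoted to the higher level, or explicit numeric
thresholds), and producer concentration is summarized as the share of all
edges emitted by the top-k strains in the score ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix_io import InteractionNetwork

LEVELS = ("high", "medium", "low")


def scores_from_adjacency(adj: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                     np.ndarray]:
    """Reward / in-penalty / reciprocal-penalty / score vectors from a
    boolean producer x receiver adjacency matrix."""
    adj = np.asarray(adj, dtype=bool)
    reward = adj.sum(axis=1).astype(np.int64)
    penalty_in = adj.sum(axis=0).astype(np.int64)
    penalty_reciprocal = (adj & adj.T).sum(axis=1).astype(np.int64)
    return reward, penalty_in, penalty_reciprocal, (
        reward - penalty_in - penalty_reciprocal
    )


@dataclass(frozen=True)
class HierarchyResult:
    """Per-strain hierarchy score with its reward/penalty decomposition."""

    strains: tuple[str, ...]
    reward: np.ndarray
    penalty_in: np.ndarray
    penalty_reciprocal: np.ndarray
    score: np.ndarray

    def score_of(self, strain: str) -> int:
        return int(self.score[self.strains.index(strain)])

    def scores(self) -> dict[str, int]:
        return {s: int(v) for s, v in zip(self.strains, self.score)}

    def to_frame(self, levels: dict[str, str] | None = None) -> pd.DataFrame:
        frame = pd.DataFrame({
            "strain": self.strains,
            "reward": self.reward,
            "penalty_in": self.penalty_in,
            "penalty_reciprocal": self.penalty_reciprocal,
            "score": self.score,
        })
        if levels is not None:
            frame["level"] = [levels[s] for s in self.strains]
        return frame


@dataclass(frozen=True)
class TopProducerShare:
    k: int
    producers: tuple[str, ...]
    edge_count: int
    share: float  # exact fraction of union edges
    share_percent: int  # rounded to the nearest integer (half-even)


def hierarchy_scores(network: InteractionNetwork) -> HierarchyResult:
    """Score every strain of the union network.

    The three point rules are applied to distinct partners: an edge supported
    by several conditions counts once, and a reciprocal pair costs each
    member one extra penalty on top of the mutual reward/in-penalty
    exchange (net -1 each), which is what pushes predominantly reciprocal
    strains below neutral.
    """
    reward, penalty_in, penalty_reciprocal, score = scores_from_adjacency(
        network.adjacency()
    )
    result = HierarchyResult(
        strains=network.strains.ids,
        reward=reward,
        penalty_in=penalty_in,
        penalty_reciprocal=penalty_reciprocal,
        score=score,
    )
    # conservation law: rewards and in-penalties cancel pairwise, so the
    # score total is minus the reciprocal-penalty total
    assert int(result.score.sum()) == -int(result.penalty_reciprocal.sum())
    return result


def _tertile_sizes(n: int) -> tuple[int, int, int]:
    base, rem = divmod(n, 3)
    return base + (rem > 0), base + (rem > 1), base


def assign_levels(result: HierarchyResult,
                  scheme: str | Sequence[float] = "tertile"
                  ) -> dict[str, str]:
    """Map each strain to ``high`` / ``medium`` / ``low``.

    ``scheme="tertile"`` splits the score-ranked strains into three groups of
    near-equal size (remainders go to the upper groups); strains tied at a
    boundary all take the higher level.  Alternatively a pair of strictly
    decreasing thresholds ``(t_high, t_medium)`` assigns ``high`` to scores
    ``>= t_high``, ``medium`` to scores ``>= t_medium``, ``low`` otherwise.
    Levels are presentational only and never feed back into scores.
    """
    scores = result.score
    if isinstance(scheme, str):
        if scheme != "tertile":
            raise ConfigurationError(f"unknown level scheme {scheme!r}")
        n = len(scores)
        n_high, n_med, _ = _tertile_sizes(n)
        # a strain's group is decided by its best rank: the number of
        # strictly better scores, so equal scores share the higher level
        best_rank = (scores[:, None] > scores[None, :]).sum(axis=0)
        out = {}
        for strain, rank in zip(result.strains, best_rank):
            if rank < n_high:
                out[strain] = "high"
            elif rank < n_high + n_med:
                out[strain] = "medium"
            else:
                out[strain] = "low"
        return out
    t_high, t_medium = (float(t) for t in scheme)
    if not t_high > t_medium:
        raise ConfigurationError(
            f"level thresholds must be strictly decreasing, got "
            f"({t_high}, {t_medium})"
        )
    return {
        strain: ("high" if s >= t_high
                 else "medium" if s >= t_medium else "low")
        for strain, s in zip(result.strains, scores)
    }


def producer_ranking(result: HierarchyResult) -> list[str]:
    """Strains ordered by score (desc), then reward (desc), then id —
    the deterministic ranking used for top-k concentration."""
    order = sorted(
        range(len(result.strains)),
        key=lambda i: (-int(result.score[i]), -int(result.reward[i]),
                       result.strains[i]),
    )
    return [result.strains[i] for i in order]


def top_k_producer_share(network: InteractionNetwork,
                         result: HierarchyResult | None = None,
                         k: int = 4) -> TopProducerShare:
    """Share of all union edges emitted by the k top-scoring strains.

    Raises a bounds error unless ``1 <= k <= n_species``.  The percentage is
    reported relative to the union edge count, rounded half-even to the
    nearest integer.
    """
    if result is None:
        result = hierarchy_scores(network)
    if not 1 <= k <= network.n_species:
        raise ConfigurationError(
            f"k={k} out of range 1..{network.n_species}"
        )
    top = tuple(producer_ranking(result)[:k])
    top_set = set(top)
    count = sum(1 for (p, _r) in network.edges if p in top_set)
    if network.n_edges == 0:
        share = 0.0
    else:
        share = count / network.n_edges
    return TopProducerShare(
        k=k,
        producers=top,
        edge_count=count,
        share=share,
        share_percent=int(round(100.0 * share)),
    )
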
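"""Permutation null models for inhibition-network statistics.

Descriptive statistics (producer concentration, reciprocity, asymmetry) say
little on their own; these nulls ask whether the observed value exceeds what
networks of the same size produce by chance. Three families, in increasing
order of what they hold fixed:

* ``erdos`` — same strain count and edge count, edges placed uniformly at
  random over off-diagonal ordered pairs without replacement;
* ``out-preserving`` — every producer keeps its distinct-target out-degree
  but its targets are resampled uniformly (no self-loops, no duplicates);
* ``both-margins`` — both the in- and out-degree sequences are preserved via
  checkerboard swaps (pick two edges a->b, c->d and rewire to a->d, c->b
  when that creates no self-loop or duplicate), run for a burn-in of
  ``burn_in_factor x |edges|`` accepted swaps from the observed network.

Each randomized network inherits the observed edges' condition-support sets
(supports travel with edge slots), so the support-size histogram is an
exact invariant of every family; none of the shipped statistics read the
supports, but the networks stay structurally valid.

Significance is summarized with the add-one Monte-Carlo p-value
``p = (1 + #{null >= observed}) / (1 + n_perm)`` (mirrored for direction
``less``), which can never be exactly zero. All draws are deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError, FeasibilityError, UndefinedStatisticError
from .hierarchy import hierarchy_scores, top_k_producer_share
from .matrix_io import InteractionNetwork
from .metrics import reciprocity, sender_receiver_asymmetry

NULL_FAMILIES = ("erdos", "out-preserving", "both-margins")

#: default test direction per statistic: concentration and reciprocity are
#: interesting when larger than chance, asymmetry when more negative
DEFAULT_DIRECTIONS = {
    "top_k_share": "greater",
    "reciprocal_pairs": "greater",
    "asymmetry_q": "less",
}


@dataclass(frozen=True)
class NullModelResult:
    statistic: str
    observed: float
    null_sample: tuple[float, ...]
    p_value: float
    direction: str
    family: str
    seed: int
    n_excluded: int = 0

    def to_dict(self, include_sample: bool = False) -> dict:
        out = {
            "statistic": self.statistic,
            "observed": self.observed,
            "p_value": self.p_value,
            "direction": self.direction,
            "family": self.family,
            "seed": self.seed,
            "n_perm": len(self.null_sample) + self.n_excluded,
            "n_excluded": self.n_excluded,
            "null_mean": float(np.mean(self.null_sample))
            if self.null_sample else None,
        }
        if include_sample:
            out["null_sample"] = list(self.null_sample)
        return out


# ---------------------------------------------------------------------------
# randomization cores operating on (adjacency, edge slots, supports)


def _edges_and_supports(network: InteractionNetwork):
    idx = {s: i for i, s in enumerate(network.strains.ids)}
    items = sorted(network.edges.items())  # deterministic slot order
    src = np.array([idx[p] for (p, _r), _ in items], dtype=np.int64)
    dst = np.array([idx[r] for (_p, r), _ in items], dtype=np.int64)
    supports = [support for _, support in items]
    return src, dst, supports


def _rebuild(network: InteractionNetwork, src, dst, supports
             ) -> InteractionNetwork:
    ids = network.strains.ids
    edges = {
        (ids[int(a)], ids[int(b)]): s
        for a, b, s in zip(src, dst, supports)
    }
    return InteractionNetwork(network.strains, network.conditions, edges)


def _erdos_core(n: int, n_edges: int, rng: np.random.Generator):
    flat = rng.choice(n * (n - 1), size=n_edges, replace=False)
    src = flat // (n - 1)
    rem = flat % (n - 1)
    dst = rem + (rem >= src)  # skip the diagonal
    return src, dst


def _out_preserving_core(n: int, src, dst, rng: np.random.Generator):
    new_dst = np.empty_like(dst)
    for producer in np.unique(src):
        slots = np.nonzero(src == producer)[0]
        others = np.delete(np.arange(n), producer)
        new_dst[slots] = rng.choice(others, size=len(slots), replace=False)
    return src.copy(), new_dst


def _both_margins_core(n: int, src, dst, rng: np.random.Generator,
                       burn_in_factor: int):
    adj = np.zeros((n, n), dtype=bool)
    adj[src, dst] = True
    src = src.copy()
    dst = dst.copy()
    n_edges = len(src)
    target = burn_in_factor * n_edges
    accepted = 0
    attempts = 0
    max_attempts = max(200 * target, 10_000)
    batch = 4096
    while accepted < target and attempts < max_attempts:
        picks = rng.integers(0, n_edges, size=(batch, 2))
        for e1, e2 in picks:
            attempts += 1
            a, b = src[e1], dst[e1]
            c, d = src[e2], dst[e2]
            if a == d or c == b or adj[a, d] or adj[c, b]:
                continue
            adj[a, b] = adj[c, d] = False
            adj[a, d] = adj[c, b] = True
            dst[e1] = d
            dst[e2] = b
            accepted += 1
            if accepted >= target:
                break
    if accepted == 0 and n_edges > 1 and target > 0:
        # a matrix admitting no checkerboard swap is the unique realization
        # of its margins; anything else hitting this point is a failure
        if _has_any_swap(adj):
            raise FeasibilityError(
                "checkerboard burn-in accepted no swaps despite available "
                "moves; increase the attempt budget"
            )
    return src, dst


def _has_any_swap(adj: np.ndarray) -> bool:
    src, dst = np.nonzero(adj)
    for i in range(len(src)):
        a, b = src[i], dst[i]
        for j in range(len(src)):
            c, d = src[j], dst[j]
            if a != d and c != b and not adj[a, d] and not adj[c, b]:
                return True
    return False


def randomize(network: InteractionNetwork, family: str,
              seed: int | np.random.Generator, *,
              burn_in_factor: int = 10) -> InteractionNetwork:
    """Draw one randomized network from the given null family.

    Deterministic given an integer seed; strain count and edge count are
    always preserved and self-loops never occur. Support sets of the
    observed edges are reassigned to the randomized edge slots.
    """
    if family not in NULL_FAMILIES:
        raise ConfigurationError(
            f"unknown null family {family!r}; choose from {NULL_FAMILIES}"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = network.n_species
    src, dst, supports = _edges_and_supports(network)
    if family == "erdos":
        new_src, new_dst = _erdos_core(n, len(src), rng)
        supports = [supports[i] for i in rng.permutation(len(supports))]
    elif family == "out-preserving":
        new_src, new_dst = _out_preserving_core(n, src, dst, rng)
    else:
        new_src, new_dst = _both_margins_core(n, src, dst, rng,
                                              burn_in_factor)
    return _rebuild(network, new_src, new_dst, supports)


# ---------------------------------------------------------------------------
# statistics and the permutation test


def make_statistic(name: str, *, k: int = 4
                   ) -> tuple[str, Callable[[InteractionNetwork], float]]:
    """Resolve a statistic name to (label, callable)."""
    if name == "top_k_share":
        def stat(g: InteractionNetwork) -> float:
            return top_k_producer_share(g, hierarchy_scores(g), k).share
        return f"top_{k}_share", stat
    if name == "reciprocal_pairs":
        def stat(g: InteractionNetwork) -> float:
            return float(len(reciprocity(g)))
        return "reciprocal_pairs", stat
    if name == "asymmetry_q":
        def stat(g: InteractionNetwork) -> float:
            return sender_receiver_asymmetry(g)
        return "asymmetry_q", stat
    raise ConfigurationError(
        f"unknown statistic {name!r}; choose from "
        f"{sorted(DEFAULT_DIRECTIONS)}"
    )


def empirical_p(observed: float, null_sample, direction: str) -> float:
    """Add-one Monte-Carlo p-value.

    ``greater``: (1 + #{null >= observed}) / (1 + n); ``less`` mirrors it.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    n = len(null_sample)
    if direction == "greater":
        extreme = int((null_sample >= observed).sum())
    elif direction == "less":
        extreme = int((null_sample <= observed).sum())
    else:
        raise ConfigurationError(f"unknown direction {direction!r}")
    return (1 + extreme) / (1 + n)


def null_test(network: InteractionNetwork, statistic: str, family: str,
              n_perm: int, seed: int, *, k: int = 4,
              direction: str | None = None,
              burn_in_factor: int = 10) -> NullModelResult:
    """Permutation test of one statistic against one null family.

    Computes the statistic on the observed network and on ``n_perm``
    independent randomizations (each restarted from the observed network),
    then reports the add-one empirical p-value. Draws on which the
    statistic is undefined are excluded from the null sample and counted
    in ``n_excluded``.
    """
    if n_perm < 99:
        raise ConfigurationError("n_perm must be at least 99")
    label, stat = make_statistic(statistic, k=k)
    if direction is None:
        direction = DEFAULT_DIRECTIONS[statistic]
    observed = stat(network)
    rng = np.random.default_rng(seed)
    sample: list[float] = []
    excluded = 0
    for _ in range(n_perm):
        draw = randomize(network, family, rng, burn_in_factor=burn_in_factor)
        try:
            sample.append(stat(draw))
        except UndefinedStatisticError:
            excluded += 1
    return NullModelResult(
        statistic=label,
        observed=float(observed),
        null_sample=tuple(sample),
        p_value=empirical_p(observed, sample, direction),
        direction=direction,
        family=family,
        seed=seed,
        n_excluded=excluded,
    )
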
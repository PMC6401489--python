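"""Global statistics of a directed inhibition network.

Three descriptors summarize how densely and how asymmetrically a strain
collection antagonizes itself:

* **connectance** ``C = E / S**2`` — the realized fraction of all ordered
  producer-receiver combinations (the denominator deliberately includes the
  diagonal, matching the food-web convention of interactions over species
  squared);
* **sender–receiver asymmetry** ``Q`` — a signed, scale-free contrast of how
  much structure sits on the producer side versus the receiver side.  With
  per-strain distinct-target out-degrees and distinct-source in-degrees,

      Q = (Var_in - Var_out) / (Var_in + Var_out)

  using population variances, so ``Q`` is in ``[-1, 1]``; ``Q < 0`` means
  producer identity carries more of the variance ("producer determined"),
  ``Q > 0`` the receivers do.  By construction ``Q`` flips sign exactly when
  the network is transposed.
* **degree/partner summaries** — per-strain distinct-target and
  distinct-source counts, and the number of distinct partners (a reciprocal
  partner counted once).

Reciprocal pairs — both ``i -> j`` and ``j -> i`` present — are enumerated
here as well; they are the "nonhierarchical" interactions of the hierarchy
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, UndefinedStatisticError
from .matrix_io import InteractionNetwork

Q_DEFINITIONS = ("degree-variance", "profile-correlation")


@dataclass(frozen=True)
class ReciprocalPair:
    """An unordered strain pair with inhibition in both directions."""

    pair: tuple[str, str]  # lexicographically sorted
    support_counts: tuple[int, int]  # aligned with pair order: a->b, b->a

    @property
    def max_support(self) -> int:
        return max(self.support_counts)


@dataclass(frozen=True)
class DegreeSummary:
    out_degree: dict[str, int]
    in_degree: dict[str, int]
    partner_count: dict[str, int]
    mean_partner_count: float


@dataclass(frozen=True)
class NetworkStats:
    """Bundle of the global statistics computed on one union network."""

    n_species: int
    n_edges: int
    connectance: float
    asymmetry_q: float | None
    degrees: DegreeSummary
    reciprocal_pairs: tuple[ReciprocalPair, ...]

    def to_dict(self) -> dict:
        """JSON-ready dictionary; reported values follow the package's
        rounding conventions (connectance 2 decimals, mean partners 1
        decimal, half-even), full precision kept alongside."""
        return {
            "n_species": self.n_species,
            "n_edges": self.n_edges,
            "connectance": self.connectance,
            "connectance_reported": round(self.connectance, 2),
            "asymmetry_q": self.asymmetry_q,
            "mean_partner_count": self.degrees.mean_partner_count,
            "mean_partner_count_reported": round(
                self.degrees.mean_partner_count, 1),
            "out_degree": self.degrees.out_degree,
            "in_degree": self.degrees.in_degree,
            "partner_count": self.degrees.partner_count,
            "n_reciprocal_pairs": len(self.reciprocal_pairs),
            "reciprocal_pairs": [
                {"pair": list(p.pair),
                 "support_counts": list(p.support_counts)}
                for p in self.reciprocal_pairs
            ],
        }


def connectance(network: InteractionNetwork) -> float:
    """Edges over species squared (diagonal included in the denominator)."""
    n = network.n_species
    return network.n_edges / (n * n)


def degree_arrays(network: InteractionNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Distinct-target out-degrees and distinct-source in-degrees, in
    canonical strain order."""
    adj = network.adjacency()
    return adj.sum(axis=1), adj.sum(axis=0)


def sender_receiver_asymmetry(network: InteractionNetwork,
                              definition: str = "degree-variance") -> float:
    """Signed producer-vs-receiver asymmetry Q of the network.

    Raises
    ------
    UndefinedStatisticError
        If the network has no edges (the ratio is 0/0 with no structure to
        compare).

    Notes
    -----
    A network whose in- and out-degree sequences are both constant (e.g. a
    perfect cycle, or every edge reciprocated symmetrically) has
    ``Var_in == Var_out`` and Q is defined as 0.  The
    ``profile-correlation`` definition name is reserved for an alternative
    formulation and is not yet implemented.
    """
    if definition not in Q_DEFINITIONS:
        raise ConfigurationError(
            f"unknown Q definition {definition!r}; choose from {Q_DEFINITIONS}"
        )
    if definition == "profile-correlation":
        raise NotImplementedError(
            "the profile-correlation Q definition is reserved but not "
            "implemented; use 'degree-variance'"
        )
    if network.n_edges == 0:
        raise UndefinedStatisticError(
            "sender-receiver asymmetry is undefined on an edgeless network"
        )
    out_deg, in_deg = degree_arrays(network)
    v_out = float(np.var(out_deg))  # population variance
    v_in = float(np.var(in_deg))
    if v_in == 0.0 and v_out == 0.0:
        return 0.0
    return (v_in - v_out) / (v_in + v_out)


def degree_summary(network: InteractionNetwork) -> DegreeSummary:
    """Per-strain degrees and distinct-partner counts.

    A strain's partner count is the size of the union of its targets and
    sources, so a pair interacting in both directions contributes one
    partner to each side, not two.
    """
    adj = network.adjacency()
    ids = network.strains.ids
    out_deg = adj.sum(axis=1)
    in_deg = adj.sum(axis=0)
    partners = (adj | adj.T).sum(axis=1)
    return DegreeSummary(
        out_degree={s: int(d) for s, d in zip(ids, out_deg)},
        in_degree={s: int(d) for s, d in zip(ids, in_deg)},
        partner_count={s: int(d) for s, d in zip(ids, partners)},
        mean_partner_count=float(partners.mean()),
    )


def reciprocity(network: InteractionNetwork) -> tuple[ReciprocalPair, ...]:
    """All unordered pairs with edges in both directions, sorted, each
    annotated with the two directed edges' support sizes."""
    pairs = []
    for (p, r), support in network.edges.items():
        if p < r and (r, p) in network.edges:
            pairs.append(ReciprocalPair(
                pair=(p, r),
                support_counts=(len(support), len(network.edges[(r, p)])),
            ))
    return tuple(sorted(pairs, key=lambda x: x.pair))


def network_stats(network: InteractionNetwork) -> NetworkStats:
    """Compute the full :class:`NetworkStats` bundle for one network."""
    q: float | None
    try:
        q = sender_receiver_asymmetry(network)
    except UndefinedStatisticError:
        q = None
    return NetworkStats(
        n_species=network.n_species,
        n_edges=network.n_edges,
        connectance=connectance(network),
        asymmetry_q=q,
        degrees=degree_summary(network),
        reciprocal_pairs=reciprocity(network),
    )
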
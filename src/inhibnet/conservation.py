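"""Cross-condition conservation of inhibitory interactions.

With k assay conditions, every union edge falls into exactly one Venn cell:
the non-empty subset of conditions in which it was detected. This module
tabulates that partition, the support-size histogram derived from it, the
"conserved in at least s conditions" counts/percentages (relative to the
union edge count), and the single- vs multi-medium classification of
reciprocal pairs. It also computes the nonhierarchical fraction: the share
of directed edges whose reverse edge also exists, i.e. edges tied up in
reciprocal (mutual-inhibition) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from .errors import ConsistencyError, UndefinedStatisticError
from .matrix_io import InhibitionTensor, InteractionNetwork, union_network
from .metrics import ReciprocalPair, reciprocity


@dataclass(frozen=True)
class ConservedCount:
    count: int
    percent: int  # of union edges, rounded half-even to nearest integer


@dataclass(frozen=True)
class ConservationSummary:
    """Venn partition of union edges over condition subsets."""

    conditions: tuple[str, ...]
    n_union_edges: int
    venn_counts: dict[frozenset[str], int]
    support_histogram: dict[int, int]
    conserved_at_least: dict[int, ConservedCount]

    def venn_label(self, subset: frozenset[str]) -> str:
        return "+".join(c for c in self.conditions if c in subset)

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "n_union_edges": self.n_union_edges,
            "venn_counts": {
                self.venn_label(s): c
                for s, c in sorted(
                    self.venn_counts.items(),
                    key=lambda kv: (len(kv[0]), self.venn_label(kv[0])),
                )
            },
            "support_histogram": {
                str(s): c for s, c in sorted(self.support_histogram.items())
            },
            "conserved_at_least": {
                str(s): {"count": cc.count, "percent": cc.percent}
                for s, cc in sorted(self.conserved_at_least.items())
            },
        }


@dataclass(frozen=True)
class ReciprocalClassification:
    """Conservation class of one mutual-inhibition pair.

    The pair is ``single-medium`` only when both of its directed edges were
    detected in exactly one condition; one multi-condition edge is enough to
    class the pair ``multi-medium``. Per-edge classes are kept alongside.
    """

    pair: tuple[str, str]
    pair_class: str  # "single-medium" | "multi-medium"
    edge_classes: tuple[str, str]  # aligned with (a->b, b->a)


@dataclass(frozen=True)
class NonhierarchicalFraction:
    edge_count: int  # directed edges whose reverse also exists
    n_edges: int
    fraction: float
    percent: int


def conservation_summary(tensor: InhibitionTensor) -> ConservationSummary:
    """Assign every union edge to its exact condition subset and summarize.

    The Venn cells are disjoint and exhaustive by construction; the routine
    asserts that their total matches the union edge count, and that the
    support histogram is the size-marginal of the partition. Percentages
    are relative to the union edge count.
    """
    conditions = tensor.conditions
    k = len(conditions)
    venn: dict[frozenset[str], int] = {
        frozenset(sub): 0
        for size in range(1, k + 1)
        for sub in combinations(conditions, size)
    }
    counts = tensor.support_counts()
    n_union = 0
    for i, j in zip(*np.nonzero(counts)):
        subset = frozenset(
            conditions[ci] for ci in range(k) if tensor.data[ci, i, j]
        )
        venn[subset] += 1
        n_union += 1
    histogram = {s: 0 for s in range(1, k + 1)}
    for subset, c in venn.items():
        histogram[len(subset)] += c
    assert sum(venn.values()) == n_union == sum(histogram.values())
    conserved: dict[int, ConservedCount] = {}
    for s in range(1, k + 1):
        c = sum(histogram[t] for t in range(s, k + 1))
        pct = 0 if n_union == 0 else int(round(100.0 * c / n_union))
        conserved[s] = ConservedCount(count=c, percent=pct)
    return ConservationSummary(
        conditions=conditions,
        n_union_edges=n_union,
        venn_counts=venn,
        support_histogram=histogram,
        conserved_at_least=conserved,
    )


def classify_reciprocal(
    network: InteractionNetwork,
    pairs: Iterable[ReciprocalPair] | None = None,
) -> tuple[ReciprocalClassification, ...]:
    """Class each reciprocal pair by the conservation of its two edges."""
    if pairs is None:
        pairs = reciprocity(network)
    out = []
    for pair in pairs:
        a, b = pair.pair
        if not (network.has_edge(a, b) and network.has_edge(b, a)):
            raise ConsistencyError(
                f"pair ({a!r}, {b!r}) is not reciprocal in this network"
            )
        supports = (len(network.support(a, b)), len(network.support(b, a)))
        edge_classes = tuple(
            "multi" if s >= 2 else "single" for s in supports
        )
        pair_class = ("multi-medium" if any(s >= 2 for s in supports)
                      else "single-medium")
        out.append(ReciprocalClassification(
            pair=(a, b), pair_class=pair_class, edge_classes=edge_classes,
        ))
    return tuple(out)


def nonhierarchical_fraction(
    network: InteractionNetwork) -> NonhierarchicalFraction:
    """Fraction of directed edges participating in reciprocal pairs.

    Mutual inhibition breaks a strict pecking order, so edges whose reverse
    edge also exists are the network's nonhierarchical component. Undefined
    (raises) on an edgeless network.
    """
    if network.n_edges == 0:
        raise UndefinedStatisticError(
            "nonhierarchical fraction is undefined on an edgeless network"
        )
    count = sum(1 for (p, r) in network.edges if (r, p) in network.edges)
    fraction = count / network.n_edges
    return NonhierarchicalFraction(
        edge_count=count,
        n_edges=network.n_edges,
        fraction=fraction,
        percent=int(round(100.0 * fraction)),
    )


def conservation_report(tensor: InhibitionTensor) -> dict:
    """Convenience: full conservation block for the JSON report."""
    network = union_network(tensor)
    summary = conservation_summary(tensor)
    classes = classify_reciprocal(network)
    block = summary.to_dict()
    block["reciprocal_classes"] = [
        {"pair": list(c.pair), "class": c.pair_class,
         "edge_classes": list(c.edge_classes)}
        for c in classes
    ]
    if network.n_edges:
        nh = nonhierarchical_fraction(network)
        block["nonhierarchical"] = {
            "edge_count": nh.edge_count,
            "fraction": nh.fraction,
            "percent": nh.percent,
        }
    return block
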
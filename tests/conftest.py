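"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from inhibnet.matrix_io import (
    InhibitionTensor,
    InteractionNetwork,
    StrainSet,
)
from inhibnet.synthetic import study_scale_fixture


def strain_ids(n: int) -> tuple[str, ...]:
    return tuple(f"S{i:02d}" for i in range(1, n + 1))


def tensor_from_arrays(data: np.ndarray,
                       conditions: tuple[str, ...] | None = None
                       ) -> InhibitionTensor:
    data = np.asarray(data, dtype=np.uint8)
    k, n, _ = data.shape
    if conditions is None:
        conditions = tuple(f"c{i + 1}" for i in range(k))
    return InhibitionTensor(StrainSet(strain_ids(n)), conditions, data)


def network_from_edges(n: int, edges, conditions=("c1",)
                       ) -> InteractionNetwork:
    """Build a network over n strains; ``edges`` maps (producer index,
    receiver index) 1-based pairs to support condition sets, or is an
    iterable of pairs (support defaults to the first condition)."""
    ids = strain_ids(n)
    if not isinstance(edges, dict):
        edges = {pair: {conditions[0]} for pair in edges}
    mapped = {
        (ids[p - 1], ids[r - 1]): frozenset(support)
        for (p, r), support in edges.items()
    }
    return InteractionNetwork(StrainSet(ids), tuple(conditions), mapped)


def random_tensor(rng: np.random.Generator, n: int = 8, k: int = 3,
                  density: float = 0.25) -> InhibitionTensor:
    data = (rng.random((k, n, n)) < density).astype(np.uint8)
    for ci in range(k):
        np.fill_diagonal(data[ci], 0)
    return tensor_from_arrays(data)


def transpose_network(network: InteractionNetwork) -> InteractionNetwork:
    return InteractionNetwork(
        network.strains,
        network.conditions,
        {(r, p): s for (p, r), s in network.edges.items()},
    )


@pytest.fixture(scope="session")
def fixture_tensor() -> InhibitionTensor:
    """The pinned 21-strain, 3-condition study-scale tensor."""
    return study_scale_fixture(seed=7)
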
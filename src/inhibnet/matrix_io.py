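"""Input/output and core containers for multi-condition inhibition data.

The raw result of a pairwise antagonism screen is, per growth condition, a
square binary matrix: rows are potential producers (strains tested for the
ability to inhibit), columns are receivers, and cell ``(p, r) = 1`` records a
zone of inhibition of ``r`` by ``p`` on that medium. This module defines the
three containers the rest of the package computes on —

* :class:`StrainSet` — the ordered strain collection with optional phylum
  labels,
* :class:`InhibitionTensor` — the strains x strains x conditions stack of
  binary detection matrices,
* :class:`InteractionNetwork` — the union directed graph, each edge annotated
  with the set of conditions supporting it —

plus readers/writers for the two on-disk layouts (wide square tables, one per
condition, and a sparse long edge table) and the Cytoscape-oriented exports
(SIF, GraphML).

Conventions: UTF-8 text; the delimiter is inferred from the file extension
(``.tsv`` tab, ``.csv`` comma) unless given explicitly; the canonical strain
order is the order of the first condition file and is enforced on all others.
Diagonal cells may be present in input files but must be 0 — the assay never
scores self-inhibition, so a nonzero diagonal is treated as corruption and
rejected loudly rather than dropped.
"""

from __future__ import annotations

import logging
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConflictError, ConsistencyError, MatrixFormatError

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("producer", "receiver", "condition", "value")


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass(frozen=True)
class StrainSet:
    """Ordered collection of strain identifiers with optional phylum labels.

    Parameters
    ----------
    ids
        Unique, non-empty strain identifiers. The order is the canonical
        order used by every matrix and report in the package.
    phylum
        Optional mapping from strain id to a phylum label (e.g. Firmicutes,
        Proteobacteria, Bacteroidetes, Actinobacteria). When present it must
        cover every id.
    """

    ids: tuple[str, ...]
    phylum: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        if len(ids) == 0:
            raise MatrixFormatError("strain set is empty")
        if any(i == "" for i in ids):
            raise MatrixFormatError("strain ids must be non-empty strings")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConsistencyError(f"duplicate strain ids: {dupes}")
        if self.phylum is not None:
            missing = [i for i in ids if i not in self.phylum]
            if missing:
                raise ConsistencyError(
                    f"phylum labels missing for strains: {missing}"
                )
            object.__setattr__(
                self, "phylum", {i: self.phylum[i] for i in ids}
            )

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __contains__(self, strain: object) -> bool:
        return strain in self.ids

    def index(self, strain: str) -> int:
        return self.ids.index(strain)


@dataclass(frozen=True)
class InhibitionTensor:
    """Binary inhibition matrices stacked over assay conditions.

    ``data`` has shape ``(n_conditions, n_strains, n_strains)``; axis 1 is
    the producer, axis 2 the receiver. Entries are strictly 0/1 and the
    diagonal is identically zero.
    """

    strains: StrainSet
    conditions: tuple[str, ...]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        conditions = tuple(str(c) for c in self.conditions)
        object.__setattr__(self, "conditions", conditions)
        if len(conditions) == 0:
            raise MatrixFormatError("tensor needs at least one condition")
        if len(set(conditions)) != len(conditions):
            raise ConsistencyError(f"duplicate condition names: {conditions}")
        n = len(self.strains)
        data = np.asarray(self.data)
        if data.shape != (len(conditions), n, n):
            raise MatrixFormatError(
                f"data shape {data.shape} does not match "
                f"({len(conditions)}, {n}, {n})"
            )
        if not np.isin(data, (0, 1)).all():
            bad = np.argwhere(~np.isin(data, (0, 1)))[0]
            c, i, j = (int(x) for x in bad)
            raise MatrixFormatError(
                f"non-binary entry {data[c, i, j]!r} at producer="
                f"{self.strains.ids[i]!r}, receiver={self.strains.ids[j]!r}, "
                f"condition={conditions[c]!r}"
            )
        diag = np.einsum("kii->ki", data.astype(np.uint8))
        if diag.any():
            c, i = (int(x) for x in np.argwhere(diag)[0])
            raise MatrixFormatError(
                f"nonzero diagonal (self-inhibition) for strain "
                f"{self.strains.ids[i]!r} in condition {conditions[c]!r}"
            )
        data = data.astype(np.uint8)
        data.setflags(write=False)
        object.__setattr__(self, "data", data)

    @property
    def n_species(self) -> int:
        return len(self.strains)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def condition_index(self, condition: str) -> int:
        try:
            return self.conditions.index(condition)
        except ValueError:
            raise KeyError(
                f"unknown condition {condition!r}; have {list(self.conditions)}"
            ) from None

    def matrix(self, condition: str) -> np.ndarray:
        """The (producer x receiver) 0/1 matrix for one condition."""
        return self.data[self.condition_index(condition)]

    def union_matrix(self) -> np.ndarray:
        """Boolean matrix of pairs detected under at least one condition."""
        return self.data.any(axis=0)

    def support_counts(self) -> np.ndarray:
        """Integer matrix counting in how many conditions each pair was seen."""
        return self.data.sum(axis=0, dtype=np.int64)


@dataclass(frozen=True)
class InteractionNetwork:
    """Union directed inhibition graph with per-edge condition support.

    ``edges`` maps ordered pairs ``(producer, receiver)`` to the non-empty
    frozenset of conditions in which that inhibition was detected; the edge
    weight used in reports is the support size.
    """

    strains: StrainSet
    conditions: tuple[str, ...]
    edges: Mapping[tuple[str, str], frozenset[str]]

    def __post_init__(self) -> None:
        conditions = tuple(self.conditions)
        object.__setattr__(self, "conditions", conditions)
        cond_set = set(conditions)
        clean: dict[tuple[str, str], frozenset[str]] = {}
        for (p, r), support in self.edges.items():
            if p == r:
                raise ConsistencyError(f"self-edge {p!r}->{r!r} is not allowed")
            if p not in self.strains or r not in self.strains:
                raise ConsistencyError(f"edge {p!r}->{r!r} names unknown strain")
            support = frozenset(support)
            if not support:
                raise ConsistencyError(f"edge {p!r}->{r!r} has empty support")
            if not support <= cond_set:
                raise ConsistencyError(
                    f"edge {p!r}->{r!r} supported by unknown conditions "
                    f"{sorted(support - cond_set)}"
                )
            clean[(p, r)] = support
        object.__setattr__(self, "edges", clean)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_species(self) -> int:
        return len(self.strains)

    def support(self, producer: str, receiver: str) -> frozenset[str]:
        return self.edges[(producer, receiver)]

    def has_edge(self, producer: str, receiver: str) -> bool:
        return (producer, receiver) in self.edges

    def adjacency(self) -> np.ndarray:
        """Boolean producer x receiver adjacency in canonical strain order."""
        n = len(self.strains)
        idx = {s: i for i, s in enumerate(self.strains.ids)}
        adj = np.zeros((n, n), dtype=bool)
        for p, r in self.edges:
            adj[idx[p], idx[r]] = True
        return adj

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for s in self.strains:
            attrs = {}
            if self.strains.phylum is not None:
                attrs["phylum"] = self.strains.phylum[s]
            g.add_node(s, **attrs)
        for (p, r), support in self.edges.items():
            g.add_edge(p, r, support_count=len(support),
                       support="|".join(sorted(support)))
        return g


# ---------------------------------------------------------------------------
# readers


def _read_wide_frame(path: Path, delimiter: str | None) -> pd.DataFrame:
    sep = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                        encoding="utf-8")
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    return frame


def _wide_to_matrix(frame: pd.DataFrame, path: Path,
                    order: Sequence[str]) -> np.ndarray:
    have = list(frame.index)
    if set(have) != set(order):
        diff = sorted(set(have) ^ set(order))
        raise ConsistencyError(
            f"{path}: strain set differs from the first condition file; "
            f"symmetric difference: {diff}"
        )
    frame = frame.reindex(index=order, columns=order)
    n = len(order)
    mat = np.zeros((n, n), dtype=np.uint8)
    for i, p in enumerate(order):
        for j, r in enumerate(order):
            raw = frame.iat[i, j]
            if pd.isna(raw):
                raise MatrixFormatError(
                    f"{path}: missing cell at producer={p!r}, receiver={r!r}"
                )
            val = str(raw).strip()
            if val not in ("0", "1"):
                raise MatrixFormatError(
                    f"{path}: non-binary value {raw!r} at producer={p!r}, "
                    f"receiver={r!r}"
                )
            mat[i, j] = int(val)
    return mat


def _read_wide(paths: Mapping[str, Path],
               delimiter: str | None) -> tuple[list[str], np.ndarray]:
    order: list[str] | None = None
    mats = []
    for condition, path in paths.items():
        frame = _read_wide_frame(path, delimiter)
        if list(frame.index) != list(frame.columns):
            raise MatrixFormatError(
                f"{path}: row and column strain orderings differ"
            )
        if order is None:
            order = list(frame.index)
            if len(set(order)) != len(order):
                raise ConsistencyError(f"{path}: duplicate strain ids {order}")
        mats.append(_wide_to_matrix(frame, path, order))
    assert order is not None
    return order, np.stack(mats)


def _read_long(paths: Mapping[str, Path], delimiter: str | None,
               strains: Sequence[str] | None) -> tuple[list[str], np.ndarray]:
    records: list[tuple[str, str, str, int, Path]] = []
    seen_order: list[str] = []
    for condition, path in paths.items():
        sep = _infer_delimiter(path, delimiter)
        frame = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
        frame.columns = [c.strip().lower() for c in frame.columns]
        for col in ("producer", "receiver", "value"):
            if col not in frame.columns:
                raise MatrixFormatError(f"{path}: missing column {col!r}")
        for _, row in frame.iterrows():
            p, r = str(row["producer"]).strip(), str(row["receiver"]).strip()
            if "condition" in frame.columns:
                c = str(row["condition"]).strip()
                if c != condition:
                    # one file may hold several conditions; rows belonging
                    # to another mapped condition are read in its own pass
                    if c in paths and paths[c] == path:
                        continue
                    raise ConsistencyError(
                        f"{path}: row condition {c!r} does not match mapped "
                        f"condition {condition!r}"
                    )
            raw = str(row["value"]).strip()
            if raw not in ("0", "1"):
                raise MatrixFormatError(
                    f"{path}: non-binary value {raw!r} for producer={p!r}, "
                    f"receiver={r!r}"
                )
            for s in (p, r):
                if s not in seen_order:
                    seen_order.append(s)
            records.append((p, r, condition, int(raw), path))
    order = list(strains) if strains is not None else seen_order
    if strains is not None:
        unknown = sorted({s for rec in records for s in rec[:2]}
                         - set(order))
        if unknown:
            raise ConsistencyError(
                f"long-format rows name strains outside the declared set: "
                f"{unknown}"
            )
    n = len(order)
    idx = {s: i for i, s in enumerate(order)}
    k = len(paths)
    cond_idx = {c: ci for ci, c in enumerate(paths)}
    data = np.full((k, n, n), -1, dtype=np.int16)
    for p, r, c, v, path in records:
        cell = (cond_idx[c], idx[p], idx[r])
        prev = data[cell]
        if prev != -1 and prev != v:
            raise ConflictError(
                f"{path}: conflicting duplicate rows for producer={p!r}, "
                f"receiver={r!r}, condition={c!r} ({prev} vs {v})"
            )
        data[cell] = v
    n_missing = int((data == -1).sum())
    if n_missing:
        logger.warning(
            "long-format input: %d unspecified cells treated as 0 "
            "(no inhibition observed)", n_missing,
        )
    data[data == -1] = 0
    return order, data.astype(np.uint8)


def read_tensor(
    paths_per_condition: Mapping[str, str | Path],
    format: str = "wide",
    *,
    delimiter: str | None = None,
    strains: Sequence[str] | None = None,
    phylum: Mapping[str, str] | None = None,
) -> InhibitionTensor:
    """Read one file per condition into a validated :class:`InhibitionTensor`.

    Parameters
    ----------
    paths_per_condition
        Ordered mapping condition name -> file path. The condition order of
        the tensor is the mapping's iteration order; the canonical strain
        order is taken from the first file (wide) or the declared ``strains``
        / first appearance (long).
    format
        ``"wide"`` — square table with strain ids as first row and first
        column; ``"long"`` — sparse edge table with header
        ``producer receiver [condition] value``, unlisted cells meaning 0.
    delimiter
        Overrides the extension-based delimiter inference.
    strains
        Long format only: the full declared strain list (needed when some
        strain has no interactions at all).
    phylum
        Optional strain -> phylum mapping attached to the result.
    """
    if not paths_per_condition:
        raise MatrixFormatError("no condition files given")
    paths = {str(c): Path(p) for c, p in paths_per_condition.items()}
    for path in paths.values():
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
    if format == "wide":
        if strains is not None:
            raise MatrixFormatError(
                "a declared strain list is only meaningful for the long "
                "format; wide files carry their own strain ordering"
            )
        order, data = _read_wide(paths, delimiter)
    elif format == "long":
        order, data = _read_long(paths, delimiter, strains)
    else:
        raise MatrixFormatError(f"unknown format {format!r}")
    strain_set = StrainSet(tuple(order), phylum)
    return InhibitionTensor(strain_set, tuple(paths), data)


def read_strain_metadata(path: str | Path,
                         delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column ``strain  phylum`` table into a mapping."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    frame.columns = [c.strip().lower() for c in frame.columns]
    if not {"strain", "phylum"} <= set(frame.columns):
        raise MatrixFormatError(f"{path}: expected columns 'strain' 'phylum'")
    return {str(row["strain"]).strip(): str(row["phylum"]).strip()
            for _, row in frame.iterrows()}


# ---------------------------------------------------------------------------
# writers


def write_wide(tensor: InhibitionTensor, directory: str | Path, *,
               delimiter: str | None = None, suffix: str = ".tsv"
               ) -> dict[str, Path]:
    """Write one square table per condition; returns condition -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    ids = list(tensor.strains.ids)
    for ci, condition in enumerate(tensor.conditions):
        path = directory / f"{condition}{suffix}"
        sep = _infer_delimiter(path, delimiter)
        frame = pd.DataFrame(tensor.data[ci], index=ids, columns=ids)
        frame.to_csv(path, sep=sep, encoding="utf-8")
        out[condition] = path
    return out


def write_long(tensor: InhibitionTensor, path: str | Path, *,
               delimiter: str | None = None) -> Path:
    """Write all positive cells as a sparse ``producer receiver condition value``
    table (zeros are implied)."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    rows = []
    ids = tensor.strains.ids
    for ci, condition in enumerate(tensor.conditions):
        for i, j in zip(*np.nonzero(tensor.data[ci])):
            rows.append((ids[int(i)], ids[int(j)], condition, 1))
    frame = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
    frame.to_csv(path, sep=sep, index=False, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# network construction


def union_network(tensor: InhibitionTensor) -> InteractionNetwork:
    """Collapse the tensor into the union directed graph.

    An ordered pair becomes one edge as soon as it is detected under at
    least one condition; its support set lists exactly the detecting
    conditions (an interaction seen on all media is still a single edge).
    """
    ids = tensor.strains.ids
    edges: dict[tuple[str, str], frozenset[str]] = {}
    counts = tensor.support_counts()
    for i, j in zip(*np.nonzero(counts)):
        support = frozenset(
            tensor.conditions[ci]
            for ci in range(tensor.n_conditions)
            if tensor.data[ci, i, j]
        )
        edges[(ids[int(i)], ids[int(j)])] = support
    return InteractionNetwork(tensor.strains, tensor.conditions, edges)


def condition_slice(tensor: InhibitionTensor,
                    condition: str) -> InteractionNetwork:
    """The single-condition network; every edge has singleton support."""
    ci = tensor.condition_index(condition)
    ids = tensor.strains.ids
    support = frozenset((condition,))
    edges = {
        (ids[int(i)], ids[int(j)]): support
        for i, j in zip(*np.nonzero(tensor.data[ci]))
    }
    return InteractionNetwork(tensor.strains, (condition,), edges)


def network_to_tensor(network: InteractionNetwork) -> InhibitionTensor:
    """Re-expand a network into a tensor over its own condition list."""
    n = len(network.strains)
    k = len(network.conditions)
    idx = {s: i for i, s in enumerate(network.strains.ids)}
    cidx = {c: ci for ci, c in enumerate(network.conditions)}
    data = np.zeros((k, n, n), dtype=np.uint8)
    for (p, r), support in network.edges.items():
        for c in support:
            data[cidx[c], idx[p], idx[r]] = 1
    return InhibitionTensor(network.strains, network.conditions, data)


# ---------------------------------------------------------------------------
# exports


def write_sif(network: InteractionNetwork, path: str | Path,
              relation: str = "inhibits") -> Path:
    """Cytoscape SIF export: one ``producer inhibits receiver`` line per edge."""
    path = Path(path)
    lines = [f"{p}\t{relation}\t{r}"
             for (p, r) in sorted(network.edges)]
    path.write_text("\n".join(lines) + ("\n" if lines else ""),
                    encoding="utf-8")
    return path


def write_graphml(network: InteractionNetwork, path: str | Path, *,
                  scores: Mapping[str, int] | None = None,
                  levels: Mapping[str, str] | None = None) -> Path:
    """GraphML export with edge attribute ``support_count`` and optional
    per-node ``score`` / ``level`` / ``phylum`` attributes."""
    g = network.to_networkx()
    if scores is not None:
        nx.set_node_attributes(g, {s: int(v) for s, v in scores.items()},
                               "score")
    if levels is not None:
        nx.set_node_attributes(g, dict(levels), "level")
    path = Path(path)
    nx.write_graphml(g, path)
    return path
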
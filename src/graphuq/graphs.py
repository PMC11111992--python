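"""Attributed-graph data model and generic JSON graph I/O.

Graphs are small (molecule-scale), so the adjacency matrix is stored dense;
an edge-list view is used only for serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "AttributedGraph",
    "Dataset",
    "GraphValidationError",
    "validate_graph",
    "graph_to_json",
    "graph_from_json",
    "write_graph_json",
    "read_graph_json",
]

Split = Literal["train", "valid", "test"]


class GraphValidationError(ValueError):
    """Raised when an :class:`AttributedGraph` violates a type invariant."""


@dataclass
class AttributedGraph:
    """An undirected attributed graph with optional label and ground truth.

    Parameters
    ----------
    features
        Node feature matrix of shape ``(n_nodes, d_in)``.
    adjacency
        Binary symmetric matrix of shape ``(n_nodes, n_nodes)``, zero diagonal.
    label
        Optional class index in ``{0..C-1}``.
    node_truth
        Optional binary vector marking ground-truth-important nodes.
    edge_truth
        Optional binary matrix marking ground-truth-important edges; nonzero
        only on the support of ``adjacency``.
    """

    features: np.ndarray
    adjacency: np.ndarray
    label: int | None = None
    node_truth: np.ndarray | None = None
    edge_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        if self.node_truth is not None:
            self.node_truth = np.asarray(self.node_truth, dtype=np.int8)
        if self.edge_truth is not None:
            self.edge_truth = np.asarray(self.edge_truth, dtype=np.int8)

    @property
    def node_count(self) -> int:
        return self.features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges as sorted 0-based pairs (i < j)."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def copy(self) -> "AttributedGraph":
        return AttributedGraph(
            features=self.features.copy(),
            adjacency=self.adjacency.copy(),
            label=self.label,
            node_truth=None if self.node_truth is None else self.node_truth.copy(),
            edge_truth=None if self.edge_truth is None else self.edge_truth.copy(),
        )

    def with_(self, **changes) -> "AttributedGraph":
        return replace(self, **changes)


def validate_graph(g: AttributedGraph) -> AttributedGraph:
    """Return ``g`` unchanged if all invariants hold, else raise.

    Checks: square symmetric {0,1} adjacency with zero diagonal, feature row
    count matching the node count, and truth masks consistent with shape and
    adjacency support.
    """
    a = g.adjacency
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise GraphValidationError(f"adjacency must be square, got shape {a.shape}")
    if g.features.ndim != 2 or g.features.shape[0] != a.shape[0]:
        raise GraphValidationError(
            f"feature rows ({g.features.shape[0]}) must equal node count ({a.shape[0]})"
        )
    if not np.array_equal(a, a.T):
        raise GraphValidationError("adjacency must be symmetric")
    if not np.isin(a, (0, 1)).all():
        raise GraphValidationError("adjacency entries must be 0 or 1")
    if np.any(np.diag(a) != 0):
        raise GraphValidationError("adjacency diagonal must be zero (no self-loops)")
    if g.node_truth is not None and g.node_truth.shape != (a.shape[0],):
        raise GraphValidationError("node_truth length must equal node count")
    if g.edge_truth is not None:
        if g.edge_truth.shape != a.shape:
            raise GraphValidationError("edge_truth shape must match adjacency")
        if np.any((g.edge_truth != 0) & (a == 0)):
            raise GraphValidationError("edge_truth nonzero off the adjacency support")
    return g


@dataclass
class Dataset:
    """An ordered collection of graphs sharing a feature dimension."""

    graphs: list[AttributedGraph]
    class_count: int = 2
    split_assignment: dict[int, Split] | None = None
    skipped_rows: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = {g.feature_dim for g in self.graphs}
        if len(dims) > 1:
            raise GraphValidationError(f"graphs mix feature dimensions: {sorted(dims)}")
        for g in self.graphs:
            if g.label is not None and not (0 <= g.label < self.class_count):
                raise GraphValidationError(
                    f"label {g.label} outside {{0..{self.class_count - 1}}}"
                )

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self) -> Iterator[AttributedGraph]:
        return iter(self.graphs)

    def __getitem__(self, idx: int) -> AttributedGraph:
        return self.graphs[idx]

    @property
    def feature_dim(self) -> int:
        return self.graphs[0].feature_dim

    def labels(self) -> np.ndarray:
        return np.array([g.label for g in self.graphs])

    def split(self, which: Split) -> "Dataset":
        """Subset of graphs assigned to one split; indices renumbered."""
        if self.split_assignment is None:
            raise ValueError("dataset has no split assignment; call split_dataset first")
        graphs = [self.graphs[i] for i in sorted(self.split_assignment)
                  if self.split_assignment[i] == which]
        return Dataset(graphs, class_count=self.class_count, metadata=dict(self.metadata))

    def split_indices(self, which: Split) -> list[int]:
        if self.split_assignment is None:
            raise ValueError("dataset has no split assignment")
        return [i for i in sorted(self.split_assignment)
                if self.split_assignment[i] == which]


# --------------------------------------------------------------------- JSON IO

def graph_to_json(g: AttributedGraph) -> dict:
    """Serializable dict: feature rows, 0-based undirected edges, label, truth."""
    out: dict = {
        "nodes": g.features.tolist(),
        "edges": [list(e) for e in g.edges()],
    }
    if g.label is not None:
        out["label"] = int(g.label)
    if g.node_truth is not None:
        out["node_truth"] = g.node_truth.astype(int).tolist()
    if g.edge_truth is not None:
        i, j = np.nonzero(np.triu(g.edge_truth, k=1))
        out["edge_truth"] = [[int(a), int(b)] for a, b in zip(i, j)]
    return out


def graph_from_json(payload: dict) -> AttributedGraph:
    features = np.asarray(payload["nodes"], dtype=np.float64)
    n = features.shape[0]
    adjacency = np.zeros((n, n), dtype=np.int8)
    for i, j in payload.get("edges", []):
        adjacency[i, j] = adjacency[j, i] = 1
    node_truth = None
    if "node_truth" in payload:
        node_truth = np.asarray(payload["node_truth"], dtype=np.int8)
    edge_truth = None
    if "edge_truth" in payload:
        edge_truth = np.zeros((n, n), dtype=np.int8)
        for i, j in payload["edge_truth"]:
            edge_truth[i, j] = edge_truth[j, i] = 1
    return validate_graph(
        AttributedGraph(
            features=features,
            adjacency=adjacency,
            label=payload.get("label"),
            node_truth=node_truth,
            edge_truth=edge_truth,
        )
    )


def write_graph_json(graphs: AttributedGraph | Sequence[AttributedGraph], path) -> None:
    """Write one graph (dict) or a sequence (list of dicts) as JSON."""
    if isinstance(graphs, AttributedGraph):
        payload = graph_to_json(graphs)
    else:
        payload = [graph_to_json(g) for g in graphs]
    Path(path).write_text(json.dumps(payload))


def read_graph_json(path) -> list[AttributedGraph]:
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, dict):
        payload = [payload]
    return [graph_from_json(p) for p in payload]
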
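"""Patch-adjacency graphs over retained tiles.

A patch is connected to each of its 8 grid neighbours (4 sides + 4 corners),
i.e. edge(i, j) iff the Chebyshev distance between grid coordinates is 1.
Slides with several tissue sections give disconnected graphs — components are
never relinked, and neither the gap between components nor their absolute
position carries information (the model never sees coordinates, only the
adjacency structure and node features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "SparseAdjacency",
    "SlideGraph",
    "build_adjacency",
    "connected_components",
    "normalize_adjacency",
    "assemble_graph",
    "save_graph",
    "load_graph",
]


@dataclass
class SparseAdjacency:
    """Undirected, unweighted adjacency as a COO edge list (i < j, no self-edges)."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) int64

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_scipy(self) -> sparse.csr_matrix:
        e = self.edges
        data = np.ones(2 * len(e))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix((data, (rows, cols)),
                                 shape=(self.n_nodes, self.n_nodes))

    def to_dense(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        if len(self.edges):
            a[self.edges[:, 0], self.edges[:, 1]] = 1.0
            a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        for col in (0, 1):
            np.add.at(d, self.edges[:, col], 1)
        return d


def build_adjacency(grid_coords: np.ndarray) -> SparseAdjacency:
    """8-connectivity adjacency from (N, 2) integer grid coordinates.

    Edge (i, j) iff max(|dr|, |dc|) == 1. Duplicate coordinates are an error.
    """
    coords = np.asarray(grid_coords, dtype=np.int64).reshape(-1, 2)
    n = len(coords)
    index = {}
    for i, rc in enumerate(map(tuple, coords)):
        if rc in index:
            raise ValueError(f"duplicate grid coordinate {rc}")
        index[rc] = i
    edges = []
    # scan only the 4 "forward" offsets so each undirected edge appears once
    for i, (r, c) in enumerate(map(tuple, coords)):
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
            j = index.get((r + dr, c + dc))
            if j is not None:
                edges.append((min(i, j), max(i, j)))
    e = np.array(sorted(edges), dtype=np.int64).reshape(-1, 2)
    return SparseAdjacency(n_nodes=n, edges=e)


def connected_components(adj: SparseAdjacency) -> np.ndarray:
    """Component label per node (0..C-1); empty array for an empty graph."""
    if adj.n_nodes == 0:
        return np.zeros(0, dtype=np.int64)
    _, labels = _cc(adj.to_scipy(), directed=False)
    return labels.astype(np.int64)


def normalize_adjacency(adj: SparseAdjacency) -> np.ndarray:
    """Symmetric renormalised adjacency D^-1/2 (A + I) D^-1/2 (dense).

    Self-loops are added here only; the raw adjacency stays loop-free. An
    edgeless graph yields the identity.
    """
    a = adj.to_dense() + np.eye(adj.n_nodes)
    dinv = 1.0 / np.sqrt(a.sum(axis=1))
    return a * dinv[:, None] * dinv[None, :]


@dataclass
class SlideGraph:
    """Node features + 8-connectivity structure of one slide's retained patches."""

    slide_id: str
    features: np.ndarray          # (N, d)
    adjacency: SparseAdjacency
    grid_coords: np.ndarray       # (N, 2) int
    component_labels: np.ndarray  # (N,) int
    _normalized: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.n_nodes

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if len(self.component_labels) else 0

    @property
    def normalized_adjacency(self) -> np.ndarray:
        if self._normalized is None:
            self._normalized = normalize_adjacency(self.adjacency)
        return self._normalized


def assemble_graph(features: np.ndarray, adjacency: SparseAdjacency,
                   grid_coords: np.ndarray, slide_id: str) -> SlideGraph:
    features = np.asarray(features, dtype=np.float64)
    grid_coords = np.asarray(grid_coords, dtype=np.int64).reshape(-1, 2)
    if not (len(features) == adjacency.n_nodes == len(grid_coords)):
        raise ValueError(
            f"row-count mismatch: {len(features)} features, "
            f"{adjacency.n_nodes} nodes, {len(grid_coords)} coords"
        )
    return SlideGraph(
        slide_id=slide_id,
        features=features,
        adjacency=adjacency,
        grid_coords=grid_coords,
        component_labels=connected_components(adjacency),
    )


def graph_from_features(feature_matrix, slide_id: str | None = None) -> SlideGraph:
    """Convenience: build the 8-connectivity graph straight from a FeatureMatrix."""
    adj = build_adjacency(feature_matrix.grid_coords)
    return assemble_graph(feature_matrix.matrix, adj, feature_matrix.grid_coords,
                          slide_id or feature_matrix.slide_id)


def save_graph(graph: SlideGraph, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=graph.features)
        f.create_dataset("edges", data=graph.adjacency.edges)
        f.create_dataset("grid_coords", data=graph.grid_coords)
        f.create_dataset("component_labels", data=graph.component_labels)
        f.attrs["slide_id"] = graph.slide_id
        f.attrs["n_nodes"] = graph.n_nodes


def load_graph(path: str | Path) -> SlideGraph:
    with h5py.File(path, "r") as f:
        adj = SparseAdjacency(n_nodes=int(f.attrs["n_nodes"]), edges=f["edges"][()])
        return SlideGraph(
            slide_id=str(f.attrs["slide_id"]),
            features=f["features"][()],
            adjacency=adj,
            grid_coords=f["grid_coords"][()],
            component_labels=f["component_labels"][()],
        )
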
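"""Spot-grid graphs for sequencing-based spatial transcriptomics sections.

Spots of one tissue section sit on a regular array (e.g. a 33x35 grid) and
are connected with an 8-neighbourhood: two spots are adjacent when their grid
rows and columns each differ by at most one.  Positions without tissue are
simply absent from the grid and leave holes in the graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc
from scipy.sparse.csgraph import shortest_path as _sp

__all__ = [
    "SpotGrid",
    "SpatialGraph",
    "RefinedGraph",
    "build_grid_graph",
    "shortest_path_distances",
    "random_edge_dropout",
    "connected_components",
]


@dataclass(frozen=True)
class SpotGrid:
    """Ordered spots of one section with integer (row, col) array coordinates.

    Spot order is canonical (row-major by (row, col)) and is the row index of
    every per-section matrix downstream.
    """

    spot_ids: tuple
    grid_coords: np.ndarray  # (n, 2) int
    pixel_coords: np.ndarray | None = None  # (n, 2) float, optional

    def __post_init__(self):
        coords = np.asarray(self.grid_coords, dtype=int)
        object.__setattr__(self, "grid_coords", coords)
        object.__setattr__(self, "spot_ids", tuple(self.spot_ids))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("grid_coords must be an (n, 2) array")
        if len(self.spot_ids) != coords.shape[0]:
            raise ValueError("spot_ids and grid_coords length mismatch")
        if coords.size and coords.min() < 0:
            raise ValueError("grid coordinates must be non-negative")
        seen = set(map(tuple, coords))
        if len(seen) != coords.shape[0]:
            raise ValueError("duplicate (row, col) grid coordinates")
        order = np.lexsort((coords[:, 1], coords[:, 0]))
        if not np.array_equal(order, np.arange(coords.shape[0])):
            raise ValueError(
                "spots must be in canonical row-major (row, col) order; "
                "use SpotGrid.from_unsorted to reorder"
            )
        if self.pixel_coords is not None:
            px = np.asarray(self.pixel_coords, dtype=float)
            if px.shape != (coords.shape[0], 2):
                raise ValueError("pixel_coords must be (n, 2)")
            object.__setattr__(self, "pixel_coords", px)

    @classmethod
    def from_unsorted(
        cls,
        spot_ids: Sequence,
        grid_coords,
        pixel_coords=None,
    ) -> "SpotGrid":
        """Build a grid, reordering spots into canonical row-major order."""
        coords = np.asarray(grid_coords, dtype=int)
        order = np.lexsort((coords[:, 1], coords[:, 0]))
        ids = tuple(np.asarray(spot_ids, dtype=object)[order])
        px = None
        if pixel_coords is not None:
            px = np.asarray(pixel_coords, dtype=float)[order]
        return cls(ids, coords[order], px)

    @property
    def n_spots(self) -> int:
        return self.grid_coords.shape[0]


def _validate_edges(edges: np.ndarray, n_spots: int) -> np.ndarray:
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    if edges.size:
        if edges.min() < 0 or edges.max() >= n_spots:
            raise ValueError("edge endpoint out of range")
        if np.any(edges[:, 0] >= edges[:, 1]):
            raise ValueError("edges must be stored (low, high) with low < high")
        as_tuples = set(map(tuple, edges))
        if len(as_tuples) != edges.shape[0]:
            raise ValueError("duplicate edges")
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges = edges[order]
    return edges


@dataclass(frozen=True)
class SpatialGraph:
    """Undirected graph over the spots of one :class:`SpotGrid`.

    Edges are stored with the lower spot index first and iterated in sorted
    order, so every seeded downstream computation is reproducible.
    """

    grid: SpotGrid
    edges: np.ndarray  # (m, 2) int, low < high, lexsorted
    self_loops_allowed: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "edges", _validate_edges(self.edges, self.grid.n_spots)
        )

    @property
    def n_spots(self) -> int:
        return self.grid.n_spots

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self, dtype=float) -> sp.csr_matrix:
        """Symmetric sparse adjacency matrix (no self-loops)."""
        n = self.n_spots
        if self.n_edges == 0:
            return sp.csr_matrix((n, n), dtype=dtype)
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * self.n_edges, dtype=dtype)
        return sp.csr_matrix(
            (data, (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        )

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()


@dataclass(frozen=True)
class RefinedGraph:
    """A spatial graph restricted to edges inside one cluster.

    ``kept_edges`` is always a subset of ``base.edges``; for every kept edge
    both endpoints carry the same label of ``cluster_labels``.
    """

    base: SpatialGraph
    kept_edges: np.ndarray
    cluster_labels: np.ndarray  # per-spot labels that produced the pruning

    def __post_init__(self):
        kept = _validate_edges(self.kept_edges, self.base.n_spots)
        base_set = set(map(tuple, self.base.edges))
        if not set(map(tuple, kept)) <= base_set:
            raise ValueError("kept_edges must be a subset of base.edges")
        labels = np.asarray(self.cluster_labels)
        if labels.shape[0] != self.base.n_spots:
            raise ValueError("cluster label vector length mismatch")
        if kept.size and np.any(labels[kept[:, 0]] != labels[kept[:, 1]]):
            raise ValueError("kept edge crosses a cluster boundary")
        object.__setattr__(self, "kept_edges", kept)
        object.__setattr__(self, "cluster_labels", labels)

    @property
    def n_spots(self) -> int:
        return self.base.n_spots

    @property
    def edges(self) -> np.ndarray:
        return self.kept_edges

    def as_graph(self) -> SpatialGraph:
        return SpatialGraph(self.base.grid, self.kept_edges)

    def adjacency(self, dtype=float) -> sp.csr_matrix:
        return self.as_graph().adjacency(dtype)


# 8-neighbourhood offsets (half, to emit each undirected edge once)
_HALF_OFFSETS = ((0, 1), (1, -1), (1, 0), (1, 1))


def build_grid_graph(grid: SpotGrid) -> SpatialGraph:
    """8-connected undirected graph over the spots present in ``grid``."""
    index = {tuple(rc): i for i, rc in enumerate(grid.grid_coords)}
    edges = []
    for i, (r, c) in enumerate(grid.grid_coords):
        for dr, dc in _HALF_OFFSETS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                edges.append((min(i, j), max(i, j)))
    arr = np.array(sorted(edges), dtype=int).reshape(-1, 2)
    return SpatialGraph(grid, arr)


def shortest_path_distances(graph: SpatialGraph) -> np.ndarray:
    """Unweighted shortest-path hop counts between all spot pairs.

    Pairs in different connected components get the finite cap ``n_spots``
    (a stand-in for infinity that keeps downstream similarities finite).
    """
    n = graph.n_spots
    if n == 0:
        raise ValueError("graph has no spots")
    d = _sp(graph.adjacency(), method="D", directed=False, unweighted=True)
    d[~np.isfinite(d)] = n
    return d.astype(int)


def random_edge_dropout(
    graph: SpatialGraph, ratio: float, seed: int
) -> SpatialGraph:
    """Keep a uniformly random ``round((1 - ratio) * |E|)``-edge subset."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"dropout ratio must be in [0, 1], got {ratio}")
    m = graph.n_edges
    n_keep = int(round((1.0 - ratio) * m))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(m, size=n_keep, replace=False))
    return SpatialGraph(graph.grid, graph.edges[keep], graph.self_loops_allowed)


def connected_components(graph: SpatialGraph | RefinedGraph) -> np.ndarray:
    """Per-spot component labels, contiguous integers from 0."""
    _, labels = _cc(graph.adjacency(), directed=False)
    # scipy labels are already contiguous from 0 in discovery order
    return labels.astype(int)
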
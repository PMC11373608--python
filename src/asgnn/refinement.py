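"""Adaptive graph refinement: meta-features, spot distances, AP pruning.

A linear projection W0 maps image features X to meta-features Z = X W0.
Spot-pair distances combine feature dissimilarity and spatial separation,

    d(n1, n2) = alpha * ||z_n1 - z_n2||_2 + beta * hops(n1, n2),

where hops counts edges of the shortest path in the initial 8-connected
grid graph.  Affinity propagation on -d partitions the spots into putative
spatial domains, and all grid edges crossing a domain boundary are removed,
restricting message passing of the downstream regressor to within-domain
spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .ap import affinity_propagation
from .data import FeatureMatrix
from .graph import RefinedGraph, SpatialGraph, shortest_path_distances

__all__ = [
    "MetaProjection",
    "RefinementConfig",
    "ClusterAssignment",
    "project_meta_features",
    "pairwise_distance",
    "ap_cluster",
    "refine_graph",
    "refine_from_features",
    "ap_gtn_pregraph",
]


@dataclass(frozen=True)
class MetaProjection:
    """The learned D_X x D_Z linear map from image to meta-features."""

    w0: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w0, dtype=float)
        if w.ndim != 2:
            raise ValueError("W0 must be 2-D (D_X x D_Z)")
        if not np.all(np.isfinite(w)):
            raise ValueError("W0 must be finite")
        object.__setattr__(self, "w0", w)

    @property
    def d_x(self) -> int:
        return self.w0.shape[0]

    @property
    def d_z(self) -> int:
        return self.w0.shape[1]


@dataclass(frozen=True)
class RefinementConfig:
    """Weights of the spot distance and affinity-propagation settings.

    ``alpha`` weights the Euclidean meta-feature distance, ``beta`` the
    hop-count distance; ``preference`` of None means the median of the
    off-diagonal similarities.
    """

    alpha: float = 1.0
    beta: float = 0.1
    d_z: int = 3
    preference: float | None = None
    damping: float = 0.9
    max_iter: int = 1000
    convergence_iter: int = 50

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")
        if not 0.5 <= self.damping < 1.0:
            raise ValueError("damping must be in [0.5, 1)")
        if self.d_z < 1:
            raise ValueError("d_z must be >= 1")


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-spot cluster labels in 1..K with optional exemplar spots."""

    labels: np.ndarray
    exemplars: np.ndarray | None = None

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a non-empty vector")
        k = labels.max()
        if labels.min() < 1:
            raise ValueError("labels must be in 1..K")
        present = np.unique(labels)
        if present.size != k:
            raise ValueError("every cluster in 1..K must be non-empty")
        object.__setattr__(self, "labels", labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def project_meta_features(
    features: FeatureMatrix | np.ndarray, projection: MetaProjection
) -> np.ndarray:
    """Meta-features Z = X W0 (no bias, no non-linearity)."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if x.shape[1] != projection.d_x:
        raise ValueError(
            f"feature dim {x.shape[1]} does not match W0 rows {projection.d_x}"
        )
    return x @ projection.w0


def pairwise_distance(
    meta: np.ndarray,
    graph: SpatialGraph,
    config: RefinementConfig,
    hops: np.ndarray | None = None,
) -> np.ndarray:
    """Combined feature/hop distance matrix over all spot pairs.

    ``hops`` may pass a precomputed hop-count matrix of ``graph`` (it only
    depends on the fixed initial grid, so callers cache it).
    """
    meta = np.asarray(meta, dtype=float)
    if meta.shape[0] != graph.n_spots:
        raise ValueError("meta-feature rows must match graph spots")
    if hops is None:
        hops = shortest_path_distances(graph)
    d1 = squareform(pdist(meta)) if meta.shape[0] > 1 else np.zeros((1, 1))
    d = config.alpha * d1 + config.beta * hops
    np.fill_diagonal(d, 0.0)
    return d


def ap_cluster(
    distances: np.ndarray, config: RefinementConfig
) -> ClusterAssignment:
    """Affinity propagation on similarity = -distance."""
    d = np.asarray(distances, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    labels0, exemplars, _ = affinity_propagation(
        -d,
        preference=config.preference,
        damping=config.damping,
        max_iter=config.max_iter,
        convergence_iter=config.convergence_iter,
    )
    return ClusterAssignment(labels0 + 1, exemplars)


def refine_graph(
    graph: SpatialGraph, clusters: ClusterAssignment
) -> RefinedGraph:
    """Drop every edge whose endpoints lie in different clusters."""
    labels = clusters.labels
    if labels.shape[0] != graph.n_spots:
        raise ValueError("cluster labels must cover all spots of the graph")
    e = graph.edges
    keep = labels[e[:, 0]] == labels[e[:, 1]] if e.size else np.zeros(0, bool)
    return RefinedGraph(graph, e[keep], labels)


def refine_from_features(
    features: FeatureMatrix | np.ndarray,
    graph: SpatialGraph,
    config: RefinementConfig,
    projection: MetaProjection | None = None,
    hops: np.ndarray | None = None,
) -> tuple[RefinedGraph, ClusterAssignment]:
    """Full refinement pipeline for one section.

    With a projection, distances use meta-features Z = X W0; without one,
    the raw features are used directly (the pre-clustered AP-GTN baseline).
    """
    if projection is not None:
        z = project_meta_features(features, projection)
    else:
        z = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    d = pairwise_distance(z, graph, config, hops=hops)
    clusters = ap_cluster(d, config)
    return refine_graph(graph, clusters), clusters


def ap_gtn_pregraph(
    features: FeatureMatrix,
    graph: SpatialGraph,
    config: RefinementConfig,
    hops: np.ndarray | None = None,
) -> RefinedGraph:
    """Fixed pre-clustered graph of the AP-GTN baseline (raw features)."""
    refined, _ = refine_from_features(features, graph, config, hops=hops)
    return refined
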
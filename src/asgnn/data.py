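"""Light containers for per-section matrices.

Every matrix of a section is indexed by the canonical spot order of its
:class:`~asgnn.graph.SpotGrid` (row-major by grid row then column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import RefinedGraph, SpatialGraph, SpotGrid

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "FeatureMatrix",
    "Section",
]


@dataclass(frozen=True)
class CountMatrix:
    """Raw UMI counts, spots x genes, non-negative integers."""

    values: np.ndarray
    gene_ids: tuple
    section_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("counts must be 2-D (spots x genes)")
        if v.size and v.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.allclose(v, np.round(v)):
                raise ValueError("counts must be integers")
            v = np.round(v).astype(np.int64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(self.gene_ids) != v.shape[1]:
            raise ValueError("gene_ids length does not match gene axis")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log-scale normalized expression, spots x genes."""

    values: np.ndarray
    gene_ids: tuple
    section_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("expression must be 2-D (spots x genes)")
        if not np.all(np.isfinite(v)):
            raise ValueError("expression must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(self.gene_ids) != v.shape[1]:
            raise ValueError("gene_ids length does not match gene axis")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-spot image-derived feature vectors, spots x D_X.

    ``feature_kind`` records the provenance of the vectors: morphological
    (nuclei-segmentation statistics), convolutional (pretrained-CNN
    embeddings) or synthetic.
    """

    values: np.ndarray
    feature_kind: str = "synthetic"

    _KINDS = ("morphological", "convolutional", "synthetic")

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("features must be 2-D (spots x D_X)")
        if not np.all(np.isfinite(v)):
            raise ValueError("features must be finite")
        object.__setattr__(self, "values", v)
        if self.feature_kind not in self._KINDS:
            raise ValueError(f"feature_kind must be one of {self._KINDS}")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class Section:
    """One tissue section: grid, graph, features, expression targets.

    ``annotation`` holds optional per-spot region labels (strings, ``None``
    for unannotated spots); ``nuclei_proportions`` an optional spots x types
    composition table.  ``hops`` caches the full-graph hop-count matrix.
    """

    section_id: str
    grid: SpotGrid
    graph: SpatialGraph
    features: FeatureMatrix
    expression: ExpressionMatrix | None = None
    counts: CountMatrix | None = None
    annotation: np.ndarray | None = None  # (n,) object, None = unannotated
    nuclei_proportions: np.ndarray | None = None
    nuclei_types: tuple | None = None
    _hops: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        n = self.grid.n_spots
        for name, mat in (
            ("features", self.features),
            ("expression", self.expression),
            ("counts", self.counts),
        ):
            if mat is not None and mat.n_spots != n:
                raise ValueError(
                    f"{name} has {mat.n_spots} rows, grid has {n} spots"
                )
        if self.annotation is not None:
            ann = np.asarray(self.annotation, dtype=object)
            if ann.shape[0] != n:
                raise ValueError("annotation length does not match spot count")
            self.annotation = ann
        if self.nuclei_proportions is not None:
            p = np.asarray(self.nuclei_proportions, dtype=float)
            if p.shape[0] != n:
                raise ValueError("nuclei proportion rows must match spots")
            self.nuclei_proportions = p

    @property
    def n_spots(self) -> int:
        return self.grid.n_spots

    @property
    def hops(self) -> np.ndarray:
        """Hop-count matrix of the *initial* full graph (cached)."""
        if self._hops is None:
            from .graph import shortest_path_distances

            self._hops = shortest_path_distances(self.graph)
        return self._hops
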
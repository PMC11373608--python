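"""Spatial-domain detection and downstream prototype analyses.

Fine-grained spot clusters come either from affinity propagation on (meta-)
features or from the connected components of the AP-sparsified grid graph.
Fine clusters are merged by agglomerative clustering of their mean feature
vectors, scanning every cut of the dendrogram for the best adjusted Rand
index against a pathologist-style annotation.  Spatial domains pooled
across sections are grouped into prototype clusters by k-means on their
mean nuclei-type composition, characterized by one-vs-rest Wilcoxon
rank-sum differential expression, and assessed with a bootstrap stability
score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ranksums
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .data import Section
from .graph import connected_components
from .refinement import (
    ClusterAssignment,
    MetaProjection,
    RefinementConfig,
    refine_from_features,
)

__all__ = [
    "DomainResult",
    "adjusted_rand_index",
    "merge_clusters",
    "detect_domains",
    "prototype_kmeans",
    "wilcoxon_de",
    "stability_score",
]


@dataclass
class DomainResult:
    """Spot clustering of one section with optional merged labels and ARI."""

    fine_labels: np.ndarray
    merged_labels: np.ndarray | None = None
    ari: float | None = None
    mode: str = "ap"
    singleton_mask: np.ndarray | None = None  # spots in singleton clusters


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement; ``None`` entries are dropped."""
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    keep = np.array(
        [x is not None and y is not None for x, y in zip(a, b)], dtype=bool
    )
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least 2 co-annotated spots")
    _, a_codes = np.unique(a.astype(str), return_inverse=True)
    _, b_codes = np.unique(b.astype(str), return_inverse=True)
    return float(adjusted_rand_score(a_codes, b_codes))


def merge_clusters(
    fine_labels: np.ndarray,
    cluster_mean_features: np.ndarray,
    annotation: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Agglomeratively merge fine clusters, keeping the best-ARI cut.

    ``cluster_mean_features`` holds one row per fine cluster (rows ordered
    by the sorted unique fine labels).  Average-linkage Euclidean merging;
    every dendrogram cut (number of clusters from n_fine down to 1) is
    scored by ARI against ``annotation`` and the best labeling is returned
    with its ARI.  This protocol searches for the best alignment with the
    annotation, so the reported ARI is optimistic by construction.
    """
    fine_labels = np.asarray(fine_labels)
    uniq = np.unique(fine_labels)
    means = np.asarray(cluster_mean_features, dtype=float)
    if means.shape[0] != uniq.size:
        raise ValueError("one mean-feature row per fine cluster required")
    if uniq.size == 1:
        return fine_labels.copy(), adjusted_rand_index(fine_labels, annotation)
    z = linkage(means, method="average", metric="euclidean")
    pos = {lab: i for i, lab in enumerate(uniq)}
    fine_idx = np.array([pos[l] for l in fine_labels])
    best_labels, best_ari = None, -np.inf
    for k in range(uniq.size, 0, -1):
        cut = fcluster(z, t=k, criterion="maxclust")
        merged = cut[fine_idx]
        ari = adjusted_rand_index(merged, annotation)
        if ari > best_ari:
            best_ari, best_labels = ari, merged
    return best_labels, float(best_ari)


def detect_domains(
    section: Section,
    config: RefinementConfig,
    mode: str = "cc",
    feature_source: str = "meta",
    projection: MetaProjection | None = None,
    merge: bool | None = None,
) -> DomainResult:
    """Spatial domains of one section via AP or connected components.

    ``mode`` "ap" takes the affinity-propagation labels directly; "cc"
    takes the connected components of the graph sparsified by those labels
    (finer clusters).  ``feature_source`` "meta" projects the image
    features through ``projection`` first; "raw" uses them as-is (the naive
    baseline).  With an annotation on the section (and ``merge`` not
    False), fine clusters are hierarchically merged to the best-ARI cut.
    """
    if mode not in ("ap", "cc"):
        raise ValueError("mode must be 'ap' or 'cc'")
    if feature_source not in ("raw", "meta"):
        raise ValueError("feature_source must be 'raw' or 'meta'")
    if feature_source == "meta" and projection is None:
        raise ValueError("meta feature_source requires a fitted projection")
    proj = projection if feature_source == "meta" else None
    refined, clusters = refine_from_features(
        section.features, section.graph, config,
        projection=proj, hops=section.hops,
    )
    if mode == "ap":
        fine = clusters.labels.copy()
    else:
        fine = connected_components(refined) + 1  # 1-based like AP labels

    counts = np.bincount(fine)
    singleton = counts[fine] == 1

    if merge is None:
        merge = section.annotation is not None
    if not merge:
        return DomainResult(fine, None, None, mode, singleton)
    if section.annotation is None:
        raise ValueError("merging requested but the section has no annotation")

    if proj is not None:
        feats = section.features.values @ proj.w0
    else:
        feats = section.features.values
    uniq = np.unique(fine)
    means = np.stack([feats[fine == u].mean(axis=0) for u in uniq])
    merged, ari = merge_clusters(fine, means, section.annotation)
    return DomainResult(fine, merged, ari, mode, singleton)


def prototype_kmeans(
    domain_proportions: np.ndarray, k: int, seed: int = 0
) -> np.ndarray:
    """k-means prototype labels (0..k-1) for per-domain composition rows."""
    p = np.asarray(domain_proportions, dtype=float)
    if p.ndim != 2:
        raise ValueError("domain proportions must be 2-D (domains x types)")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("proportion rows must sum to 1")
    if k > p.shape[0]:
        raise ValueError(f"k={k} exceeds the {p.shape[0]} available domains")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(p)


def wilcoxon_de(expression, labels) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum DE per prototype cluster and gene.

    Returns a table with columns cluster, gene, statistic, p, adj_p
    (Benjamini-Hochberg across all tests).  Genes tied across all spots
    get p = 1 by convention.
    """
    values = np.asarray(getattr(expression, "values", expression), float)
    gene_ids = getattr(expression, "gene_ids", None) or tuple(
        range(values.shape[1])
    )
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("labels must match expression rows")
    rows = []
    for cluster in np.unique(labels):
        mask = labels == cluster
        if mask.all() or not mask.any():
            raise ValueError("each cluster needs a non-empty complement")
        inside, outside = values[mask], values[~mask]
        for j, gene in enumerate(gene_ids):
            col_in, col_out = inside[:, j], outside[:, j]
            if np.ptp(values[:, j]) == 0:
                stat, p = 0.0, 1.0
            else:
                stat, p = ranksums(col_in, col_out)
            rows.append((cluster, gene, float(stat), float(p)))
    table = pd.DataFrame(rows, columns=["cluster", "gene", "statistic", "p"])
    table["adj_p"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def stability_score(
    domain_proportions: np.ndarray,
    k: int,
    n_bootstrap: int = 50,
    seed: int = 0,
    recluster_k: str = "k_minus_1",
) -> dict[int, float | None]:
    """Bootstrap stability of each prototype cluster.

    For each prototype cluster q of the k-means on ``domain_proportions``:
    mask q's domains, bootstrap-resample the remaining domains, re-run
    k-means (with k-1 centers by default, or k when ``recluster_k='k'``)
    and record the ARI between the new labels and the original labels of
    the resampled domains.  SS(q) is the mean over bootstraps; ``None``
    when masking leaves fewer domains than centers.
    """
    if n_bootstrap < 1:
        raise ValueError("need at least one bootstrap replicate")
    p = np.asarray(domain_proportions, dtype=float)
    base = prototype_kmeans(p, k, seed)
    rng = np.random.default_rng(seed)
    k_new = k - 1 if recluster_k == "k_minus_1" else k
    if recluster_k not in ("k_minus_1", "k"):
        raise ValueError("recluster_k must be 'k_minus_1' or 'k'")
    out: dict[int, float | None] = {}
    for q in np.unique(base):
        keep = np.flatnonzero(base != q)
        if keep.size < max(k_new, 2):
            out[int(q)] = None
            continue
        aris = []
        for _ in range(n_bootstrap):
            idx = rng.choice(keep, size=keep.size, replace=True)
            km = KMeans(
                n_clusters=k_new,
                random_state=int(rng.integers(2**31)),
                n_init=10,
            )
            new_labels = km.fit_predict(p[idx])
            aris.append(adjusted_rand_index(new_labels, base[idx]))
        out[int(q)] = float(np.mean(aris))
    return out
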
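"""Seeded synthetic spatial-transcriptomics datasets with planted domains.

Emulates a small sequencing-based ST study: each section is a partially
occupied spot grid partitioned into contiguous spatial domains (nearest
seed spot by hop distance).  Per-spot image features arise from a
domain-specific latent centroid passed through a fixed random linear lift
plus Gaussian noise; UMI counts are multinomial draws from a domain-
specific softmax expression program; nuclei-type compositions are
domain-specific Dirichlet draws.  Domain programs are shared across
sections (so models trained on some sections generalize to others) while
each section gets its own domain layout and noise.

All randomness flows from a single master seed through named substreams,
so changing one knob does not shift unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CountMatrix, FeatureMatrix, Section
from .graph import SpotGrid, build_grid_graph, shortest_path_distances
from .preprocessing import normalize_counts

__all__ = ["SyntheticSpec", "plant_domains", "generate_section", "simulate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and noise parameters of the synthetic study.

    The defaults give a small 15x15-grid study (occupancy 0.9, 3 contiguous
    domains, 10-d features, 20 genes, 4 sections) sized for minute-scale
    testing while keeping the qualitative structure of a real ST section:
    partially occupied grid, domain-coherent morphology and expression.
    """

    rows: int = 15
    cols: int = 15
    occupancy: float = 0.9
    n_domains: int = 3
    d_x: int = 10
    d_y: int = 20
    d_z_true: int = 3
    feature_noise: float = 0.3
    expression_noise: float = 0.2
    count_depth: float = 1000.0
    n_sections: int = 4
    n_nuclei_types: int = 6
    domain_feature_scale: float = 1.5
    domain_expression_scale: float = 1.0
    shared_label_patches: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must be in (0, 1]")
        if self.n_domains < 1:
            raise ValueError("need at least one domain")
        for name in ("d_x", "d_y", "d_z_true", "n_sections", "rows", "cols"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.feature_noise < 0 or self.expression_noise < 0:
            raise ValueError("noise levels must be non-negative")


def _rng(spec_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec_seed, spawn_key=tuple(key))
    )


def _make_grid(spec: SyntheticSpec, seed_key: tuple) -> SpotGrid:
    rng = _rng(spec.seed, *seed_key)
    total = spec.rows * spec.cols
    n_occ = max(int(round(spec.occupancy * total)), spec.n_domains)
    chosen = np.sort(rng.choice(total, size=n_occ, replace=False))
    coords = np.stack([chosen // spec.cols, chosen % spec.cols], axis=1)
    ids = tuple(f"spot_{r}x{c}" for r, c in coords)
    return SpotGrid(ids, coords)  # row-major because `chosen` is sorted


def plant_domains(
    spec: SyntheticSpec, grid: SpotGrid, seed: int
) -> np.ndarray:
    """Contiguous per-spot domain labels (0..n_domains-1) via hop Voronoi.

    Each domain is the set of spots nearest (in hop distance on the
    8-connected graph) to one of ``n_domains`` randomly chosen seed spots;
    ties go to the lower domain index.  With ``shared_label_patches`` two
    seed spots share one label, planting spatially disjoint patches with a
    common expression program.
    """
    n = grid.n_spots
    if spec.n_domains > n:
        raise ValueError("more domains than spots")
    rng = np.random.default_rng(seed)
    graph = build_grid_graph(grid)
    hops = shortest_path_distances(graph)
    n_seeds = spec.n_domains + (1 if spec.shared_label_patches else 0)
    seeds = rng.choice(n, size=n_seeds, replace=False)
    seed_labels = np.arange(n_seeds)
    if spec.shared_label_patches:
        seed_labels[-1] = 0  # the extra patch reuses domain 0's program
    d = hops[:, seeds].astype(float)
    labels = seed_labels[np.argmin(d, axis=1)]
    # re-attach any domain emptied by ties (cannot happen with argmin on
    # distinct seeds, but guard against a seed swallowed by the cap)
    for k in range(spec.n_domains):
        if not np.any(labels == k):
            labels[seeds[list(seed_labels).index(k)]] = k
    return labels


@dataclass(frozen=True)
class _DomainPrograms:
    """Domain-level generative parameters shared across sections."""

    latent_centroids: np.ndarray  # (n_domains, d_z_true)
    feature_lift: np.ndarray  # (d_z_true, d_x)
    log_rates: np.ndarray  # (n_domains, d_y)
    nuclei_alpha: np.ndarray  # (n_domains, n_types)


def _make_programs(spec: SyntheticSpec) -> _DomainPrograms:
    rng = _rng(spec.seed, 1)
    centroids = spec.domain_feature_scale * rng.standard_normal(
        (spec.n_domains, spec.d_z_true)
    )
    lift = rng.standard_normal((spec.d_z_true, spec.d_x)) / np.sqrt(
        spec.d_z_true
    )
    log_rates = spec.domain_expression_scale * rng.standard_normal(
        (spec.n_domains, spec.d_y)
    )
    nuclei_alpha = rng.uniform(0.5, 5.0, (spec.n_domains, spec.n_nuclei_types))
    return _DomainPrograms(centroids, lift, log_rates, nuclei_alpha)


def generate_section(
    spec: SyntheticSpec,
    grid: SpotGrid,
    domain_labels: np.ndarray,
    seed: int,
    programs: _DomainPrograms | None = None,
    section_id: str = "section_0",
) -> Section:
    """One synthetic section from a grid and planted domain labels."""
    if programs is None:
        programs = _make_programs(spec)
    labels = np.asarray(domain_labels, dtype=int)
    if labels.shape[0] != grid.n_spots:
        raise ValueError("domain labels must cover all spots")
    rng = np.random.default_rng(seed)
    n = grid.n_spots

    latent = programs.latent_centroids[labels]
    x = latent @ programs.feature_lift
    x = x + spec.feature_noise * rng.standard_normal((n, spec.d_x))

    log_rates = programs.log_rates[labels]
    log_rates = log_rates + spec.expression_noise * rng.standard_normal(
        (n, spec.d_y)
    )
    probs = np.exp(log_rates - log_rates.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    depths = rng.poisson(spec.count_depth, size=n)
    counts = np.stack(
        [rng.multinomial(depths[i], probs[i]) for i in range(n)]
    )

    props = np.stack(
        [rng.dirichlet(programs.nuclei_alpha[labels[i]]) for i in range(n)]
    )

    gene_ids = tuple(f"gene_{j}" for j in range(spec.d_y))
    count_mat = CountMatrix(counts, gene_ids, section_id)
    return Section(
        section_id=section_id,
        grid=grid,
        graph=build_grid_graph(grid),
        features=FeatureMatrix(x, "synthetic"),
        expression=normalize_counts(count_mat),
        counts=count_mat,
        annotation=np.array(
            [f"domain_{k}" for k in labels], dtype=object
        ),
        nuclei_proportions=props,
        nuclei_types=tuple(
            f"nuclei_{t}" for t in range(spec.n_nuclei_types)
        ),
    )


def simulate_dataset(spec: SyntheticSpec) -> list[Section]:
    """All sections of one synthetic study (shared domain programs)."""
    programs = _make_programs(spec)
    sections = []
    for i in range(spec.n_sections):
        grid = _make_grid(spec, (2, i))
        label_seed = int(_rng(spec.seed, 3, i).integers(2**31))
        labels = plant_domains(spec, grid, label_seed)
        sec_seed = int(_rng(spec.seed, 4, i).integers(2**31))
        sections.append(
            generate_section(
                spec, grid, labels, sec_seed, programs, f"section_{i}"
            )
        )
    return sections
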
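"""Seeded tissue simulators used for testing and benchmarking.

A :class:`TissueSpec` describes a rectangular spot grid with layer bands
along one axis and a gene panel where every gene follows one spatial
log-intensity pattern.  Counts are Poisson with a log link, so the standard
log1p + z-score preprocessing applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import CellExpression, SpotExpression, normalize_expression

__all__ = [
    "LayerMarker", "LinearGradient", "RadialBump", "CoexpressedCluster",
    "NullGene", "TissueSpec", "make_reference", "make_query",
    "make_cluster_panel",
]


@dataclass(frozen=True)
class LayerMarker:
    layer: int          # 1-based band index
    effect: float       # added log-intensity inside the band


@dataclass(frozen=True)
class LinearGradient:
    direction: str      # "row" or "col"
    slope: float


@dataclass(frozen=True)
class RadialBump:
    center: tuple[float, float]   # in unit square (row, col) fractions
    width: float
    height: float


@dataclass(frozen=True)
class CoexpressedCluster:
    cluster_id: int


@dataclass(frozen=True)
class NullGene:
    pass


@dataclass
class TissueSpec:
    grid: tuple[int, int] = (20, 20)
    hole_fraction: float = 0.0
    n_layers: int = 4
    genes: list[tuple[str, object]] = field(default_factory=list)
    baseline: float = 1.0           # baseline log-intensity
    band_axis: str = "row"
    cluster_templates: dict[int, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        n1, n2 = self.grid
        if n1 < 2 or n2 < 2:
            raise ValueError("degenerate grid: both dimensions must be >= 2")
        if not 0.0 <= self.hole_fraction <= 0.5:
            raise ValueError("hole_fraction must be in [0, 0.5]")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")

    # band boundaries as fractions of the band axis, equally spaced
    def band_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_layers + 1)

    def layer_of(self, u_band: np.ndarray) -> np.ndarray:
        """1-based layer index for band-axis positions in [0, 1]."""
        edges = self.band_edges()
        idx = np.clip(np.searchsorted(edges, u_band, side="right") - 1,
                      0, self.n_layers - 1)
        return idx + 1


def _log_intensity(spec: TissueSpec, pattern, u_row: np.ndarray,
                   u_col: np.ndarray) -> np.ndarray:
    u_band = u_row if spec.band_axis == "row" else u_col
    base = np.full_like(u_row, spec.baseline)
    if isinstance(pattern, NullGene):
        return base
    if isinstance(pattern, LayerMarker):
        return base + pattern.effect * (spec.layer_of(u_band) == pattern.layer)
    if isinstance(pattern, LinearGradient):
        u = u_row if pattern.direction == "row" else u_col
        return base + pattern.slope * u
    if isinstance(pattern, RadialBump):
        d2 = (u_row - pattern.center[0]) ** 2 + (u_col - pattern.center[1]) ** 2
        return base + pattern.height * np.exp(-d2 / (2.0 * pattern.width ** 2))
    if isinstance(pattern, CoexpressedCluster):
        tpl = spec.cluster_templates[pattern.cluster_id]
        n1, n2 = spec.grid
        r = np.clip((u_row * (n1 - 1)).round().astype(int), 0, n1 - 1)
        c = np.clip((u_col * (n2 - 1)).round().astype(int), 0, n2 - 1)
        return base + tpl[r, c]
    raise TypeError(f"unknown gene pattern {pattern!r}")


def make_reference(spec: TissueSpec) -> SpotExpression:
    """Simulate the spatial reference: spots at non-hole grid positions."""
    if not spec.genes:
        raise ValueError("spec declares no genes")
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.grid
    rows, cols = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    if spec.hole_fraction > 0:
        n_holes = int(round(spec.hole_fraction * rows.size))
        holes = rng.choice(rows.size, size=n_holes, replace=False)
        keep = np.setdiff1d(np.arange(rows.size), holes)
        rows, cols = rows[keep], cols[keep]
    u_row = rows / (n1 - 1)
    u_col = cols / (n2 - 1)
    counts = np.empty((rows.size, len(spec.genes)))
    for j, (_, pattern) in enumerate(spec.genes):
        lam = np.exp(_log_intensity(spec, pattern, u_row, u_col))
        counts[:, j] = rng.poisson(lam)
    u_band = u_row if spec.band_axis == "row" else u_col
    labels = np.array([f"L{k}" for k in spec.layer_of(u_band)])
    return SpotExpression(
        matrix=counts,
        gene_ids=[g for g, _ in spec.genes],
        spot_ids=[f"spot_{r}_{c}" for r, c in zip(rows, cols)],
        spatial_coords=np.column_stack([rows, cols]).astype(float),
        array_coords=np.column_stack([rows, cols]),
        labels=labels,
    )


def make_query(spec: TissueSpec, m: int, noise_sd: float = 0.0,
               seed: int = 0) -> CellExpression:
    """Simulate ``m`` query cells at uniform positions in the tissue.

    Counts come from the same intensity model as the reference; the returned
    container is normalized (log1p + z-score) with additive Gaussian noise of
    SD ``noise_sd`` applied to the standardized values, mirroring a
    perturb-the-test-set robustness design.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n1, n2 = spec.grid
    u_row = rng.uniform(size=m)
    u_col = rng.uniform(size=m)
    counts = np.empty((m, len(spec.genes)))
    for j, (_, pattern) in enumerate(spec.genes):
        lam = np.exp(_log_intensity(spec, pattern, u_row, u_col))
        counts[:, j] = rng.poisson(lam)
    u_band = u_row if spec.band_axis == "row" else u_col
    labels = np.array([f"L{k}" for k in spec.layer_of(u_band)])
    raw = CellExpression(
        matrix=counts,
        gene_ids=[g for g, _ in spec.genes],
        cell_ids=[f"cell{i}" for i in range(m)],
        true_coords=np.column_stack([u_row * (n1 - 1), u_col * (n2 - 1)]),
        true_labels=labels,
    )
    normed = normalize_expression(raw)
    if noise_sd > 0:
        normed.matrix = normed.matrix + rng.normal(
            scale=noise_sd, size=normed.matrix.shape)
    return normed


def make_cluster_panel(K: int, genes_per_cluster: int, separation: float,
                       seed: int = 0, grid: tuple[int, int] = (20, 20),
                       amplitude: float = 2.5) -> TissueSpec:
    """Build a spec whose genes form ``K`` co-expressed families.

    Each family shares a smooth bump template; templates are placed on a
    circle so they are pairwise distinct.  Raises when the achieved pairwise
    template distance (normalized l2) falls below ``separation``.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    n1, n2 = grid
    rr, cc = np.meshgrid(np.linspace(0, 1, n1), np.linspace(0, 1, n2),
                         indexing="ij")
    templates = {}
    for k in range(K):
        theta = 2 * np.pi * k / K
        cy, cx = 0.5 + 0.3 * np.sin(theta), 0.5 + 0.3 * np.cos(theta)
        templates[k] = amplitude * np.exp(
            -((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * 0.12 ** 2))
    flat = np.stack([templates[k].ravel() for k in range(K)])
    flat = flat / np.linalg.norm(flat, axis=1, keepdims=True)
    min_d = min(np.linalg.norm(flat[a] - flat[b])
                for a in range(K) for b in range(a + 1, K))
    if min_d < separation:
        raise ValueError(
            f"separation {separation} infeasible: achieved {min_d:.3f} on grid {grid}")
    genes = [(f"clu{k}_g{i}", CoexpressedCluster(k))
             for k in range(K) for i in range(genes_per_cluster)]
    return TissueSpec(grid=grid, genes=genes, cluster_templates=templates,
                      seed=seed)
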
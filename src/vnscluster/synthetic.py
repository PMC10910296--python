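"""Synthetic spatial-transcriptomics-like datasets with planted clusters.

Real inputs to the clustering are (x, y) tissue positions plus a per-cell
embedding vector; cells of one biological domain sit near each other in the
tissue AND share an embedding direction.  The generator emulates exactly that
joint structure: cluster g has a spatial center and an embedding center, its
cells scatter around both with Gaussian noise, and embeddings are re-scaled
to unit norm afterwards (cosine geometry well-conditioned, zero-norm rows
impossible).  It does NOT simulate raw counts, dropout, platform noise, or
irregular tissue shapes — recovery results on these fixtures demonstrate the
optimisation machinery, not robustness to real spatial-transcriptomics
artifacts.

Defaults describe a well-separated instance: 3 domains x 30 cells, spatial
centers 10 noise-SDs apart, orthogonal embedding centers 20 noise-SDs long.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import CellDataset
from .errors import ConfigError, ValidationError

__all__ = ["SyntheticSpec", "generate", "two_pair_instance"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one planted-cluster dataset.

    Parameters
    ----------
    n_clusters, cells_per_cluster : int
        Partition shape; n = n_clusters * cells_per_cluster.
    coord_centers : (n_clusters, 2) array, optional
        Spatial cluster centers.  Default: evenly spaced on a circle whose
        radius makes the minimum center separation ``coord_separation``.
    coord_noise_sd : float
        Isotropic Gaussian scatter of a cell around its spatial center, in
        coordinate units.
    coord_separation : float
        Minimum pairwise distance between default spatial centers; ignored
        when ``coord_centers`` is given.
    emb_dim : int
        Embedding dimensionality (>= 2).
    emb_center_separation : float
        Length of each cluster's embedding center along its own (mutually
        orthogonal when emb_dim >= n_clusters) direction; relative to
        ``emb_noise_sd`` this sets transcriptional cluster separation.
    emb_noise_sd : float
        Per-coordinate Gaussian noise added to the embedding center before
        unit normalisation.
    seed : int
        Generator seed; datasets are deterministic per seed.
    """

    n_clusters: int = 3
    cells_per_cluster: int = 30
    coord_centers: Optional[np.ndarray] = None
    coord_noise_sd: float = 1.0
    coord_separation: float = 10.0
    emb_dim: int = 16
    emb_center_separation: float = 1.0
    emb_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.cells_per_cluster < 1:
            raise ConfigError("cells_per_cluster must be >= 1")
        if self.emb_dim < 2:
            raise ConfigError("emb_dim must be >= 2")
        if min(self.coord_noise_sd, self.emb_noise_sd) < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.coord_centers is not None:
            centers = np.asarray(self.coord_centers, dtype=float)
            if centers.shape != (self.n_clusters, 2):
                raise ConfigError(
                    f"coord_centers must be ({self.n_clusters}, 2), got {centers.shape}"
                )

    @property
    def n(self) -> int:
        return self.n_clusters * self.cells_per_cluster


def _default_coord_centers(spec: SyntheticSpec) -> np.ndarray:
    g = spec.n_clusters
    if g == 1:
        return np.zeros((1, 2))
    # evenly spaced on a circle; chord between neighbors = coord_separation
    radius = spec.coord_separation / (2.0 * np.sin(np.pi / g))
    angles = 2.0 * np.pi * np.arange(g) / g
    return radius * np.column_stack([np.cos(angles), np.sin(angles)])


def _embedding_centers(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    g, d = spec.n_clusters, spec.emb_dim
    if g <= d:
        # random orthonormal directions via QR: centers mutually orthogonal
        q, _ = np.linalg.qr(rng.standard_normal((d, g)))
        dirs = q.T
    else:
        dirs = rng.standard_normal((g, d))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return spec.emb_center_separation * dirs


def generate(spec: SyntheticSpec) -> CellDataset:
    """Draw one dataset from the spec; ground-truth labels are attached.

    Embedding rows are unit-normalised after noise; the (measure-zero)
    zero-norm draw is resampled.
    """
    rng = np.random.default_rng(spec.seed)
    coord_centers = (
        np.asarray(spec.coord_centers, dtype=float)
        if spec.coord_centers is not None
        else _default_coord_centers(spec)
    )
    emb_centers = _embedding_centers(spec, rng)

    n = spec.n
    coords = np.empty((n, 2))
    emb = np.empty((n, spec.emb_dim))
    labels = []
    row = 0
    for g in range(spec.n_clusters):
        for _ in range(spec.cells_per_cluster):
            coords[row] = coord_centers[g] + spec.coord_noise_sd * rng.standard_normal(2)
            v = emb_centers[g] + spec.emb_noise_sd * rng.standard_normal(spec.emb_dim)
            norm = np.linalg.norm(v)
            while norm == 0.0:  # resample the degenerate draw
                v = emb_centers[g] + spec.emb_noise_sd * rng.standard_normal(spec.emb_dim)
                norm = np.linalg.norm(v)
            emb[row] = v / norm
            labels.append(f"cluster_{g + 1}")
            row += 1
    ids = [f"cell_{i + 1}" for i in range(n)]
    return CellDataset(ids, coords, emb, labels)


def two_pair_instance() -> CellDataset:
    """Canonical 4-cell worked example used throughout the tests.

    Cells sit on a line at x = 0, 1, 10, 11 (y = 0), grouped in two tight
    pairs; each pair shares an embedding direction orthogonal to the other
    pair's.  Under the pure spatial distance (alpha = 0, no normalisation)
    the best K = 2 medoid choice picks one cell per pair, giving F = 2.0
    (each non-medoid cell is 1 unit from its medoid); K = 4 gives F = 0.
    """
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 0.0]])
    emb = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    labels = ["left", "left", "right", "right"]
    return CellDataset(["c1", "c2", "c3", "c4"], coords, emb, labels)
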
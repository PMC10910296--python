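"""The blended cell-cell distance D = alpha * D_gene + (1 - alpha) * D_coord.

``D_gene`` is the cosine distance between embedding vectors (1 minus cosine
similarity, in [0, 2]); ``D_coord`` is the Euclidean distance between spatial
positions.  ``alpha`` in [0, 1] weights the transcriptional term: alpha = 1
ignores space entirely, alpha = 0.95 lets 5% of the blend come from spatial
proximity.

Raw coordinate distances carry the input's spatial units (pixels, µm) and can
dwarf the cosine term; ``normalize_coords=True`` divides the spatial term by
the maximum pairwise coordinate distance so both terms live on comparable
scales.  The constant actually applied is recorded as ``coord_scale`` (1.0
when normalization is off) so every downstream artifact can state which
convention produced it.

Two concrete models share one interface: :class:`DistanceModel` stores the
full dense n x n matrix; :class:`LazyDistanceModel` keeps only the inputs and
computes rows on demand, for datasets too large to hold n^2 floats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .data import CellDataset
from .errors import ConfigError, ValidationError

__all__ = [
    "DistanceModel",
    "LazyDistanceModel",
    "gene_distance",
    "coord_distance",
    "build_distance_model",
    "save_distance_model",
    "load_distance_model",
]


def gene_distance(emb_i, emb_j, *, metric: str = "distance") -> float:
    """Transcriptional term between two embedding vectors.

    With the default ``metric="distance"`` this is the cosine distance
    ``1 - cos(emb_i, emb_j)`` in [0, 2]: identical directions give 0,
    orthogonal 1, opposite 2.  ``metric="similarity"`` returns the raw cosine
    similarity instead — an audit mode; a similarity inside a minimisation
    objective rewards dissimilar cells, so it is never the default.
    """
    emb_i = np.asarray(emb_i, dtype=float)
    emb_j = np.asarray(emb_j, dtype=float)
    ni = np.linalg.norm(emb_i)
    nj = np.linalg.norm(emb_j)
    if ni == 0.0 or nj == 0.0:
        raise ValidationError("cosine distance undefined for a zero-norm vector")
    cos = float(np.dot(emb_i, emb_j) / (ni * nj))
    cos = min(1.0, max(-1.0, cos))
    if metric == "similarity":
        return cos
    if metric != "distance":
        raise ConfigError(f"unknown gene metric {metric!r}")
    return max(0.0, 1.0 - cos)


def coord_distance(p_i, p_j) -> float:
    """Euclidean distance between two spatial positions."""
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if not (np.isfinite(p_i).all() and np.isfinite(p_j).all()):
        raise ValidationError("non-finite coordinate")
    return float(np.hypot(p_i[0] - p_j[0], p_i[1] - p_j[1]))


def _gene_matrix(emb: np.ndarray, metric: str) -> np.ndarray:
    d = squareform(pdist(emb, metric="cosine"))
    if metric == "similarity":
        d = 1.0 - d
    elif metric == "distance":
        np.clip(d, 0.0, None, out=d)  # clamp -1e-16 style rounding
    else:
        raise ConfigError(f"unknown gene metric {metric!r}")
    np.fill_diagonal(d, 0.0 if metric == "distance" else 1.0)
    return d


class _BaseDistance:
    """Shared row/column access used by the solver and the oracle."""

    n: int
    alpha: float
    coord_scale: float

    def row(self, i: int) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def columns(self, idx) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def value(self, i: int, j: int) -> float:
        return float(self.row(i)[j])


@dataclass
class DistanceModel(_BaseDistance):
    """Dense symmetric n x n blended distance matrix with its provenance.

    Invariants: zero diagonal, symmetry, all entries >= 0.
    """

    matrix: np.ndarray
    alpha: float
    coord_scale: float = 1.0
    gene_metric: str = "distance"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def row(self, i: int) -> np.ndarray:
        return self.matrix[i]

    def columns(self, idx) -> np.ndarray:
        return self.matrix[:, np.asarray(idx, dtype=int)]


@dataclass
class LazyDistanceModel(_BaseDistance):
    """Row-on-demand variant for datasets where n^2 floats will not fit.

    Holds the coordinates and (row-normalised) embeddings; ``row(i)`` and
    ``columns(idx)`` recompute their slices of D each call.  Numerically
    identical to the dense model within floating-point tolerance.
    """

    coords: np.ndarray
    embeddings: np.ndarray
    alpha: float
    coord_scale: float = 1.0
    gene_metric: str = "distance"
    _unit: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")
        self.coords = np.asarray(self.coords, dtype=float)
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        norms = np.linalg.norm(self.embeddings, axis=1, keepdims=True)
        if np.any(norms == 0.0):
            raise ValidationError("zero-norm embedding row")
        self._unit = self.embeddings / norms

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def _blend(self, gene: np.ndarray, coord: np.ndarray) -> np.ndarray:
        return self.alpha * gene + (1.0 - self.alpha) * (coord / self.coord_scale)

    def columns(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=int)
        cos = self._unit @ self._unit[idx].T
        np.clip(cos, -1.0, 1.0, out=cos)
        gene = cos if self.gene_metric == "similarity" else np.clip(1.0 - cos, 0.0, None)
        coord = cdist(self.coords, self.coords[idx])
        out = self._blend(gene, coord)
        if self.gene_metric == "distance":
            out[idx, np.arange(idx.size)] = 0.0
        return out

    def row(self, i: int) -> np.ndarray:
        return self.columns([i])[:, 0]


def build_distance_model(
    dataset: CellDataset,
    alpha: float,
    normalize_coords: bool = False,
    *,
    gene_metric: str = "distance",
    lazy: Optional[bool] = None,
    lazy_threshold: int = 20_000,
) -> _BaseDistance:
    """Build the blended distance for a dataset.

    Parameters
    ----------
    alpha : float in [0, 1]
        Weight of the transcriptional (cosine) term; ``1 - alpha`` weights
        the spatial term.
    normalize_coords : bool
        Divide coordinate distances by the maximum pairwise coordinate
        distance before blending.  Off by default (the blend is applied to
        the raw Euclidean distances); the applied constant is recorded in
        ``coord_scale`` either way.
    lazy : bool, optional
        Force the row-on-demand model; defaults to dense below
        ``lazy_threshold`` cells and lazy above.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ConfigError(f"alpha must be in [0, 1], got {alpha}")
    coord_scale = 1.0
    if normalize_coords:
        if dataset.n > 1:
            # max pairwise distance == max distance from a hull vertex; a
            # direct pdist is fine at the sizes where dense D is feasible,
            # and cheap enough otherwise via chunked cdist against the hull
            try:
                from scipy.spatial import ConvexHull

                hull = dataset.coords[ConvexHull(dataset.coords).vertices]
            except Exception:  # collinear / tiny inputs
                hull = dataset.coords
            dmax = float(max(pdist(hull).max(), 0.0)) if len(hull) > 1 else 0.0
            coord_scale = dmax if dmax > 0.0 else 1.0
    if lazy is None:
        lazy = dataset.n > lazy_threshold
    if lazy:
        return LazyDistanceModel(
            coords=dataset.coords,
            embeddings=dataset.embeddings,
            alpha=alpha,
            coord_scale=coord_scale,
            gene_metric=gene_metric,
        )
    gene = _gene_matrix(dataset.embeddings, gene_metric)
    coord = squareform(pdist(dataset.coords))
    matrix = alpha * gene + (1.0 - alpha) * (coord / coord_scale)
    if gene_metric == "distance":
        np.fill_diagonal(matrix, 0.0)
    return DistanceModel(
        matrix=matrix, alpha=alpha, coord_scale=coord_scale, gene_metric=gene_metric
    )


def save_distance_model(model: DistanceModel, array_path, sidecar_path) -> None:
    """Dump the dense matrix as a .npy file plus a JSON provenance sidecar."""
    np.save(array_path, model.matrix)
    Path(sidecar_path).write_text(
        json.dumps(
            {
                "alpha": model.alpha,
                "coord_scale": model.coord_scale,
                "gene_metric": model.gene_metric,
                "n": model.n,
            },
            indent=2,
        )
    )


def load_distance_model(array_path, sidecar_path) -> DistanceModel:
    meta = json.loads(Path(sidecar_path).read_text())
    matrix = np.load(array_path)
    if matrix.shape[0] != meta.get("n", matrix.shape[0]):
        raise ValidationError("sidecar n disagrees with array shape")
    return DistanceModel(
        matrix=matrix,
        alpha=meta["alpha"],
        coord_scale=meta["coord_scale"],
        gene_metric=meta.get("gene_metric", "distance"),
    )
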
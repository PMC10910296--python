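"""Model/results interface over the medoid-VNS machinery.

:class:`SpatialPMedian` is constructed from a dataset (or a flat DataFrame /
files) plus the distance blend; calling :meth:`~SpatialPMedian.fit` runs the
seeded multi-start search and returns a :class:`SpatialPMedianResults`
carrying the best solution, the per-seed objective spread (f_VNS, err,
sigma), cluster labels, and a ``summary()`` table.

Example
-------
>>> from vnscluster import SpatialPMedian, synthetic
>>> ds = synthetic.generate(synthetic.SyntheticSpec(seed=7))
>>> res = SpatialPMedian(ds, n_clusters=3, alpha=0.5,
...                      normalize_coords=True).fit(n_runs=5, seed=1,
...                                                 max_iter=150)
>>> round(res.f_VNS, 3) >= 0
True
"""

from __future__ import annotations

from dataclasses import asdict
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .data import CellDataset, ClusterLabeling, read_dataset, write_labels
from .distance import _BaseDistance, build_distance_model
from .errors import ConfigError
from .evaluation import RunStats, adjusted_rand_index, run_batch
from .vns import CentroidSolution, VNSConfig, VNSTrace

__all__ = ["SpatialPMedian", "SpatialPMedianResults"]


class SpatialPMedian:
    """Medoid (p-median) clustering model for spatially resolved cells.

    Chooses K cells as cluster representatives minimising the summed blended
    distance D = alpha * D_gene + (1 - alpha) * D_coord from every cell to
    its nearest representative, via variable neighborhood search.

    Parameters
    ----------
    dataset : CellDataset
        Cells with coordinates and embeddings (labels optional).
    n_clusters : int
        K, the number of representatives to open.
    alpha : float in [0, 1]
        Weight of the embedding (cosine) term; 1.0 ignores space.
    normalize_coords : bool
        Scale the spatial term by the maximum pairwise coordinate distance.
    gene_metric : {"distance", "similarity"}
        Audit switch for the transcriptional term; see the distance module.
    """

    def __init__(
        self,
        dataset: CellDataset,
        n_clusters: int,
        alpha: float = 1.0,
        normalize_coords: bool = False,
        gene_metric: str = "distance",
        lazy: Optional[bool] = None,
    ) -> None:
        if not 1 <= n_clusters <= dataset.n:
            raise ConfigError(
                f"n_clusters must be in [1, n={dataset.n}], got {n_clusters}"
            )
        self.dataset = dataset
        self.n_clusters = int(n_clusters)
        self.alpha = float(alpha)
        self.normalize_coords = bool(normalize_coords)
        self.gene_metric = gene_metric
        self.distance_model: _BaseDistance = build_distance_model(
            dataset,
            alpha,
            normalize_coords,
            gene_metric=gene_metric,
            lazy=lazy,
        )

    # -- alternative constructors -------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        n_clusters: int,
        *,
        id_col: str = "id",
        x_col: str = "x",
        y_col: str = "y",
        label_col: Optional[str] = None,
        embedding_cols: Optional[Sequence[str]] = None,
        **kwargs,
    ) -> "SpatialPMedian":
        """Build from a flat table: id, x, y, embedding columns[, label]."""
        if embedding_cols is None:
            reserved = {id_col, x_col, y_col, label_col}
            embedding_cols = [c for c in df.columns if c not in reserved]
        labels = df[label_col].tolist() if label_col is not None else None
        ds = CellDataset(
            df[id_col].astype(str).tolist(),
            df[[x_col, y_col]].to_numpy(dtype=float),
            df[list(embedding_cols)].to_numpy(dtype=float),
            labels,
        )
        return cls(ds, n_clusters, **kwargs)

    @classmethod
    def from_files(
        cls,
        coords_path,
        n_clusters: int,
        embeddings_path=None,
        labels_path=None,
        **kwargs,
    ) -> "SpatialPMedian":
        """Build from on-disk delimited tables (see :func:`read_dataset`)."""
        ds = read_dataset(coords_path, embeddings_path, labels_path)
        return cls(ds, n_clusters, **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_runs: int = 20,
        seed: int = 0,
        max_iter: int = 500,
        k_min: int = 1,
        k_max: Optional[int] = None,
        k_step: int = 1,
        m: int = 10,
        p: int = 10,
        collect_traces: bool = False,
    ) -> "SpatialPMedianResults":
        """Run the search for ``n_runs`` consecutive seeds and keep the best.

        Returns a results object; identical arguments give bit-identical
        results.
        """
        config = VNSConfig(
            k=self.n_clusters,
            alpha=self.alpha,
            k_min=k_min,
            k_max=k_max,
            k_step=k_step,
            max_iter=max_iter,
            m=m,
            p=p,
            seed=seed,
            n_runs=n_runs,
            normalize_coords=self.normalize_coords,
        )
        config.validate_against(self.dataset.n)
        stats, best, traces = run_batch(
            self.distance_model, config, collect_traces=collect_traces
        )
        return SpatialPMedianResults(self, config, stats, best, traces)


class SpatialPMedianResults:
    """Fitted clustering: best solution, per-seed spread, labels, summary."""

    def __init__(
        self,
        model: SpatialPMedian,
        config: VNSConfig,
        stats: RunStats,
        solution: CentroidSolution,
        traces: List[VNSTrace],
    ) -> None:
        self.model = model
        self.config = config
        self.stats = stats
        self.solution = solution
        self.traces = traces

    # -- headline quantities -------------------------------------------------

    @property
    def f_VNS(self) -> float:
        """Best objective over the seed batch."""
        return self.stats.f_VNS

    @property
    def err(self) -> float:
        """Mean relative gap of each run's objective to f_VNS."""
        return self.stats.err

    @property
    def sigma(self) -> float:
        """Standard deviation of the per-run relative gaps."""
        return self.stats.sigma

    @property
    def centroid_ids(self) -> List[str]:
        ids = self.model.dataset.cell_ids
        return [ids[y] for y in np.sort(self.solution.Y)]

    @property
    def labels_(self) -> ClusterLabeling:
        """Cluster assignment of every cell; cluster names are centroid ids."""
        ids = self.model.dataset.cell_ids
        return ClusterLabeling(ids, [ids[x] for x in self.solution.X])

    def ari(self, truth: Optional[Sequence] = None) -> float:
        """Adjusted Rand index against ground truth (defaults to the
        dataset's own labels)."""
        if truth is None:
            truth = self.model.dataset.labels
        if truth is None:
            raise ConfigError("no ground-truth labels available for ARI")
        return adjusted_rand_index(list(truth), list(self.labels_.cluster_of))

    # -- reporting -----------------------------------------------------------

    def manifest(self) -> dict:
        """Full reproducibility record: config, blend provenance, version."""
        dm = self.model.distance_model
        return {
            "tool": "vnscluster",
            "version": _pkg_version,
            "config": asdict(self.config),
            "n_cells": self.model.dataset.n,
            "embedding_dim": self.model.dataset.m,
            "alpha": dm.alpha,
            "coord_scale": dm.coord_scale,
            "gene_metric": getattr(dm, "gene_metric", "distance"),
        }

    def to_report(self) -> dict:
        """JSON-ready run report: manifest + statistics + best solution."""
        rep = {
            "manifest": self.manifest(),
            "stats": self.stats.to_dict(),
            "best": {
                "F": self.solution.F,
                "centroid_ids": self.centroid_ids,
                "seed": self.stats.seeds[self.stats.best_index],
            },
        }
        if self.model.dataset.labels is not None:
            rep["ari_best_F_run"] = self.ari()
        return rep

    def save_labels(self, path) -> None:
        write_labels(self.labels_, path)

    def summary(self) -> str:
        """Plain-text summary table in the style of fitted-model reports."""
        c = self.config
        dm = self.model.distance_model
        lines = [
            "        Spatial p-median clustering (VNS)",
            "=" * 52,
            f"{'No. cells:':<28}{self.model.dataset.n}",
            f"{'Embedding dim:':<28}{self.model.dataset.m}",
            f"{'Clusters (K):':<28}{c.k}",
            f"{'alpha (gene weight):':<28}{c.alpha}",
            f"{'coord scale:':<28}{dm.coord_scale:.6g}",
            f"{'Runs (seeds):':<28}{c.n_runs} (base seed {c.seed})",
            f"{'max_iter / k_max / m / p:':<28}"
            f"{c.max_iter} / {c.resolved_k_max()} / {c.m} / {c.p}",
            "-" * 52,
            f"{'f_VNS (best objective):':<28}{self.f_VNS:.6f}",
            f"{'err (mean rel. gap):':<28}{self.err:.6f}",
            f"{'sigma (SD of gaps):':<28}{self.sigma:.6f}",
        ]
        if self.model.dataset.labels is not None:
            lines.append(f"{'ARI vs truth (best-F run):':<28}{self.ari():.4f}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def plot(self, ax=None, show_centroids: bool = True):
        """Scatter the cells in tissue coordinates colored by cluster.

        Requires matplotlib; returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        coords = self.model.dataset.coords
        clusters = np.asarray(self.solution.X)
        for y in np.sort(self.solution.Y):
            mask = clusters == y
            ax.scatter(coords[mask, 0], coords[mask, 1], s=12, label=f"medoid {y}")
        if show_centroids:
            Y = self.solution.Y
            ax.scatter(coords[Y, 0], coords[Y, 1], marker="x", s=80, c="black")
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        ax.set_aspect("equal")
        return ax
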
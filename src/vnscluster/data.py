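"""Domain types and tabular I/O.

A :class:`CellDataset` holds, for each of *n* cells, a 2-D spatial position
(x, y) and an *M*-dimensional embedding vector produced upstream (PCA or a
graph neural embedding — this package does not compute embeddings).  Optional
ground-truth labels ride along for evaluation.  Row order defines the cell
indices ``0..n-1`` used by the solver; logs report 1-based indices.

On-disk formats are plain delimited text (comma or tab) with a header:

* coordinates table: ``id,x,y[,e1,e2,...]`` — embedding columns may be
  inlined as all remaining numeric columns;
* embedding matrix: ``id,e1,e2,...`` or headerless numeric columns aligned
  by row;
* labels: ``id,label``;
* raw counts: MatrixMarket ``.mtx`` plus one-barcode-per-line and
  one-feature-per-line text files (ingestion convenience only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, IdError, ParseError, ValidationError

__all__ = [
    "CellDataset",
    "ClusterLabeling",
    "read_dataset",
    "read_labels",
    "write_labels",
    "write_dataset",
    "read_mtx_expression",
]

_ZERO_NORM_TOL = 0.0  # exact zero norm is the degenerate case for cosine


@dataclass
class CellDataset:
    """n cells with spatial coordinates, embeddings and optional truth labels.

    Parameters
    ----------
    cell_ids : sequence of str
        Unique identifiers, one per cell; order defines cell indices.
    coords : (n, 2) float array
        x, y positions in the input's spatial units.
    embeddings : (n, M) float array
        Per-cell embedding vectors; no row may have zero norm.
    labels : sequence, optional
        Ground-truth cluster labels aligned with ``cell_ids``.
    """

    cell_ids: Sequence[str]
    coords: np.ndarray
    embeddings: np.ndarray
    labels: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.coords = np.asarray(self.coords, dtype=float)
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        n = len(self.cell_ids)
        if n < 1:
            raise ValidationError("dataset must contain at least one cell")
        if self.coords.ndim != 2 or self.coords.shape != (n, 2):
            raise ValidationError(
                f"coords must be an (n, 2) matrix, got {self.coords.shape} for n={n}"
            )
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] != n:
            raise ValidationError(
                f"embeddings must have {n} rows, got shape {self.embeddings.shape}"
            )
        if self.embeddings.shape[1] < 1:
            raise ValidationError("embeddings must have at least one column")
        if len(set(self.cell_ids)) != n:
            seen: set = set()
            dup = next(c for c in self.cell_ids if c in seen or seen.add(c))
            raise IdError(f"duplicate cell id: {dup!r}")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coordinates contain non-finite values")
        if not np.isfinite(self.embeddings).all():
            raise ValidationError("embeddings contain non-finite values")
        norms = np.linalg.norm(self.embeddings, axis=1)
        bad = np.flatnonzero(norms <= _ZERO_NORM_TOL)
        if bad.size:
            raise ValidationError(
                f"zero-norm embedding for cell id {self.cell_ids[bad[0]]!r} "
                "(cosine distance undefined)"
            )
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != n:
                raise ValidationError(
                    f"labels length {len(self.labels)} != number of cells {n}"
                )

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @property
    def m(self) -> int:
        """Embedding dimensionality."""
        return self.embeddings.shape[1]

    def index_of(self, cell_id: str) -> int:
        try:
            return self.cell_ids.index(cell_id)
        except ValueError:
            raise IdError(f"unknown cell id {cell_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a single table: id, x, y, e1..eM [, label]."""
        df = pd.DataFrame({"id": self.cell_ids})
        df["x"] = self.coords[:, 0]
        df["y"] = self.coords[:, 1]
        for j in range(self.m):
            df[f"e{j + 1}"] = self.embeddings[:, j]
        if self.labels is not None:
            df["label"] = self.labels
        return df


@dataclass
class ClusterLabeling:
    """A clustering of the cells of a :class:`CellDataset`.

    ``cluster_of[i]`` is the cluster identifier of cell i; for solver output
    these identifiers are the centroid cell ids.
    """

    cell_ids: Sequence[str]
    cluster_of: Sequence

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cluster_of = list(self.cluster_of)
        if len(self.cell_ids) < 1:
            raise ValidationError("labeling must cover at least one cell")
        if len(self.cell_ids) != len(self.cluster_of):
            raise ValidationError("cell_ids and cluster_of differ in length")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise IdError("duplicate cell id in labeling")

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_of))


def _detect_sep(path: Path, sep: Optional[str]) -> str:
    # auto-detection deliberately limited to comma/tab; anything else must be
    # passed explicitly (predictability over magic)
    if sep is not None:
        return sep
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path, sep: Optional[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_detect_sep(path, sep))
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _id_column(df: pd.DataFrame, path) -> str:
    for cand in ("id", "Id", "ID", "cell_id", "barcode"):
        if cand in df.columns:
            return cand
    raise ParseError(f"{path}: no id column (expected one of id/cell_id/barcode)")


def _numeric_block(df: pd.DataFrame, cols: Sequence[str], path) -> np.ndarray:
    block = df[list(cols)].apply(pd.to_numeric, errors="coerce")
    if block.isna().any().any():
        col = block.columns[block.isna().any()][0]
        row = int(block[col].isna().idxmax())
        raise ParseError(f"{path}: non-numeric value in column {col!r}, row {row}")
    return block.to_numpy(dtype=float)


def read_dataset(
    coords_path,
    embeddings_path=None,
    labels_path=None,
    sep: Optional[str] = None,
) -> CellDataset:
    """Read a :class:`CellDataset` from delimited text files.

    The coordinates table must contain ``id``, ``x`` and ``y`` columns.  When
    ``embeddings_path`` is omitted, every remaining numeric column of the
    coordinates table is treated as an embedding dimension.  A separate
    embeddings file is joined on its id column when it has one, otherwise
    aligned by row order.  Labels are always joined on cell id.

    Raises
    ------
    IdError
        Missing, duplicate or unmatched cell ids.
    ParseError
        Non-numeric values where numbers are required.
    ValidationError
        A structural invariant fails (e.g. zero-norm embedding row).
    """
    coords_path = Path(coords_path)
    df = _read_table(coords_path, sep)
    idcol = _id_column(df, coords_path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ParseError(f"{coords_path}: missing required column {col!r}")
    ids = df[idcol].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise IdError(f"{coords_path}: duplicate cell ids")
    coords = _numeric_block(df, ["x", "y"], coords_path)

    if embeddings_path is None:
        emb_cols = [c for c in df.columns if c not in (idcol, "x", "y", "label")]
        if not emb_cols:
            raise ParseError(
                f"{coords_path}: no embedding columns and no embeddings file given"
            )
        embeddings = _numeric_block(df, emb_cols, coords_path)
    else:
        embeddings_path = Path(embeddings_path)
        edf = _read_table(embeddings_path, sep)
        try:
            eid = _id_column(edf, embeddings_path)
        except ParseError:
            eid = None
        if eid is not None:
            edf = edf.set_index(edf[eid].astype(str)).drop(columns=[eid])
            missing = [c for c in ids if c not in edf.index]
            if missing:
                raise IdError(
                    f"{embeddings_path}: no embedding for id {missing[0]!r}"
                )
            edf = edf.loc[ids]
        elif len(edf) != len(ids):
            raise IdError(
                f"{embeddings_path}: {len(edf)} rows cannot align with "
                f"{len(ids)} cells (no id column to join on)"
            )
        embeddings = _numeric_block(edf, edf.columns, embeddings_path)

    labels = None
    if labels_path is not None:
        lab = read_labels(labels_path, sep=sep)
        by_id = dict(zip(lab.cell_ids, lab.cluster_of))
        missing = [c for c in ids if c not in by_id]
        if missing:
            raise IdError(f"{labels_path}: no label for id {missing[0]!r}")
        labels = [by_id[c] for c in ids]

    return CellDataset(ids, coords, embeddings, labels)


def read_labels(path, sep: Optional[str] = None) -> ClusterLabeling:
    """Read a two-column (id, cluster) delimited file."""
    path = Path(path)
    df = _read_table(path, sep)
    idcol = _id_column(df, path)
    value_cols = [c for c in df.columns if c != idcol]
    if not value_cols:
        raise ParseError(f"{path}: expected a cluster column next to {idcol!r}")
    ids = df[idcol].astype(str).tolist()
    return ClusterLabeling(ids, df[value_cols[0]].tolist())


def write_labels(labeling: ClusterLabeling, path) -> None:
    """Write (id, cluster) rows as CSV, preserving cell order; round-trips
    through :func:`read_labels`."""
    pd.DataFrame(
        {"id": labeling.cell_ids, "cluster": labeling.cluster_of}
    ).to_csv(path, index=False)


def write_dataset(dataset: CellDataset, path) -> None:
    """Write the flattened dataset table (id,x,y,e1..eM[,label]) as CSV."""
    dataset.to_frame().to_csv(path, index=False)


def read_mtx_expression(mtx_path, barcodes_path, features_path):
    """Read a MatrixMarket count matrix with barcode/feature sidecar lists.

    Returns ``(counts, barcodes, features)`` where ``counts`` is a CSR sparse
    matrix of shape (n_barcodes, n_features) aligned to the sidecar order.
    This is an ingestion convenience for feeding an external embedding step;
    the clustering itself consumes embeddings, never raw counts.

    Raises
    ------
    FormatError
        Header dimensions disagree with the barcode or feature counts.
    """
    try:
        mat = scipy.io.mmread(mtx_path)
    except ValueError as exc:
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    barcodes = [ln.strip() for ln in Path(barcodes_path).read_text().splitlines() if ln.strip()]
    features = [ln.strip() for ln in Path(features_path).read_text().splitlines() if ln.strip()]
    if mat.shape[0] != len(barcodes):
        raise FormatError(
            f"{mtx_path}: header declares {mat.shape[0]} rows but "
            f"{barcodes_path} lists {len(barcodes)} barcodes"
        )
    if mat.shape[1] != len(features):
        raise FormatError(
            f"{mtx_path}: header declares {mat.shape[1]} columns but "
            f"{features_path} lists {len(features)} features"
        )
    return scipy.sparse.csr_matrix(mat), barcodes, features
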
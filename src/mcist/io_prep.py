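"""Reading, writing and preprocessing of spot x gene expression data.

The canonical in-memory layout is genes x spots (``X`` is M x N with M genes
in rows and N spots/cells in columns); every spot-level structure downstream
(graphs, embeddings, labels) indexes columns of ``X``.  Loaders accept the
transposed orientation through a flag.

The preprocessing pipeline is the standard one for spatial transcriptomics
count matrices: quality-control filtering of near-silent genes and near-empty
spots, per-spot total-count normalization to a fixed scale, log1p transform,
and selection of highly variable genes by binned normalized dispersion.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "SpatialCoords",
    "read_expression",
    "write_expression",
    "read_coords",
    "write_coords",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "QcReport",
]

State = Literal["raw_counts", "normalized", "log_transformed", "hvg_subset"]

_STATE_ORDER = ["raw_counts", "normalized", "log_transformed", "hvg_subset"]


def _check_ids(ids: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(map(str, dups)))}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x spots expression values with identifiers and a processing tag.

    Parameters
    ----------
    values
        M x N array (dense ndarray or scipy sparse), rows = genes,
        columns = spots.  Non-negative.
    gene_ids, spot_ids
        Unique string identifiers for rows and columns respectively.
    state
        Processing stage; transitions only move forward through
        ``raw_counts -> normalized -> log_transformed -> hvg_subset``.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    state: State = "raw_counts"

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.spot_ids = _check_ids(self.spot_ids, "spot")
        M, N = self.values.shape
        if M != len(self.gene_ids) or N != len(self.spot_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        if self.state not in _STATE_ORDER:
            raise ValueError(f"unknown state {self.state!r}")
        mn = self.values.min() if not sp.issparse(self.values) else self.values.min()
        if mn < 0:
            raise ValueError("expression values must be non-negative")
        if self.state == "raw_counts":
            dat = self.values.data if sp.issparse(self.values) else self.values
            if not np.allclose(dat, np.round(dat)):
                raise ValueError("raw_counts state requires integer values")

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Values as a dense float array (copy if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def _advance(self, new_state: State, **changes) -> "ExpressionMatrix":
        if _STATE_ORDER.index(new_state) <= _STATE_ORDER.index(self.state):
            raise ValueError(f"illegal state transition {self.state} -> {new_state}")
        return replace(self, state=new_state, **changes)


@dataclass
class SpatialCoords:
    """Per-spot 2-D coordinates aligned to an :class:`ExpressionMatrix`."""

    spot_ids: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.spot_ids = _check_ids(self.spot_ids, "spot")
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be N x 2")
        if len(self.spot_ids) != self.xy.shape[0]:
            raise ValueError("spot_ids length does not match xy")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite coordinates")

    def check_aligned(self, X: ExpressionMatrix) -> None:
        if list(self.spot_ids) != list(X.spot_ids):
            raise ValueError("coordinate spot_ids do not match expression spot_ids")


@dataclass
class QcReport:
    """Per-step record of items removed by quality control."""

    rows: list = field(default_factory=list)  # (step, items_removed, items_remaining)

    def add(self, step: str, removed: int, remaining: int) -> None:
        self.rows.append((step, int(removed), int(remaining)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["step", "items_removed", "items_remaining"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_id_column(path: pathlib.Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None)
    return df.iloc[:, 0].astype(str).to_numpy(dtype=object)


def _find_companion(d: pathlib.Path, stem: str) -> pathlib.Path:
    for name in (f"{stem}.tsv", f"{stem}.tsv.gz", "genes.tsv", "genes.tsv.gz") if stem == "features" else (f"{stem}.tsv", f"{stem}.tsv.gz"):
        p = d / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing MTX companion file {stem}.tsv(.gz) in {d}")


def read_expression(
    path,
    format: str = "mtx_dir",
    spots_as_rows: bool = False,
    state: State = "raw_counts",
) -> ExpressionMatrix:
    """Read a raw count matrix from a 10x-style MTX directory or a dense table.

    Parameters
    ----------
    path
        Directory containing ``matrix.mtx``, ``features.tsv`` (or
        ``genes.tsv``) and ``barcodes.tsv`` for ``format='mtx_dir'``; a single
        file for ``'csv'``/``'tsv'`` with a header row of spot ids and an
        index column of gene ids.
    spots_as_rows
        If True the table on disk is spots x genes and is transposed on load.

    Returns
    -------
    ExpressionMatrix in state ``raw_counts`` (genes x spots).
    """
    path = pathlib.Path(path)
    if format == "mtx_dir":
        if not path.is_dir():
            raise FileNotFoundError(f"{path} is not a directory")
        mtx = None
        for name in ("matrix.mtx", "matrix.mtx.gz"):
            if (path / name).exists():
                mtx = path / name
        if mtx is None:
            raise FileNotFoundError(f"missing MTX companion file matrix.mtx(.gz) in {path}")
        values = scipy.io.mmread(mtx).tocsr()
        gene_ids = _read_id_column(_find_companion(path, "features"))
        spot_ids = _read_id_column(_find_companion(path, "barcodes"))
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        for ci, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                ri = int(np.where(bad.isna())[0][0])
                raise ValueError(
                    f"non-numeric cell at row {df.index[ri]!r}, column {col!r}"
                )
        values = df.to_numpy(dtype=float)
        gene_ids = df.index.astype(str).to_numpy(dtype=object)
        spot_ids = np.asarray([str(c) for c in df.columns], dtype=object)
    else:
        raise ValueError(f"unknown format {format!r}")

    if spots_as_rows:
        values = values.T
        gene_ids, spot_ids = spot_ids, gene_ids

    if state == "raw_counts":
        dat = values.data if sp.issparse(values) else values
        if np.allclose(dat, np.round(dat)):
            if sp.issparse(values):
                values = values.astype(np.int64)
            else:
                values = np.round(values).astype(np.int64)
    return ExpressionMatrix(values=values, gene_ids=gene_ids, spot_ids=spot_ids, state=state)


def write_expression(X: ExpressionMatrix, path, format: str = "mtx_dir") -> None:
    """Write an expression matrix in any of the supported dialects."""
    path = pathlib.Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(X.values))
        pd.DataFrame({0: X.gene_ids}).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
        pd.DataFrame({0: X.spot_ids}).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        pd.DataFrame(X.dense(), index=X.gene_ids, columns=X.spot_ids).to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_coords(path) -> SpatialCoords:
    """Read spot coordinates from a CSV/TSV with columns spot_id, x, y."""
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("spot_id", "x", "y"):
        if needed not in cols:
            raise ValueError(f"coordinate file missing column {needed!r}")
    return SpatialCoords(
        spot_ids=df[cols["spot_id"]].astype(str).to_numpy(dtype=object),
        xy=df[[cols["x"], cols["y"]]].to_numpy(dtype=float),
    )


def write_coords(coords: SpatialCoords, path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    pd.DataFrame(
        {"spot_id": coords.spot_ids, "x": coords.xy[:, 0], "y": coords.xy[:, 1]}
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def qc_filter(
    X: ExpressionMatrix,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 100,
    report: QcReport | None = None,
) -> ExpressionMatrix:
    """Remove near-silent genes, then near-empty spots.

    A gene is kept if it has strictly positive expression in at least
    ``min_cells_per_gene`` spots; afterwards a spot is kept if it expresses at
    least ``min_genes_per_cell`` of the remaining genes.  The gene filter runs
    first; the order matters and is fixed.
    """
    if X.state != "raw_counts":
        raise ValueError("qc_filter expects raw counts")
    V = X.values
    detected = (V > 0)
    if sp.issparse(V):
        cells_per_gene = np.asarray(detected.sum(axis=1)).ravel()
    else:
        cells_per_gene = detected.sum(axis=1)
    gene_keep = cells_per_gene >= min_cells_per_gene
    if not gene_keep.any():
        raise ValueError("empty matrix after QC")
    V2 = V[gene_keep, :]
    det2 = V2 > 0
    if sp.issparse(V2):
        genes_per_cell = np.asarray(det2.sum(axis=0)).ravel()
    else:
        genes_per_cell = det2.sum(axis=0)
    spot_keep = genes_per_cell >= min_genes_per_cell
    if not spot_keep.any():
        raise ValueError("empty matrix after QC")
    if report is not None:
        report.add("gene_filter", int((~gene_keep).sum()), int(gene_keep.sum()))
        report.add("cell_filter", int((~spot_keep).sum()), int(spot_keep.sum()))
    return ExpressionMatrix(
        values=V2[:, spot_keep],
        gene_ids=X.gene_ids[gene_keep],
        spot_ids=X.spot_ids[spot_keep],
        state="raw_counts",
    )


def normalize_log(X: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Total-count normalize each spot to ``scale``, then apply log1p.

    Each spot column is divided by its total so all spots carry the same
    total signal, multiplied by ``scale`` (1e4 by default) and transformed
    with ``log(1 + v)``.
    """
    if X.state != "raw_counts":
        raise ValueError("normalize_log expects raw counts (run qc_filter first)")
    if scale <= 0:
        raise ValueError("scale must be positive")
    V = X.values
    totals = np.asarray(V.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        zero = list(X.spot_ids[totals == 0])
        raise ValueError(f"zero-total spot columns: {zero}")
    if sp.issparse(V):
        out = V.tocsc().astype(float)
        out = out.multiply(scale / totals[None, :]).tocsr()
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(V.astype(float) / totals[None, :] * scale)
    return X._advance("log_transformed", values=out)


def select_hvg(X: ExpressionMatrix, n_top: int = 3000, n_bins: int = 20) -> ExpressionMatrix:
    """Keep the ``n_top`` most highly variable genes.

    Dispersion = variance / mean of the ``expm1`` of the log-normalized
    values, z-scored within ``n_bins`` mean-quantile bins; the genes with
    the largest normalized dispersion are retained in their input order.
    Ties are broken by higher mean, then by input order.  If the matrix has
    at most ``n_top`` genes it is returned with only the state advanced.
    """
    if X.state != "log_transformed":
        raise ValueError("select_hvg expects log-transformed input")
    if n_top <= 0:
        raise ValueError("n_top must be >= 1")
    M = X.n_genes
    if M <= n_top:
        return X._advance("hvg_subset")
    E = np.expm1(X.dense())
    mean = E.mean(axis=1)
    var = E.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # quantile bins on the mean (ties share a bin); z-score dispersion per bin
    edges = np.quantile(mean, np.linspace(0, 1, n_bins + 1))[1:-1]
    bin_of = np.searchsorted(edges, mean, side="right")
    norm_disp = np.zeros(M)
    for b in np.unique(bin_of):
        idx = bin_of == b
        d = disp[idx]
        sd = d.std(ddof=1) if idx.sum() > 1 else 0.0
        norm_disp[idx] = (d - d.mean()) / sd if sd > 0 else 0.0
    # rank: higher norm_disp first, ties -> higher mean, then input order
    key = np.lexsort((np.arange(M), -mean, -norm_disp))
    keep = np.zeros(M, dtype=bool)
    keep[key[:n_top]] = True
    return X._advance(
        "hvg_subset",
        values=X.values[keep, :],
        gene_ids=X.gene_ids[keep],
    )
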
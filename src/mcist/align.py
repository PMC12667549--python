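"""Alignment of expression-topology embeddings with a spatial embedding.

Each multiscale topological PCA embedding Q_coexpr is paired with a spatial
embedding Z (the output of a spatially informed encoder, loaded from file,
or the built-in baseline encoder) by solving the cross-product eigenproblem

    (Z^T Q_coexpr)(Q_coexpr^T Z) q = lambda q,

whose eigenvectors/eigenvalues are obtained from the singular value
decomposition of the (column-centered) cross-product M = Z^T Q_coexpr:
q are left singular vectors, lambda the squared singular values (the shared
squared correlation captured by each canonical pair), and the paired
direction p = M^T q / lambda, re-normalized to unit length.  Note this is
the literal cross-product problem — no within-view whitening — so it is a
partial-least-squares flavor of canonical correlation; ``whiten=True``
gives the classical CCA variant.

The aligned feature matrix concatenates both views' canonical scores:
F = [Z q_1..q_c | Q p_1..p_c], ordered by descending lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .io_prep import ExpressionMatrix, SpatialCoords

__all__ = [
    "SpatialEmbedding",
    "AlignedEmbedding",
    "baseline_spatial_embedding",
    "load_embedding",
    "write_embedding",
    "cca_align",
    "align_all",
]


@dataclass
class SpatialEmbedding:
    """Per-spot spatial feature matrix Z (N x d_s)."""

    spot_ids: np.ndarray
    Z: np.ndarray
    source: str = "external_file"

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("non-finite values in spatial embedding")
        if len(self.spot_ids) != self.Z.shape[0]:
            raise ValueError("spot_ids length does not match embedding rows")


@dataclass
class AlignedEmbedding:
    """CCA-aligned features for one scale combination.

    F is N x 2c (both views' canonical scores); lambdas are the squared
    singular values of the cross-product, sorted non-increasing in [0, 1+eps]
    when both views are orthonormal.
    """

    zeta: tuple
    F: np.ndarray
    lambdas: np.ndarray

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(np.diff(self.lambdas) > 1e-12):
            raise ValueError("lambdas must be non-increasing")


def _sign_fix(A: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(A), axis=0)
    s = np.sign(A[idx, np.arange(A.shape[1])])
    s[s == 0] = 1.0
    return A * s


def baseline_spatial_embedding(
    X: ExpressionMatrix,
    coords: SpatialCoords,
    k_spatial: int = 6,
    rounds: int = 2,
    n_comp: int = 30,
    seed: int = 0,
) -> SpatialEmbedding:
    """Simple spatially informed encoder: smooth, then project.

    Builds a kNN graph on the spot coordinates, averages each spot's
    expression with its spatial neighbors (including itself) for ``rounds``
    iterations, and projects the smoothed spots onto their top ``n_comp``
    principal components.  A deterministic desk-scale stand-in for deep
    spatial encoders; ``rounds=0`` is plain expression PCA.
    """
    coords.check_aligned(X)
    N = X.n_spots
    if k_spatial >= N:
        raise ValueError("k_spatial must be < number of spots")
    P = coords.xy
    d2 = ((P[:, None, :] - P[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nbr = np.argsort(d2, axis=1, kind="stable")[:, :k_spatial]

    S = X.dense().T  # spots x genes
    for _ in range(rounds):
        S = (S + S[nbr].sum(axis=1)) / (k_spatial + 1)
    S = S - S.mean(axis=0, keepdims=True)
    n_comp = min(n_comp, min(S.shape))
    _, sv, Vt = sla.svd(S, full_matrices=False)
    Z = _sign_fix(S @ Vt[:n_comp].T)
    return SpatialEmbedding(spot_ids=X.spot_ids, Z=Z, source="baseline_encoder")


def load_embedding(path, spot_ids) -> SpatialEmbedding:
    """Load an externally computed spatial embedding from CSV/TSV.

    The file needs a ``spot_id`` column (or the first column is used) plus
    numeric feature columns; rows are reordered to match ``spot_ids``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz")) else ","
    df = pd.read_csv(path, sep=sep)
    id_col = "spot_id" if "spot_id" in df.columns else df.columns[0]
    df[id_col] = df[id_col].astype(str)
    df = df.set_index(id_col)
    want = [str(s) for s in spot_ids]
    missing = sorted(set(want) - set(df.index))
    extra = sorted(set(df.index) - set(want))
    if missing or extra:
        raise ValueError(f"embedding spots mismatch: missing={missing}, extra={extra}")
    df = df.loc[want]
    try:
        Z = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise ValueError(f"non-numeric embedding column: {e}") from e
    return SpatialEmbedding(spot_ids=np.asarray(want, dtype=object), Z=Z, source="external_file")


def write_embedding(emb: SpatialEmbedding, path) -> None:
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.DataFrame(emb.Z, columns=[f"dim{i}" for i in range(emb.Z.shape[1])])
    df.insert(0, "spot_id", emb.spot_ids)
    df.to_csv(path, sep=sep, index=False)


def cca_align(
    Zs,
    Qc,
    c: int | str = "auto",
    zeta: tuple = (),
    center: bool = True,
    scale: bool = True,
    whiten: bool = False,
) -> AlignedEmbedding:
    """Align a spatial embedding with one tPCA embedding.

    Solves the cross-product eigenproblem by SVD of M = Zs^T Qc after
    column centering and unit-norm column scaling (both optional).  The
    scaling makes the entries of M correlations, so the lambdas are squared
    correlations bounded by 1 whenever each view's columns are mutually
    orthogonal (as for the orthonormal tPCA embedding); there is still no
    within-view whitening unless ``whiten=True`` (classical CCA).
    ``c='auto'`` keeps every canonical pair with lambda > 1e-10; a rank-0
    cross-product is an error ("no shared signal").
    """
    Z = Zs.Z if isinstance(Zs, SpatialEmbedding) else np.asarray(Zs, dtype=float)
    Q = np.asarray(Qc, dtype=float)
    if Z.shape[0] != Q.shape[0]:
        raise ValueError("views disagree on spot count")
    if center:
        Z = Z - Z.mean(axis=0, keepdims=True)
        Q = Q - Q.mean(axis=0, keepdims=True)
    if scale:
        Z = Z / np.maximum(np.linalg.norm(Z, axis=0, keepdims=True), 1e-30)
        Q = Q / np.maximum(np.linalg.norm(Q, axis=0, keepdims=True), 1e-30)
    if whiten:
        Z = _whiten(Z)
        Q = _whiten(Q)
    M = Z.T @ Q
    u, s, vt = sla.svd(M, full_matrices=False)
    lam = s**2
    if c == "auto":
        c = int(np.sum(lam > 1e-10))
        if c == 0:
            raise ValueError("no shared signal: cross-product has rank 0")
    c = int(c)
    if not 1 <= c <= min(Z.shape[1], Q.shape[1]):
        raise ValueError(f"c={c} out of range")
    qv = _sign_fix(u[:, :c])
    # p = M^T q / lambda, unit-normalized; equals the right singular vector
    pv = M.T @ qv
    norms = np.linalg.norm(pv, axis=0)
    norms[norms == 0] = 1.0
    pv = pv / norms
    F = np.concatenate([Z @ qv, Q @ pv], axis=1)
    return AlignedEmbedding(zeta=tuple(zeta), F=F, lambdas=lam[:c])


def _whiten(A: np.ndarray) -> np.ndarray:
    u, s, _ = sla.svd(A, full_matrices=False)
    keep = s > 1e-12 * (s[0] if len(s) else 1.0)
    return u[:, keep]


def align_all(Zs: SpatialEmbedding, scale_embeddings, c="auto", **kwargs) -> list:
    """Apply :func:`cca_align` to every (zeta, embedding) pair, preserving order."""
    out = []
    for zeta, res in scale_embeddings:
        Q = res.Q if hasattr(res, "Q") else res
        out.append(cca_align(Zs, Q, c=c, zeta=zeta, **kwargs))
    return out
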
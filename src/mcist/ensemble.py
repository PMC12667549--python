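"""Ensemble clustering of aligned embeddings into consensus spatial domains.

Every aligned scale-combination embedding is clustered independently (model
based Gaussian mixture, or Leiden on a shared-neighbor graph with the
resolution tuned by bisection to hit the requested cluster count).  The
member partitions are summarized by a co-association matrix C whose entry
C_ij is the fraction of members placing spots i and j in the same cluster;
average-linkage agglomerative clustering of the distance 1 - C cut at the
requested number of domains yields the final spatial domains.

The Residue-Similarity Index (RSI) scores a labeled embedding by contrasting
between-class separation (residue: each spot's summed distance to spots of
other classes, normalized by the maximum) with within-class compactness
(similarity: mean of 1 - d/d_max over same-class partners).  RSI needs no
ground truth, so it can select the best single scale combination when one
embedding is wanted instead of an ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as hier
import scipy.spatial.distance as ssd
from sklearn import metrics as skmetrics
from sklearn.mixture import GaussianMixture

from .align import SpatialEmbedding, align_all, baseline_spatial_embedding
from .graphs import knn_filtration, zeta_grid
from .io_prep import ExpressionMatrix, SpatialCoords
from .tpca import TpcaConfig, embed_all_scales

__all__ = [
    "ClusterLabels",
    "CoAssociation",
    "RsiReport",
    "ConsensusResult",
    "cluster_embedding",
    "co_association",
    "consensus_cluster",
    "rsi",
    "select_by_rsi",
    "nmi",
    "ari",
    "run_mcist",
]


@dataclass
class ClusterLabels:
    """Integer cluster assignment per spot, labels compacted to 0..K-1."""

    spot_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.spot_ids) != len(self.labels):
            raise ValueError("spot_ids and labels length mismatch")
        # compact to consecutive labels in order of first appearance
        _, inv = np.unique(self.labels, return_inverse=True)
        self.labels = inv

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


@dataclass
class CoAssociation:
    """N x N co-clustering frequency matrix (symmetric, unit diagonal)."""

    C: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must be square")


@dataclass
class RsiReport:
    rsi: float
    per_sample_residue: np.ndarray
    per_sample_similarity: np.ndarray


@dataclass
class ConsensusResult:
    """Final spatial domains plus the evidence that produced them."""

    domains: ClusterLabels
    member_labelsets: list
    co_association: CoAssociation | None
    zetas: list
    rsi_reports: list = field(default_factory=list)
    selected_embedding: int | None = None
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-embedding clustering
# ---------------------------------------------------------------------------


def _leiden_labels(F: np.ndarray, n_clusters: int, seed: int,
                   n_neighbors: int = 15, max_steps: int = 30) -> np.ndarray:
    import igraph
    import leidenalg

    N = F.shape[0]
    n_neighbors = min(n_neighbors, N - 1)
    sq = np.einsum("ij,ij->i", F, F)
    d2 = sq[:, None] + sq[None, :] - 2 * (F @ F.T)
    np.fill_diagonal(d2, np.inf)
    nbr = np.argsort(d2, axis=1, kind="stable")[:, :n_neighbors]
    # shared-nearest-neighbor weights
    sets = [set(row) for row in nbr]
    edges, weights = [], []
    for i in range(N):
        for j in nbr[i]:
            j = int(j)
            if i < j:
                shared = len(sets[i] & sets[j])
                edges.append((i, j))
                weights.append(1.0 + shared)
    g = igraph.Graph(n=N, edges=edges)
    g.es["weight"] = weights

    def labels_at(res: float) -> np.ndarray:
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=res, seed=seed,
        )
        return np.asarray(part.membership, dtype=int)

    lo, hi = 1e-4, 10.0
    best, best_gap = None, np.inf
    for _ in range(max_steps):
        mid = np.sqrt(lo * hi)
        lab = labels_at(mid)
        k = len(np.unique(lab))
        gap = abs(k - n_clusters)
        if gap < best_gap:
            best, best_gap = lab, gap
        if k == n_clusters:
            return lab
        if k < n_clusters:
            lo = mid
        else:
            hi = mid
    import warnings

    warnings.warn(
        f"leiden bisection reached {len(np.unique(best))} clusters "
        f"(requested {n_clusters})"
    )
    return best


def cluster_embedding(F, method: str, n_clusters: int, seed: int = 0,
                      spot_ids=None) -> ClusterLabels:
    """Cluster one feature matrix into ``n_clusters`` groups.

    ``method='gmm'``: full-covariance Gaussian mixture fit by EM with
    k-means initialization and 10 restarts, keeping the best likelihood
    (a model-based stand-in for Mclust).  ``method='leiden'``: Leiden on a
    shared-nearest-neighbor graph, resolution found by bisection so the
    cluster count matches (closest achievable otherwise, with a warning).
    Deterministic under ``seed``.
    """
    F = np.asarray(F, dtype=float)
    N = F.shape[0]
    if n_clusters > N:
        raise ValueError("n_clusters exceeds number of spots")
    if spot_ids is None:
        spot_ids = np.arange(N).astype(object)
    if method == "gmm":
        gm = GaussianMixture(
            n_components=n_clusters, covariance_type="full", n_init=10,
            init_params="kmeans", random_state=seed, reg_covar=1e-6,
        )
        labels = gm.fit_predict(F)
    elif method == "leiden":
        labels = _leiden_labels(F, n_clusters, seed)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return ClusterLabels(spot_ids=np.asarray(spot_ids, dtype=object), labels=labels)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def co_association(labelsets) -> CoAssociation:
    """C_ij = fraction of member partitions assigning i and j to one cluster."""
    if len(labelsets) == 0:
        raise ValueError("need at least one label set")
    arrs = [ls.labels if isinstance(ls, ClusterLabels) else np.asarray(ls) for ls in labelsets]
    N = len(arrs[0])
    if any(len(a) != N for a in arrs):
        raise ValueError("label sets have mismatched lengths")
    C = np.zeros((N, N))
    for a in arrs:
        C += (a[:, None] == a[None, :])
    C /= len(arrs)
    return CoAssociation(C=C)


def consensus_cluster(C, n_domains: int, linkage: str = "average",
                      spot_ids=None) -> ClusterLabels:
    """Agglomerative clustering of distance 1 - C, cut at ``n_domains``."""
    Cm = C.C if isinstance(C, CoAssociation) else np.asarray(C, dtype=float)
    N = Cm.shape[0]
    if n_domains > N:
        raise ValueError("n_domains exceeds number of spots")
    D = 1.0 - Cm
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    Z = hier.linkage(ssd.squareform(D, checks=False), method=linkage)
    labels = hier.fcluster(Z, t=n_domains, criterion="maxclust") - 1
    if spot_ids is None:
        spot_ids = np.arange(N).astype(object)
    return ClusterLabels(spot_ids=np.asarray(spot_ids, dtype=object), labels=labels)


# ---------------------------------------------------------------------------
# RSI and agreement metrics
# ---------------------------------------------------------------------------


def rsi(F, labels) -> RsiReport:
    """Residue-Similarity Index of a labeled embedding.

    residue_i = (sum of distances from i to all other-class spots) scaled by
    its maximum over spots; similarity_i = mean over same-class partners of
    1 - d/d_max (1 for singletons); rsi = mean of (residue + similarity)/2.
    Requires at least two classes.
    """
    F = np.asarray(F, dtype=float)
    lab = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels, dtype=int)
    if len(np.unique(lab)) < 2:
        raise ValueError("RSI undefined for one cluster")
    D = ssd.squareform(ssd.pdist(F))
    d_max = D.max()
    if d_max == 0:
        raise ValueError("all points identical: RSI undefined")
    other = lab[:, None] != lab[None, :]
    r_raw = (D * other).sum(axis=1)
    residue = r_raw / r_raw.max()
    sim = np.ones(len(lab))
    same = (~other) & ~np.eye(len(lab), dtype=bool)
    counts = same.sum(axis=1)
    nz = counts > 0
    sim[nz] = ((1.0 - D / d_max) * same).sum(axis=1)[nz] / counts[nz]
    return RsiReport(
        rsi=float(np.mean((residue + sim) / 2.0)),
        per_sample_residue=residue,
        per_sample_similarity=sim,
    )


def select_by_rsi(candidates) -> int:
    """Index of the (F, labels) candidate with maximal RSI (ties -> lowest)."""
    if len(candidates) == 0:
        raise ValueError("no candidates")
    scores = [rsi(F, lab).rsi for F, lab in candidates]
    return int(np.argmax(scores))


def _label_arrays(a, b):
    la = a.labels if isinstance(a, ClusterLabels) else np.asarray(a, dtype=int)
    lb = b.labels if isinstance(b, ClusterLabels) else np.asarray(b, dtype=int)
    if len(la) != len(lb):
        raise ValueError("label length mismatch")
    return la, lb


def nmi(a, b) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    la, lb = _label_arrays(a, b)
    return float(skmetrics.normalized_mutual_info_score(la, lb, average_method="arithmetic"))


def ari(a, b) -> float:
    """Adjusted Rand index (permutation-model chance correction)."""
    la, lb = _label_arrays(a, b)
    return float(skmetrics.adjusted_rand_score(la, lb))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_mcist(
    X: ExpressionMatrix,
    coords: SpatialCoords | None = None,
    spatial_embedding: SpatialEmbedding | None = None,
    n_domains: int = 5,
    ks=(15, 12, 9, 6),
    method: str = "gmm",
    mode: str = "ensemble",
    tpca_config: TpcaConfig | None = None,
    c="auto",
    linkage: str = "average",
    seed: int = 0,
    log=None,
) -> ConsensusResult:
    """Run the full multiscale pipeline on a preprocessed expression matrix.

    Stages: kNN filtration of persistent Laplacians on expression space ->
    one topological PCA embedding per scale combination -> alignment of each
    with the spatial embedding (the baseline encoder when only coordinates
    are given) -> per-member clustering -> co-association matrix ->
    agglomerative consensus.  ``mode='rsi_select'`` instead adopts the
    partition of the single aligned embedding maximizing RSI.  Fully
    deterministic under ``seed``; member clusterings derive child seeds from
    the member index plus the global seed.
    """
    if X.state not in ("log_transformed", "hvg_subset"):
        raise ValueError("run_mcist expects a log-transformed or HVG-subset matrix")
    if mode not in ("ensemble", "rsi_select"):
        raise ValueError(f"unknown mode {mode!r}")
    _log = log or (lambda *a, **k: None)

    if spatial_embedding is None:
        if coords is None:
            raise ValueError("need coords or a spatial embedding")
        coords.check_aligned(X)
        _log("building baseline spatial embedding")
        spatial_embedding = baseline_spatial_embedding(X, coords, seed=seed)
    elif list(spatial_embedding.spot_ids) != list(X.spot_ids):
        raise ValueError("spatial embedding spot_ids do not match expression")

    cfg = tpca_config or TpcaConfig(seed=seed)
    _log(f"kNN filtration at scales {tuple(ks)}")
    filt = knn_filtration(X, ks=ks)
    _log(f"solving tPCA for {2 ** filt.p - 1} scale combinations")
    scale_embeddings = embed_all_scales(X, filt, cfg)
    _log("aligning with spatial embedding")
    aligned = align_all(spatial_embedding, scale_embeddings, c=c)
    zetas = [a.zeta for a in aligned]

    _log(f"clustering {len(aligned)} members ({method})")
    members = [
        cluster_embedding(a.F, method=method, n_clusters=n_domains,
                          seed=seed + 1000 * (i + 1), spot_ids=X.spot_ids)
        for i, a in enumerate(aligned)
    ]

    config = dict(n_domains=n_domains, ks=tuple(ks), method=method, mode=mode,
                  seed=seed, linkage=linkage)
    rsi_reports = [rsi(a.F, lab) for a, lab in zip(aligned, members)]
    if mode == "rsi_select":
        best = int(np.argmax([r.rsi for r in rsi_reports]))
        _log(f"RSI selected member {best} (zeta={zetas[best]})")
        return ConsensusResult(
            domains=members[best], member_labelsets=members,
            co_association=None, zetas=zetas, rsi_reports=rsi_reports,
            selected_embedding=best, config=config,
        )

    _log("building co-association matrix and consensus")
    C = co_association(members)
    domains = consensus_cluster(C, n_domains, linkage=linkage, spot_ids=X.spot_ids)
    return ConsensusResult(
        domains=domains, member_labelsets=members, co_association=C,
        zetas=zetas, rsi_reports=rsi_reports, selected_embedding=None,
        config=config,
    )
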
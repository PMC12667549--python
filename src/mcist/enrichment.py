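"""Ligand-receptor enrichment on the edges of spatial and expression graphs.

For a graph view G and an LR pair (l, r), the observed score is the mean
symmetric edge product of log-expression,

    s(G, l, r) = (1/|E|) sum_{(i,j) in E} (x_li x_rj + x_lj x_ri) / 2,

which is large when ligand and receptor tend to be expressed on opposite
ends of graph edges.  The null distribution permutes whole spot expression
profiles (preserving within-spot gene-gene correlation) while keeping the
graph fixed; the standardized (observed - null mean) / null sd is the
reported Z-score.  A permutation-invariant pair (e.g. constant expression)
has zero null variance and is flagged degenerate with z = 0.

Null permutations are drawn in spot-id-sorted canonical order, so the
Z-scores are exactly invariant to a joint relabeling of spots in graph and
expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import KnnGraph
from .io_prep import ExpressionMatrix

__all__ = ["LrPair", "EnrichmentTable", "lr_edge_enrichment", "read_lr_pairs"]


@dataclass(frozen=True)
class LrPair:
    ligand_gene: str
    receptor_gene: str


@dataclass
class EnrichmentTable:
    """Rows of (graph_tag, ligand, receptor, observed, null stats, z, degenerate)."""

    frame: pd.DataFrame

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_lr_pairs(path) -> list:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [LrPair(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def _edge_score(a: np.ndarray, b: np.ndarray, ei: np.ndarray, ej: np.ndarray,
                symmetric: bool = True) -> float:
    if symmetric:
        return float(np.mean((a[ei] * b[ej] + a[ej] * b[ei]) / 2.0))
    # directed reading: ligand on the lower-index endpoint only
    return float(np.mean(a[ei] * b[ej]))


def lr_edge_enrichment(
    graphs: dict,
    X: ExpressionMatrix,
    pairs,
    n_perm: int = 1000,
    seed: int = 0,
    allow_self_pairs: bool = False,
    symmetric: bool = True,
) -> EnrichmentTable:
    """Permutation Z-scores of LR edge enrichment per graph view.

    Parameters
    ----------
    graphs
        Mapping of graph tag -> :class:`~mcist.graphs.KnnGraph` over the
        spots of ``X`` (e.g. a spatial graph plus each filtration scale).
    pairs
        Iterable of :class:`LrPair`; both genes must be present in ``X``.
    n_perm
        Number of profile permutations for the null (>= 100).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pairs = list(pairs)
    gene_pos = {g: i for i, g in enumerate(X.gene_ids)}
    for p in pairs:
        for g in (p.ligand_gene, p.receptor_gene):
            if g not in gene_pos:
                raise ValueError(f"gene {g!r} absent from expression matrix")
        if p.ligand_gene == p.receptor_gene and not allow_self_pairs:
            raise ValueError(f"self-pair {p.ligand_gene!r} not allowed")
    V = X.dense()
    N = X.n_spots

    # canonical (spot-id-sorted) order makes the null invariant to relabeling
    canon = np.argsort(np.asarray([str(s) for s in X.spot_ids]), kind="stable")
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(N) for _ in range(n_perm)])

    rows = []
    for tag, g in graphs.items():
        if not isinstance(g, KnnGraph):
            raise TypeError(f"graph {tag!r} is not a KnnGraph")
        if g.n != N:
            raise ValueError(f"graph {tag!r} spot count mismatch")
        e = g.edge_array
        if len(e) == 0:
            raise ValueError(f"graph {tag!r} has no edges")
        ei, ej = e[:, 0], e[:, 1]
        for p in pairs:
            a = V[gene_pos[p.ligand_gene]]
            b = V[gene_pos[p.receptor_gene]]
            obs = _edge_score(a, b, ei, ej, symmetric)
            null = np.empty(n_perm)
            for t in range(n_perm):
                # profile t of canonical slot pi(t) moves to canonical slot t
                ap = np.empty(N)
                bp = np.empty(N)
                ap[canon] = a[canon[perms[t]]]
                bp[canon] = b[canon[perms[t]]]
                null[t] = _edge_score(ap, bp, ei, ej, symmetric)
            mu, sd = float(null.mean()), float(null.std(ddof=0))
            degenerate = sd == 0.0
            z = 0.0 if degenerate else (obs - mu) / sd
            rows.append((tag, p.ligand_gene, p.receptor_gene, obs, mu, sd, z, degenerate))
    frame = pd.DataFrame(
        rows,
        columns=["graph_tag", "ligand", "receptor", "observed_score",
                 "null_mean", "null_sd", "z", "degenerate"],
    )
    return EnrichmentTable(frame=frame)
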
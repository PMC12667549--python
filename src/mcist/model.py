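"""Model/Results front end for the multiscale spatial domain pipeline.

`MCIST` is constructed from data (an expression matrix plus spot coordinates
or a precomputed spatial embedding); `fit()` runs the multiscale pipeline
and returns an `MCISTResults` carrying the consensus domains, per-member
partitions, the co-association matrix, RSI diagnostics and a `summary()`
table.  Plotting hangs off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io_prep
from .align import SpatialEmbedding
from .ensemble import ConsensusResult, run_mcist
from .io_prep import ExpressionMatrix, SpatialCoords
from .tpca import TpcaConfig

__all__ = ["MCIST", "MCISTResults"]


class MCIST:
    """Multiscale cell-cell interactive spatial transcriptomics model.

    Parameters
    ----------
    expression
        Preprocessed :class:`~mcist.io_prep.ExpressionMatrix`
        (log-transformed or HVG subset), or raw counts together with
        ``preprocess=True``.
    coords
        Spot coordinates (used by the baseline spatial encoder) — or pass
        ``spatial_embedding`` from a deep spatial encoder instead.
    n_domains
        Number of spatial domains to call.
    ks
        kNN filtration schedule in expression space, strictly decreasing.
    method
        Per-member clustering: ``'gmm'`` (model-based) or ``'leiden'``.
    mode
        ``'ensemble'`` (co-association consensus, default) or
        ``'rsi_select'`` (adopt the single best-RSI member).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        coords: SpatialCoords | None = None,
        spatial_embedding: SpatialEmbedding | None = None,
        n_domains: int = 5,
        ks=(15, 12, 9, 6),
        method: str = "gmm",
        mode: str = "ensemble",
        tpca_config: TpcaConfig | None = None,
        preprocess: bool = False,
        n_hvg: int = 3000,
        qc_min_cells: int = 3,
        qc_min_genes: int = 100,
    ):
        if preprocess:
            expression = io_prep.qc_filter(expression, qc_min_cells, qc_min_genes)
            expression = io_prep.normalize_log(expression)
            expression = io_prep.select_hvg(expression, n_top=n_hvg)
            if coords is not None:
                keep = pd.Index(coords.spot_ids).get_indexer(expression.spot_ids)
                coords = SpatialCoords(spot_ids=expression.spot_ids,
                                       xy=coords.xy[keep])
        self.expression = expression
        self.coords = coords
        self.spatial_embedding = spatial_embedding
        self.n_domains = n_domains
        self.ks = tuple(ks)
        self.method = method
        self.mode = mode
        self.tpca_config = tpca_config

    @classmethod
    def from_files(cls, expr_path, coords_path, format: str = "mtx_dir",
                   preprocess: bool = True, **kwargs) -> "MCIST":
        X = io_prep.read_expression(expr_path, format=format)
        coords = io_prep.read_coords(coords_path)
        return cls(X, coords=coords, preprocess=preprocess, **kwargs)

    def fit(self, seed: int = 0, log=None) -> "MCISTResults":
        """Run the pipeline; deterministic under ``seed``."""
        res = run_mcist(
            self.expression,
            coords=self.coords,
            spatial_embedding=self.spatial_embedding,
            n_domains=self.n_domains,
            ks=self.ks,
            method=self.method,
            mode=self.mode,
            tpca_config=self.tpca_config,
            seed=seed,
            log=log,
        )
        return MCISTResults(self, res)


class MCISTResults:
    """Fitted spatial domains with ensemble diagnostics."""

    def __init__(self, model: MCIST, consensus: ConsensusResult):
        self.model = model
        self.consensus = consensus

    @property
    def domains(self):
        return self.consensus.domains

    @property
    def co_association(self):
        return self.consensus.co_association

    @property
    def rsi_scores(self) -> np.ndarray:
        return np.asarray([r.rsi for r in self.consensus.rsi_reports])

    def domains_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "spot_id": self.domains.spot_ids,
            "domain": self.domains.labels,
        })

    def summary(self) -> str:
        cr = self.consensus
        lines = [
            "MCIST spatial domain detection",
            "=" * 46,
            f"spots                 {self.model.expression.n_spots}",
            f"genes                 {self.model.expression.n_genes}",
            f"filtration scales k   {self.model.ks}",
            f"scale combinations    {len(cr.zetas)}",
            f"member clustering     {cr.config.get('method')}",
            f"mode                  {cr.config.get('mode')}",
            f"domains requested     {cr.config.get('n_domains')}",
            f"domains found         {self.domains.n_clusters}",
        ]
        if cr.selected_embedding is not None:
            lines.append(
                f"RSI-selected member   {cr.selected_embedding} "
                f"(zeta={cr.zetas[cr.selected_embedding]})"
            )
        sizes = np.bincount(self.domains.labels)
        lines.append("domain sizes          " + ", ".join(
            f"{d}:{s}" for d, s in enumerate(sizes)))
        if cr.rsi_reports:
            lines.append("RSI per member        "
                         f"min={self.rsi_scores.min():.3f} "
                         f"max={self.rsi_scores.max():.3f}")
        return "\n".join(lines)

    def plot_domains(self, ax=None):
        """Scatter of spots colored by domain (needs model coordinates)."""
        import matplotlib.pyplot as plt

        if self.model.coords is None:
            raise ValueError("no coordinates available for plotting")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        xy = self.model.coords.xy
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=self.domains.labels,
                        cmap="tab10", s=12)
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        ax.set_title("MCIST spatial domains")
        plt.colorbar(sc, ax=ax, label="domain")
        return ax
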
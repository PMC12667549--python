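import numpy as np
import pytest

from mcist.io_prep import ExpressionMatrix, SpatialCoords


def make_expr(values, state="raw_counts", gene_ids=None, spot_ids=None):
    """Build an ExpressionMatrix from a plain array with auto ids."""
    values = np.asarray(values)
    M, N = values.shape
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids if gene_ids is not None else np.array([f"g{i}" for i in range(M)], dtype=object),
        spot_ids=spot_ids if spot_ids is not None else np.array([f"s{j}" for j in range(N)], dtype=object),
        state=state,
    )


def random_log_expr(n_genes, n_spots, seed=0, scale=1.0):
    """Seeded non-negative matrix tagged log_transformed (solver-ready)."""
    rng = np.random.default_rng(seed)
    vals = scale * np.abs(rng.standard_normal((n_genes, n_spots)))
    return make_expr(vals, state="log_transformed")


@pytest.fixture
def toy_counts():
    """4 genes x 4 spots; gene g3 detected in exactly 2 spots."""
    return make_expr(
        np.array([
            [5, 3, 2, 1],
            [1, 1, 4, 2],
            [2, 6, 1, 3],
            [0, 7, 0, 9],
        ])
    )


@pytest.fixture
def grid_coords():
    def _make(n):
        side = int(np.ceil(np.sqrt(n)))
        xy = np.array([[i % side, i // side] for i in range(n)], dtype=float)
        return SpatialCoords(
            spot_ids=np.array([f"s{j}" for j in range(n)], dtype=object), xy=xy
        )
    return _make
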
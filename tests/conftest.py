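import numpy as np
import pandas as pd
import pytest

from cokappa import CategoryScheme, RatingDataset, WeightedContingencyTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def make_table():
    """Build a square weighted contingency table from raw cell weights."""

    def _make(cells, codes=None, n_sets=100):
        cells = np.asarray(cells, dtype=float)
        cells = cells / cells.sum()
        c = cells.shape[0]
        scheme = CategoryScheme(codes=tuple(codes) if codes else tuple(range(1, c + 1)))
        return WeightedContingencyTable(
            cells=cells, row_scheme=scheme, col_scheme=scheme, n_sets=n_sets
        )

    return _make


@pytest.fixture
def make_symmetric_table(rng):
    """Random table with equal index and neighbor margins (symmetric cells)."""

    def _make(c=4, n_sets=100, rng=rng):
        raw = rng.dirichlet(np.ones(c * c)).reshape(c, c)
        sym = (raw + raw.T) / 2.0
        scheme = CategoryScheme(codes=tuple(range(1, c + 1)))
        return WeightedContingencyTable(
            cells=sym / sym.sum(), row_scheme=scheme, col_scheme=scheme, n_sets=n_sets
        )

    return _make


@pytest.fixture
def make_dataset():
    """Dataset from raw coordinates and one rating column."""

    def _make(coords, ratings=None, item="rating"):
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
        if ratings is None:
            ratings = np.ones(n, dtype=np.int64)
        return RatingDataset(
            ids=np.array([f"p{i}" for i in range(n)]),
            coords=coords,
            ratings=pd.DataFrame({item: np.asarray(ratings, dtype=np.int64)}),
        )

    return _make


def brute_force_neighbors(coords, max_radius, tie_tol=1e-9):
    """O(n^2) all-pairs nearest-neighbor oracle.

    Returns (included, neighbors, distances): for each included point
    index, the sorted tuple of tied nearest-neighbor indices and the
    minimum distance.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    included, neighbors, distances = [], {}, {}
    for i in range(n):
        dmin = d[i].min()
        if dmin > max_radius:
            continue
        included.append(i)
        neighbors[i] = tuple(np.flatnonzero(d[i] <= dmin + tie_tol))
        distances[i] = dmin
    return included, neighbors, distances
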
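"""Weighted index-by-neighbor contingency tables.

For matched set *i* with index rating *j* and ``m_i`` tied neighbors, each
neighbor contributes weight ``1/m_i`` to cell ``(j, k)`` where *k* is the
neighbor's rating.  Dividing by the number of sets yields a table of
proportions ``o_jk`` whose row sums are the index raters' relative counts
``p_j`` and whose column sums are the weighted neighbor relative counts.

Chance expectations downstream use the index margins only, under the
assumption that the nearest neighbors share the index raters' overall
rating distribution; the neighbor margins are kept so the accuracy of that
assumption can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import RatingDataset
from .errors import InvalidInputError
from .geometry import MatchedSet

__all__ = [
    "CategoryScheme",
    "WeightedContingencyTable",
    "build_table",
    "dichotomize",
    "table_long_format",
]


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered category codes with display labels.

    ``informative`` flags the substantive scale points, as opposed to
    indefinite ("cannot say") and missing-answer codes which travel through
    every computation as ordinary categories.
    """

    codes: tuple
    labels: tuple | None = None
    informative: frozenset | None = None

    def __post_init__(self) -> None:
        codes = tuple(int(c) for c in self.codes)
        object.__setattr__(self, "codes", codes)
        if len(set(codes)) != len(codes):
            raise InvalidInputError("category codes must be distinct")
        if len(codes) < 1:
            raise InvalidInputError("a category scheme needs at least one code")
        labels = self.labels
        if labels is None:
            labels = tuple(str(c) for c in codes)
        else:
            labels = tuple(str(l) for l in labels)
            if len(labels) != len(codes):
                raise InvalidInputError("labels must match codes one-to-one")
        object.__setattr__(self, "labels", labels)
        informative = self.informative
        if informative is None:
            informative = frozenset(codes)
        else:
            informative = frozenset(int(c) for c in informative)
            if not informative.issubset(codes):
                raise InvalidInputError("informative codes must be a subset of codes")
        object.__setattr__(self, "informative", informative)

    @property
    def c(self) -> int:
        return len(self.codes)

    def pos(self, code) -> int:
        try:
            return self.codes.index(int(code))
        except ValueError:
            raise InvalidInputError(f"category {code!r} not in scheme {self.codes}") from None

    def label(self, code) -> str:
        return self.labels[self.pos(code)]

    @classmethod
    def from_codes(cls, codes, noninformative=()) -> "CategoryScheme":
        codes = tuple(codes)
        return cls(codes=codes, informative=frozenset(codes) - frozenset(noninformative))


@dataclass(frozen=True)
class WeightedContingencyTable:
    """c×c (or 2×2 dichotomized) table of weighted agreement proportions.

    ``cells[j, k]`` is the proportion ``o_jk``; rows index the index
    rater's category, columns the neighbor's.  Row and column schemes
    coincide for ordinary tables and differ for a cross-category
    dichotomization (a/not-a versus b/not-b).
    """

    cells: np.ndarray
    row_scheme: CategoryScheme
    col_scheme: CategoryScheme
    n_sets: int

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=float)
        object.__setattr__(self, "cells", cells)
        if cells.shape != (self.row_scheme.c, self.col_scheme.c):
            raise InvalidInputError("cells shape must match the category schemes")
        if np.any(cells < -1e-12):
            raise InvalidInputError("cell proportions must be non-negative")
        if abs(cells.sum() - 1.0) > 1e-8:
            raise InvalidInputError("cell proportions must sum to 1")
        if self.n_sets < 1:
            raise InvalidInputError("n_sets must be >= 1")

    @property
    def scheme(self) -> CategoryScheme:
        if not self.is_square:
            raise InvalidInputError("table has distinct row/column schemes")
        return self.row_scheme

    @property
    def is_square(self) -> bool:
        return self.row_scheme.codes == self.col_scheme.codes

    @property
    def index_margins(self) -> np.ndarray:
        """Index raters' relative counts p_j (row sums)."""
        return self.cells.sum(axis=1)

    @property
    def neighbor_margins(self) -> np.ndarray:
        """Weighted neighbor relative counts (column sums)."""
        return self.cells.sum(axis=0)

    def index_margin(self, code) -> float:
        return float(self.index_margins[self.row_scheme.pos(code)])

    def cell(self, a, b) -> float:
        return float(self.cells[self.row_scheme.pos(a), self.col_scheme.pos(b)])


def build_table(
    sets: list[MatchedSet] | tuple[MatchedSet, ...],
    data: RatingDataset,
    item: str,
    scheme: CategoryScheme,
) -> WeightedContingencyTable:
    """Cross-tabulate index against neighbor ratings with 1/m weights."""
    if not sets:
        raise InvalidInputError("cannot build a table from an empty set list")
    if scheme.c < 2:
        raise InvalidInputError("build_table requires a scheme with at least 2 categories")
    values = data.rating_values(item)
    mapped = np.full(data.n, -1, dtype=np.int64)
    for j, code in enumerate(scheme.codes):
        mapped[values == code] = j

    n_sets = len(sets)
    index_pos = np.fromiter((s.index_pos for s in sets), dtype=np.int64, count=n_sets)
    m = np.fromiter((s.m for s in sets), dtype=np.int64, count=n_sets)
    nb_pos = np.concatenate([np.asarray(s.neighbor_pos, dtype=np.int64) for s in sets])
    weights = np.repeat(1.0 / m, m)
    set_of = np.repeat(np.arange(n_sets), m)

    rows = mapped[index_pos]
    cols = mapped[nb_pos]
    if np.any(rows < 0) or np.any(cols < 0):
        bad = set(values[index_pos[rows < 0]]) | set(values[nb_pos[cols < 0]])
        raise InvalidInputError(f"rating code(s) {sorted(bad)} outside scheme {scheme.codes}")

    c = scheme.c
    flat = np.zeros(c * c, dtype=float)
    np.add.at(flat, rows[set_of] * c + cols, weights)
    cells = flat.reshape(c, c) / n_sets
    return WeightedContingencyTable(
        cells=cells, row_scheme=scheme, col_scheme=scheme, n_sets=n_sets
    )


def dichotomize(table: WeightedContingencyTable, a, b) -> WeightedContingencyTable:
    """Collapse to the 2×2 {a, not-a} × {b, not-b} table.

    ``a == b`` gives the a / not-a table whose overall kappa equals the
    category-specific kappa of the full table.
    """
    ra = np.array([c == int(a) for c in table.row_scheme.codes])
    cb = np.array([c == int(b) for c in table.col_scheme.codes])
    if not ra.any():
        raise InvalidInputError(f"category {a!r} not in scheme {table.row_scheme.codes}")
    if not cb.any():
        raise InvalidInputError(f"category {b!r} not in scheme {table.col_scheme.codes}")
    cells = table.cells
    out = np.array(
        [
            [cells[ra][:, cb].sum(), cells[ra][:, ~cb].sum()],
            [cells[~ra][:, cb].sum(), cells[~ra][:, ~cb].sum()],
        ]
    )
    row_scheme = CategoryScheme(codes=(1, 0), labels=(table.row_scheme.label(a), f"not {table.row_scheme.label(a)}"))
    if int(a) == int(b) and table.is_square:
        col_scheme = row_scheme
    else:
        col_scheme = CategoryScheme(
            codes=(1, 0), labels=(table.col_scheme.label(b), f"not {table.col_scheme.label(b)}")
        )
    return WeightedContingencyTable(
        cells=out, row_scheme=row_scheme, col_scheme=col_scheme, n_sets=table.n_sets
    )


def table_long_format(table: WeightedContingencyTable, item: str) -> pd.DataFrame:
    """Long-format export: observed and chance-expected percentages per cell."""
    p = table.index_margins
    records = []
    for j, cj in enumerate(table.row_scheme.codes):
        for k, ck in enumerate(table.col_scheme.codes):
            records.append(
                {
                    "item": item,
                    "index_cat": cj,
                    "neighbor_cat": ck,
                    "obs_pct": 100.0 * table.cells[j, k],
                    "exp_pct": 100.0 * p[j] * p[k] if table.is_square else float("nan"),
                }
            )
    return pd.DataFrame.from_records(records)
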
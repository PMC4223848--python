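"""Point-referenced categorical rating data.

A :class:`RatingDataset` holds one row per rater: an opaque identifier,
planar (or lon/lat) coordinates, and one integer rating code per survey
item.  Missing or indefinite answers must be encoded as dedicated category
codes; empty cells are rejected on read so that silent case-wise deletion
can never happen downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = ["RatingDataset", "read_ratings_csv", "write_ratings_csv"]


@dataclass(frozen=True)
class RatingDataset:
    """Raters at point locations with categorical ratings per item.

    Parameters
    ----------
    ids
        One opaque identifier per rater; must be unique.
    coords
        ``(n, 2)`` array of coordinates.  Meters in a common planar
        projection for the Euclidean metric, or (lon, lat) degrees for the
        great-circle metric.
    ratings
        DataFrame with one integer column per item, row-aligned with
        ``ids``/``coords``.
    """

    ids: np.ndarray
    coords: np.ndarray
    ratings: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids)
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise InvalidInputError("coords must be an (n, 2) array")
        n = coords.shape[0]
        if ids.shape != (n,) or len(self.ratings) != n:
            raise InvalidInputError("ids, coords and ratings must have equal length")
        if len(np.unique(ids)) != n:
            raise InvalidInputError("rater ids must be unique")
        if not np.all(np.isfinite(coords)):
            raise InvalidInputError("coordinates must be finite")
        for col in self.ratings.columns:
            values = self.ratings[col]
            if values.isna().any():
                raise InvalidInputError(
                    f"item {col!r} has empty cells; encode missing answers "
                    "as a dedicated category code"
                )
            if not pd.api.types.is_integer_dtype(values):
                raise InvalidInputError(f"item {col!r} must hold integer category codes")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(map(str, self.ratings.columns))

    def rating_values(self, item: str) -> np.ndarray:
        if item not in self.ratings.columns:
            raise InvalidInputError(f"unknown item {item!r}; have {list(self.items)}")
        return self.ratings[item].to_numpy()

    def codes_used(self, item: str) -> tuple[int, ...]:
        """Sorted distinct category codes observed for ``item``."""
        return tuple(int(c) for c in np.unique(self.rating_values(item)))


def read_ratings_csv(path: str | Path, items: list[str] | None = None) -> RatingDataset:
    """Read a delimited ratings file with header ``id,x,y,<item1>,...``.

    Empty cells are an error: the input format requires missing answers to
    carry their own category code.
    """
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InvalidInputError(f"cannot read ratings file {path}: {exc}") from exc
    required = {"id", "x", "y"}
    if not required.issubset(frame.columns):
        raise InvalidInputError(
            f"ratings file must have columns id,x,y,...; got {list(frame.columns)}"
        )
    item_cols = [c for c in frame.columns if c not in required]
    if items is not None:
        unknown = [c for c in items if c not in item_cols]
        if unknown:
            raise InvalidInputError(f"unknown item column(s) {unknown}; file has {item_cols}")
        item_cols = list(items)
    if not item_cols:
        raise InvalidInputError("ratings file has no item columns")
    ratings = frame[item_cols]
    for col in item_cols:
        if ratings[col].isna().any():
            raise InvalidInputError(
                f"item {col!r} has empty cells; encode missing answers as a category code"
            )
        as_float = ratings[col].astype(float)
        if not np.all(as_float == np.round(as_float)):
            raise InvalidInputError(f"item {col!r} has non-integer category codes")
    ratings = ratings.astype(np.int64).reset_index(drop=True)
    return RatingDataset(
        ids=frame["id"].to_numpy(),
        coords=frame[["x", "y"]].to_numpy(dtype=float),
        ratings=ratings,
    )


def write_ratings_csv(data: RatingDataset, path: str | Path) -> None:
    out = pd.DataFrame({"id": data.ids, "x": data.coords[:, 0], "y": data.coords[:, 1]})
    out = pd.concat([out, data.ratings.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)
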
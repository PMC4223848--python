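"""First-order nearest-neighbor matched sets.

Every rater whose nearest other rater lies within a maximum radius becomes
the *index* of one matched set.  All raters tied at exactly the minimum
distance are included as neighbors, each carrying statistical weight
``1/m`` so that a set contributes as though it contained two raters (the
index and one effective neighbor).  Raters with no neighbor inside the
radius are excluded and counted.

Distances are planar Euclidean on projected coordinates by default; a
great-circle metric on (lon, lat) degrees is available.  Tied distances
are detected with an absolute tolerance (default 1e-9 m), far below the
precision of any survey geocoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .dataset import RatingDataset
from .errors import InvalidInputError

__all__ = [
    "NeighborConfig",
    "MatchedSet",
    "NeighborSearchResult",
    "find_nearest_neighbors",
    "EARTH_RADIUS_M",
]

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius

_METRICS = ("planar-euclidean", "great-circle")


@dataclass(frozen=True)
class NeighborConfig:
    """Search settings for matched-set construction.

    ``max_radius`` is in meters for both metrics.  ``tie_tol`` is the
    absolute distance tolerance (meters) within which neighbors count as
    tied at the minimum distance.
    """

    max_radius: float = 500.0
    distance_metric: str = "planar-euclidean"
    tie_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.max_radius > 0:
            raise InvalidInputError("max_radius must be > 0")
        if self.distance_metric not in _METRICS:
            raise InvalidInputError(f"distance_metric must be one of {_METRICS}")
        if self.tie_tol < 0:
            raise InvalidInputError("tie_tol must be >= 0")


@dataclass(frozen=True, slots=True)
class MatchedSet:
    """One index rater with its tied first-order nearest neighbors."""

    index_id: object
    neighbor_ids: tuple
    neighbor_distance: float
    index_pos: int
    neighbor_pos: tuple

    @property
    def m(self) -> int:
        """Number of tied nearest neighbors."""
        return len(self.neighbor_ids)

    @property
    def weight_per_neighbor(self) -> float:
        return 1.0 / self.m


@dataclass(frozen=True)
class NeighborSearchResult:
    """Matched sets plus the raters excluded for isolation."""

    sets: tuple[MatchedSet, ...]
    excluded_ids: tuple
    config: NeighborConfig = field(repr=False)

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)

    @property
    def distances(self) -> np.ndarray:
        return np.array([s.neighbor_distance for s in self.sets], dtype=float)

    def summary(self) -> dict:
        """n sets / n excluded and the 2.5, 50, 97.5 distance percentiles."""
        d = self.distances
        if d.size:
            lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5])
        else:
            lo = med = hi = float("nan")
        return {
            "n_sets": self.n_sets,
            "n_excluded": self.n_excluded,
            "median_distance_m": float(med),
            "p2_5_distance_m": float(lo),
            "p97_5_distance_m": float(hi),
            "max_radius_m": self.config.max_radius,
        }


def _to_search_points(coords: np.ndarray, metric: str) -> np.ndarray:
    if metric == "planar-euclidean":
        return coords
    lonlat = np.radians(coords)
    cos_lat = np.cos(lonlat[:, 1])
    return EARTH_RADIUS_M * np.column_stack(
        [cos_lat * np.cos(lonlat[:, 0]), cos_lat * np.sin(lonlat[:, 0]), np.sin(lonlat[:, 1])]
    )


def _chord_to_meters(chord: np.ndarray, metric: str) -> np.ndarray:
    if metric == "planar-euclidean":
        return chord
    # arc length from chord length on the sphere
    half = np.clip(np.asarray(chord) / (2.0 * EARTH_RADIUS_M), 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_M * np.arcsin(half)


def _meters_to_chord(meters: float, metric: str) -> float:
    if metric == "planar-euclidean":
        return meters
    arc = min(meters / EARTH_RADIUS_M, np.pi)
    return 2.0 * EARTH_RADIUS_M * np.sin(arc / 2.0)


def find_nearest_neighbors(
    data: RatingDataset, cfg: NeighborConfig | None = None
) -> NeighborSearchResult:
    """Build first-order nearest-neighbor matched sets.

    One :class:`MatchedSet` is produced per rater whose nearest other
    rater lies within ``cfg.max_radius``; all raters at the minimum
    distance (within ``cfg.tie_tol``) are included as tied neighbors with
    weight ``1/m``.  Zero distances (co-located residences) are legal;
    self-pairing is not.  Raters without a neighbor in the radius are
    excluded and reported.
    """
    cfg = cfg or NeighborConfig()
    n = data.n
    if n < 2:
        raise InvalidInputError("nearest-neighbor search requires at least 2 raters")
    pts = _to_search_points(data.coords, cfg.distance_metric)
    tree = cKDTree(pts)
    k0 = min(n, 8)
    chord, idx = tree.query(pts, k=k0)
    dist_m = _chord_to_meters(chord, cfg.distance_metric)

    rows = np.arange(n)
    self_mask = idx == rows[:, None]
    d_others = np.where(self_mask, np.inf, dist_m)
    dmin = d_others.min(axis=1)

    sets: list[MatchedSet] = []
    excluded: list = []
    for i in range(n):
        if dmin[i] > cfg.max_radius:
            excluded.append(data.ids[i])
            continue
        cutoff = dmin[i] + cfg.tie_tol
        # the k0 returned candidates may not exhaust the tie group
        if k0 < n and dist_m[i, -1] <= cutoff:
            cand = tree.query_ball_point(
                pts[i], _meters_to_chord(cutoff, cfg.distance_metric) * (1 + 1e-12)
            )
            cand = np.asarray([j for j in cand if j != i])
            cd = _chord_to_meters(
                np.sqrt(((pts[cand] - pts[i]) ** 2).sum(axis=1)), cfg.distance_metric
            )
            take = cand[cd <= cutoff]
        else:
            take = idx[i][(~self_mask[i]) & (d_others[i] <= cutoff)]
        take = np.sort(take)
        sets.append(
            MatchedSet(
                index_id=data.ids[i],
                neighbor_ids=tuple(data.ids[take]),
                neighbor_distance=float(dmin[i]),
                index_pos=i,
                neighbor_pos=tuple(int(j) for j in take),
            )
        )
    return NeighborSearchResult(sets=tuple(sets), excluded_ids=tuple(excluded), config=cfg)
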
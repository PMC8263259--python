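"""Link household clusters to birth-service facilities.

Three linking methods, mirroring how displaced DHS cluster centroids are tied
to a facility census:

* Euclidean buffers — every facility within 5 km (urban) / 10 km (rural)
  great-circle distance of the cluster centroid is linked; the asymmetric radii
  absorb the confidentiality displacement applied to published coordinates.
* Fastest-mode travel time — least-cost travel time on a friction surface
  (minutes-per-metre raster), linking all facilities within a cutoff
  (default two hours).
* Walking time — a pluggable router chain: a primary router is tried first;
  on failure, pairs less than 50 km apart (Haversine) fall through to a
  fallback router; everything else is unreachable.

Unreachable pairs carry ``math.inf`` rather than raising, so that uncalculable
pairs (islands, border facilities, missing road network) flow through the
pipeline as "never linked".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .readiness import ValidationError

EARTH_RADIUS_KM = 6371.0
UNREACHABLE = math.inf

COUNT_CATEGORIES = ("none", "one", "two_plus")


def haversine_km(a, b) -> float | np.ndarray:
    """Great-circle distance in km between (lat, lon) points, spherical earth.

    Accepts scalars or broadcastable arrays of latitudes/longitudes in
    decimal degrees.
    """
    lat1, lon1 = np.asarray(a[0], dtype=float), np.asarray(a[1], dtype=float)
    lat2, lon2 = np.asarray(b[0], dtype=float), np.asarray(b[1], dtype=float)
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
            raise ValidationError("coordinates out of range")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    return float(d) if d.ndim == 0 else d


def pairwise_distance_km(clusters: pd.DataFrame, facilities: pd.DataFrame) -> np.ndarray:
    """(n_clusters, n_facilities) Haversine distance matrix in km."""
    return haversine_km(
        (clusters["lat"].to_numpy()[:, None], clusters["lon"].to_numpy()[:, None]),
        (facilities["lat"].to_numpy()[None, :], facilities["lon"].to_numpy()[None, :]),
    )


@dataclass
class LinkageSummary:
    """Per-cluster linkage result for one linking method."""

    cluster_id: str
    method: str
    linked_facility_ids: frozenset
    count_category: str
    nearest_minutes: float | None = None
    max_linked_score: float | None = None
    score_tercile: str | None = None

    def __post_init__(self):
        n = len(self.linked_facility_ids)
        expected = "none" if n == 0 else ("one" if n == 1 else "two_plus")
        if self.count_category != expected:
            raise ValidationError(
                f"cluster {self.cluster_id}: count_category {self.count_category!r} "
                f"inconsistent with {n} linked facilities"
            )


def _count_category(n: int) -> str:
    return "none" if n == 0 else ("one" if n == 1 else "two_plus")


def buffer_link(
    clusters: pd.DataFrame,
    facilities: pd.DataFrame,
    *,
    urban_radius_km: float = 5.0,
    rural_radius_km: float = 10.0,
    method_name: str = "buffer_5_10km",
) -> list[LinkageSummary]:
    """Link each cluster to all facilities within its stratum radius (inclusive).

    ``clusters`` needs columns cluster_id, lat, lon, urban; ``facilities``
    needs facility_id, lat, lon and should already be filtered to those
    providing birth services. Sub-national boundaries are ignored.
    """
    if len(facilities):
        dist = pairwise_distance_km(clusters, facilities)
    else:
        dist = np.empty((len(clusters), 0))
    radii = np.where(clusters["urban"].to_numpy(bool), urban_radius_km, rural_radius_km)
    fac_ids = facilities["facility_id"].to_numpy()
    out = []
    for i, cid in enumerate(clusters["cluster_id"]):
        linked = frozenset(fac_ids[dist[i] <= radii[i]])
        out.append(LinkageSummary(cid, method_name, linked, _count_category(len(linked))))
    return out


# ---------------------------------------------------------------------------
# Friction-surface travel time
# ---------------------------------------------------------------------------

@dataclass
class FrictionSurface:
    """Georeferenced traversal-cost grid.

    ``values[r, c]`` is the cost of crossing cell (r, c) in minutes per metre
    (``inf`` marks an impassable barrier such as open water). Row 0 is the
    northern edge. The grid lives in a local equirectangular projection about
    the grid's mid-latitude: x east in metres from ``lon0``, y north from
    ``lat0`` (the south-west corner).
    """

    lat0: float
    lon0: float
    cell_size_m: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size_m <= 0:
            raise ValidationError("cell_size_m must be positive")
        if (self.values < 0).any():
            raise ValidationError("friction values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mid_lat(self) -> float:
        nrows = self.values.shape[0]
        return self.lat0 + 0.5 * nrows * self.cell_size_m / _M_PER_DEG_LAT

    def cell_of(self, lat: float, lon: float) -> tuple[int, int] | None:
        """Row/col of the cell containing a point, or None if off-grid."""
        nrows, ncols = self.values.shape
        y = (lat - self.lat0) * _M_PER_DEG_LAT
        x = (lon - self.lon0) * _M_PER_DEG_LAT * math.cos(math.radians(self.mid_lat))
        c = int(math.floor(x / self.cell_size_m))
        r_from_south = int(math.floor(y / self.cell_size_m))
        r = nrows - 1 - r_from_south
        if 0 <= r < nrows and 0 <= c < ncols:
            return r, c
        return None

    def cell_center(self, r: int, c: int) -> tuple[float, float]:
        """(lat, lon) of the centre of cell (r, c)."""
        nrows, _ = self.values.shape
        y = (nrows - 1 - r + 0.5) * self.cell_size_m
        x = (c + 0.5) * self.cell_size_m
        lat = self.lat0 + y / _M_PER_DEG_LAT
        lon = self.lon0 + x / (_M_PER_DEG_LAT * math.cos(math.radians(self.mid_lat)))
        return lat, lon


_M_PER_DEG_LAT = EARTH_RADIUS_KM * 1000.0 * math.pi / 180.0

# 8-connected neighbourhood offsets with step multipliers
_STEPS = [
    (-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
    (-1, -1, math.sqrt(2)), (-1, 1, math.sqrt(2)),
    (1, -1, math.sqrt(2)), (1, 1, math.sqrt(2)),
]


def _grid_graph(surface: FrictionSurface) -> coo_matrix:
    """Sparse 8-connected cost graph: edge = mean cell friction x step length."""
    f = surface.values
    nrows, ncols = f.shape
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    rows, cols, data = [], [], []
    for dr, dc, mult in _STEPS:
        if dr < 0 or (dr == 0 and dc < 0):
            continue  # add each undirected edge once
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        a, b = idx[r0, c0].ravel(), idx[r1, c1].ravel()
        cost = 0.5 * (f[r0, c0] + f[r1, c1]).ravel() * mult * surface.cell_size_m
        ok = np.isfinite(cost)
        rows.append(a[ok])
        cols.append(b[ok])
        data.append(cost[ok])
    n = nrows * ncols
    return coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def travel_time_matrix(
    surface: FrictionSurface,
    origins: Sequence[tuple[float, float]],
    destinations: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Least-cost travel time in minutes for every origin x destination pair.

    Endpoints are snapped to their containing cell; pairs in the same cell get
    0. Endpoints off-grid or on a barrier cell yield ``inf`` (unreachable), as
    do pairs separated by barriers.
    """
    graph = _grid_graph(surface)
    nrows, ncols = surface.shape

    def node(p):
        cell = surface.cell_of(*p)
        if cell is None or not math.isfinite(surface.values[cell]):
            return -1
        return cell[0] * ncols + cell[1]

    onodes = np.array([node(p) for p in origins])
    dnodes = np.array([node(p) for p in destinations])
    valid = np.unique(onodes[onodes >= 0])
    out = np.full((len(onodes), len(dnodes)), UNREACHABLE)
    if valid.size:
        dmat = dijkstra(graph, directed=False, indices=valid)
        pos = {n: i for i, n in enumerate(valid)}
        for i, on in enumerate(onodes):
            if on < 0:
                continue
            row = dmat[pos[on]]
            ok = dnodes >= 0
            out[i, ok] = row[dnodes[ok]]
    return out


def travel_time_minutes(surface: FrictionSurface, a, b) -> float:
    """Least-cost time between two (lat, lon) points; ``inf`` if unreachable."""
    return float(travel_time_matrix(surface, [a], [b])[0, 0])


def link_within_time(
    clusters: pd.DataFrame,
    facilities: pd.DataFrame,
    times: np.ndarray,
    *,
    cutoff_minutes: float = 120.0,
    method_name: str = "fastest_2h",
) -> list[LinkageSummary]:
    """Link every pair with travel time <= cutoff (inclusive).

    ``times`` is the (n_clusters, n_facilities) minute matrix; unreachable
    pairs (inf) are never linked. ``nearest_minutes`` is the minimum over the
    linked set, None when nothing links.
    """
    fac_ids = facilities["facility_id"].to_numpy()
    out = []
    for i, cid in enumerate(clusters["cluster_id"]):
        mask = times[i] <= cutoff_minutes
        linked = frozenset(fac_ids[mask])
        nearest = float(times[i][mask].min()) if mask.any() else None
        out.append(
            LinkageSummary(
                cid, method_name, linked, _count_category(len(linked)),
                nearest_minutes=nearest,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Walking-time router chain
# ---------------------------------------------------------------------------

class WalkRouter(Protocol):
    def route(self, a: tuple[float, float], b: tuple[float, float]) -> float | None:
        """Walking minutes between two points, or None when no route is found."""


@dataclass
class SyntheticWalkRouter:
    """Haversine-based walking router for synthetic worlds.

    Time = haversine distance x detour factor at ``speed_kmh``. ``fails``
    decides which pairs the router cannot route (emulating network gaps).
    """

    speed_kmh: float = 5.0
    detour_factor: float = 1.4
    fails: Callable[[tuple[float, float], tuple[float, float]], bool] | None = None

    def route(self, a, b):
        if self.fails is not None and self.fails(a, b):
            return None
        return haversine_km(a, b) * self.detour_factor / self.speed_kmh * 60.0


def walking_time_chain(
    primary: WalkRouter,
    fallback: WalkRouter | None,
    pairs: Iterable[tuple[tuple[float, float], tuple[float, float]]],
    *,
    fallback_max_km: float = 50.0,
) -> np.ndarray:
    """Walking minutes per pair through the primary->fallback router chain.

    The primary router is tried first. On failure, the fallback is consulted
    only when the pair is strictly less than ``fallback_max_km`` apart
    (Haversine); otherwise the pair is unreachable (inf). A fallback failure
    also yields inf.
    """
    out = []
    for a, b in pairs:
        t = primary.route(a, b)
        if t is None and fallback is not None and haversine_km(a, b) < fallback_max_km:
            t = fallback.route(a, b)
        if t is not None and t < 0:
            raise ValidationError("router returned negative time")
        out.append(UNREACHABLE if t is None else float(t))
    return np.array(out)


@dataclass
class PairAccounting:
    """Bookkeeping for a walking-chain run over an all-pairs linkage.

    Reproducible from counts alone: total pairs, primary successes, pairs that
    fell inside the fallback radius, fallback successes, and the residual with
    no estimate.
    """

    n_clusters: int
    n_facilities: int
    n_primary_failures: int
    n_within_fallback_km: int
    n_fallback_failures: int

    @property
    def n_pairs(self) -> int:
        return self.n_clusters * self.n_facilities

    @property
    def n_primary_success(self) -> int:
        return self.n_pairs - self.n_primary_failures

    @property
    def n_fallback_success(self) -> int:
        return self.n_within_fallback_km - self.n_fallback_failures

    @property
    def n_no_estimate(self) -> int:
        return self.n_primary_failures - self.n_fallback_success

    @property
    def pct_primary_success(self) -> float:
        return 100.0 * self.n_primary_success / self.n_pairs

    @property
    def pct_fallback_success(self) -> float:
        return 100.0 * self.n_fallback_success / self.n_pairs


def max_linked_score(
    linkage: LinkageSummary, scores: pd.Series | dict
) -> float | None:
    """Highest readiness score among a cluster's linked facilities.

    None when the cluster links to nothing; missing scores for linked
    facilities are an error.
    """
    if not linkage.linked_facility_ids:
        return None
    try:
        return float(max(scores[f] for f in linkage.linked_facility_ids))
    except KeyError as e:
        raise ValidationError(
            f"cluster {linkage.cluster_id}: no readiness score for facility {e}"
        ) from None


def attach_scores_and_terciles(
    linkages: list[LinkageSummary],
    scores: pd.Series | dict,
    cluster_weights: pd.Series | dict | None = None,
) -> list[LinkageSummary]:
    """Fill max_linked_score and weighted score terciles on linkage summaries.

    Terciles are cut over clusters that link to at least one facility, using
    the supplied cluster weights (survey design weights); unlinked clusters
    keep ``score_tercile=None`` (they enter models as the distinct
    "no facility" level).
    """
    from .readiness import tercile_cut

    for lk in linkages:
        lk.max_linked_score = max_linked_score(lk, scores)
    linked = [lk for lk in linkages if lk.max_linked_score is not None]
    if linked:
        w = (
            np.ones(len(linked))
            if cluster_weights is None
            else np.array([cluster_weights[lk.cluster_id] for lk in linked])
        )
        terciles = tercile_cut([lk.max_linked_score for lk in linked], w)
        for lk, t in zip(linked, terciles):
            lk.score_tercile = str(t)
    return linkages


def linkage_frame(linkages: list[LinkageSummary]) -> pd.DataFrame:
    """Tidy per-cluster frame of linkage summaries."""
    return pd.DataFrame(
        {
            "cluster_id": [lk.cluster_id for lk in linkages],
            "method": [lk.method for lk in linkages],
            "n_linked": [len(lk.linked_facility_ids) for lk in linkages],
            "count_category": [lk.count_category for lk in linkages],
            "nearest_minutes": [lk.nearest_minutes for lk in linkages],
            "max_linked_score": [lk.max_linked_score for lk in linkages],
            "score_tercile": [lk.score_tercile for lk in linkages],
            "linked_facility_ids": [
                ";".join(sorted(map(str, lk.linked_facility_ids))) for lk in linkages
            ],
        }
    )
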
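"""Time-scaled local convex hull (T-LoCoH) home-range construction.

The method builds one small convex hull around every GPS fix (the *parent
point*) from its nearest neighbours, then sorts the hulls by a use metric
and merges them into *isopleths* — nested unions enclosing a stated
fraction of all fixes.  The 95 % isopleth under point-density sorting is
the home range; the 30 % isopleth under visit-frequency sorting is the
core area.

Time enters through the time-scaled distance (TSD)

    TSD(i, j) = sqrt(dx^2 + dy^2 + (s * v_max * dt)^2)

which adds the time separation, scaled by the time-scaling parameter ``s``
and the animal's maximum theoretical velocity ``v_max``, as a third
Euclidean axis.  With ``s = 0`` the method reduces to the classical
space-only local hull model; as ``s`` grows, temporally distant revisits
to the same place stop being neighbours, so repeated visits produce
stacked, separately counted hulls.

Neighbour selection is either fixed-count (``k`` nearest by TSD) or
adaptive (``a``-method: neighbours accumulate, nearest first, while the
running sum of their TSDs stays within a budget ``a``), the latter giving
more detail where the animal lingers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .track_io import Season, Track

__all__ = [
    "TLoCoHConfig",
    "Hull",
    "IsoplethLevel",
    "IsoplethSet",
    "ParamDiagnostics",
    "tsd",
    "select_neighbors_k",
    "select_neighbors_a",
    "build_hull",
    "build_hulls",
    "time_selected_fraction",
    "choose_s",
    "isopleth_diagnostics",
    "build_isopleths",
    "home_range_95",
    "core_area_30",
]


@dataclass
class TLoCoHConfig:
    """Parameters of a T-LoCoH run.

    ``v_max`` is in metres per hour; ``None`` means derive it per track as
    the 99.9th percentile of observed speeds, capped at 10 km/h to match
    the quality filter.  ``method`` selects fixed-``k`` or adaptive-``a``
    neighbour selection; with ``method="a"`` and ``a=None`` the budget is
    derived as the cumulative distance realised at ``k`` neighbours
    (median across parents).  ``ivg_h`` is the minimum absence separating
    two visits to the same hull.
    """

    s: float = 0.05
    v_max: float | None = None
    k: int = 15
    a: float | None = None
    method: Literal["k", "a"] = "k"
    ivg_h: float = 12.0
    levels: tuple[float, ...] = (0.30, 0.95)
    min_season_fixes: int = 100

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.a is not None and self.a < 0:
            raise ValueError("a must be >= 0")
        if self.v_max is not None and self.v_max <= 0:
            raise ValueError("v_max must be > 0")
        if list(self.levels) != sorted(self.levels):
            raise ValueError("isopleth levels must be ascending")


@dataclass
class Hull:
    """Convex hull seeded at one parent fix."""

    parent: int                     # positional index into the track's fixes
    neighbors: np.ndarray           # positional indices, parent included
    polygon: Polygon | None         # None when degenerate
    area_km2: float
    degenerate: bool
    time_selected: bool | None = None
    enclosed: np.ndarray | None = None   # indices of all enclosed fixes
    nsv: int | None = None               # number of separate visits
    mnlv: float | None = None            # mean locations per visit

    @property
    def n_enclosed(self) -> int:
        return 0 if self.enclosed is None else len(self.enclosed)

    @property
    def density(self) -> float:
        """Enclosed fixes per km² (0 for degenerate hulls)."""
        if self.degenerate or self.area_km2 <= 0 or self.enclosed is None:
            return 0.0
        return len(self.enclosed) / self.area_km2


@dataclass(frozen=True)
class IsoplethLevel:
    level: float
    polygon: object            # shapely (Multi)Polygon
    area_km2: float
    achieved_fraction: float
    n_hulls: int


@dataclass
class IsoplethSet:
    sort_metric: Literal["point_density", "visit_frequency"]
    levels: list[IsoplethLevel]

    def at(self, level: float) -> IsoplethLevel:
        for entry in self.levels:
            if abs(entry.level - level) < 1e-9:
                return entry
        raise KeyError(f"no isopleth at level {level}")


@dataclass
class ParamDiagnostics:
    """Per-candidate diagnostics for choosing s, k or a."""

    parameter: str                      # "s", "k" or "a"
    candidates: np.ndarray
    time_selected_fraction: np.ndarray | None = None   # for s
    isopleth_area: np.ndarray | None = None            # for k/a, 95 % level
    edge_to_area: np.ndarray | None = None             # perimeter / area
    recommendation: float | None = None


# ---------------------------------------------------------------------------
# coordinates


def _coords3(track: Track, s: float, v_max: float) -> np.ndarray:
    """(x, y, s*v_max*t) with t in hours from the first fix."""
    fx = track.fixes
    t_h = (fx["timestamp"].astype("int64").to_numpy() / 3.6e12)
    t_h = t_h - t_h[0]
    return np.column_stack([
        fx["x"].to_numpy(dtype=float),
        fx["y"].to_numpy(dtype=float),
        s * v_max * t_h,
    ])


def resolve_vmax(track: Track, cap_kmh: float = 10.0) -> float:
    """Maximum theoretical velocity (m/h): 99.9th pct of speeds, capped."""
    if "speed_from_prev" in track.fixes.columns:
        v = track.fixes["speed_from_prev"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
    else:
        v = np.empty(0)
    if len(v) == 0:
        return cap_kmh * 1000.0
    return float(min(np.percentile(v, 99.9), cap_kmh)) * 1000.0


def tsd(p_i, p_j, s: float, v_max: float, dt_h: float | None = None) -> float:
    """Time-scaled distance (metres) between two projected fixes.

    ``p_i``/``p_j`` are (x, y) in metres; ``dt_h`` is the absolute time
    separation in hours.  Symmetric, >= the planar distance, and equal to
    it when ``s = 0`` or ``dt_h = 0``.
    """
    dt_h = 0.0 if dt_h is None else abs(dt_h)
    dx = p_i[0] - p_j[0]
    dy = p_i[1] - p_j[1]
    return float(np.sqrt(dx * dx + dy * dy + (s * v_max * dt_h) ** 2))


def tsd_to_parent(track: Track, parent: int, s: float, v_max: float) -> np.ndarray:
    """TSD from every fix to ``parent`` (vectorised)."""
    pts = _coords3(track, s, v_max)
    return np.linalg.norm(pts - pts[parent], axis=1)


# ---------------------------------------------------------------------------
# neighbour selection


def select_neighbors_k(track: Track, parent: int, k: int, s: float, v_max: float) -> np.ndarray:
    """Indices of the ``k`` nearest fixes by TSD (parent included)."""
    n = len(track.fixes)
    if k > n:
        raise ValueError(f"k={k} exceeds track length {n}")
    d = tsd_to_parent(track, parent, s, v_max)
    order = np.lexsort((np.arange(n), d))  # stable under ties
    return np.sort(order[:k])


def select_neighbors_a(track: Track, parent: int, a: float, s: float, v_max: float) -> np.ndarray:
    """Adaptive neighbour set: nearest first while cumulative TSD <= ``a``."""
    if a < 0:
        raise ValueError("a must be >= 0")
    n = len(track.fixes)
    d = tsd_to_parent(track, parent, s, v_max)
    order = np.lexsort((np.arange(n), d))
    csum = np.cumsum(d[order])
    m = int(np.searchsorted(csum, a, side="right"))
    m = max(m, 1)  # parent (distance 0) always included
    return np.sort(order[:m])


def _knn_all(pts: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=k)
    return dist, idx


def build_hull(points_xy: np.ndarray) -> tuple[Polygon | None, float, bool]:
    """Convex hull of (x, y) metres -> (polygon, area km², degenerate flag)."""
    geom = shapely.convex_hull(shapely.multipoints(points_xy))
    if isinstance(geom, Polygon) and geom.area > 0:
        return geom, geom.area / 1e6, False
    return None, 0.0, True


def build_hulls(track: Track, config: TLoCoHConfig) -> list[Hull]:
    """One hull per parent fix under the configured neighbour method."""
    n = len(track.fixes)
    v_max = config.v_max if config.v_max is not None else resolve_vmax(track)
    pts3 = _coords3(track, config.s, v_max)
    xy = pts3[:, :2]

    if config.method == "k":
        if config.k > n:
            raise ValueError(f"k={config.k} exceeds track length {n}")
        _, idx = _knn_all(pts3, config.k)
        neighbor_sets = [np.sort(idx[p]) for p in range(n)]
    else:
        a = config.a if config.a is not None else a_for_k(track, config.k, config.s, v_max)
        neighbor_sets = _adaptive_sets(pts3, a)

    hulls: list[Hull] = []
    for p in range(n):
        nb = neighbor_sets[p]
        poly, area, degen = build_hull(xy[nb])
        hulls.append(Hull(parent=p, neighbors=nb, polygon=poly, area_km2=area, degenerate=degen))
    return hulls


def _adaptive_sets(pts3: np.ndarray, a: float) -> list[np.ndarray]:
    """a-method neighbour sets for every parent, via progressive kNN."""
    n = len(pts3)
    tree = cKDTree(pts3)
    k0 = min(max(16, 2), n)
    out: list[np.ndarray | None] = [None] * n
    pending = np.arange(n)
    k = k0
    while len(pending) > 0:
        dist, idx = tree.query(pts3[pending], k=min(k, n))
        if dist.ndim == 1:
            dist, idx = dist[:, None], idx[:, None]
        csum = np.cumsum(dist, axis=1)
        still = []
        for row, p in enumerate(pending):
            if csum[row, -1] <= a and k < n:
                still.append(p)
                continue
            m = int(np.searchsorted(csum[row], a, side="right"))
            m = max(m, 1)
            out[p] = np.sort(idx[row, :m])
        pending = np.array(still, dtype=int)
        k = min(k * 2, n)
    return [v for v in out]  # type: ignore[misc]


def a_for_k(track: Track, k: int, s: float, v_max: float) -> float:
    """Adaptive budget realised at ``k`` neighbours: median over parents of
    the cumulative TSD of each parent's k nearest neighbours."""
    pts3 = _coords3(track, s, v_max)
    dist, _ = _knn_all(pts3, min(k, len(pts3)))
    return float(np.median(dist.sum(axis=1)))


# ---------------------------------------------------------------------------
# parameter diagnostics


def time_selected_fraction(track: Track, s: float, config: TLoCoHConfig, v_max: float | None = None) -> float:
    """Fraction of hulls whose neighbour set changes when time is switched on.

    A hull is *time selected* iff its neighbour set under ``s`` differs
    from its set under ``s = 0``.
    """
    if s == 0:
        return 0.0
    v = v_max if v_max is not None else (config.v_max or resolve_vmax(track))
    n = len(track.fixes)
    if config.method == "k":
        _, idx0 = _knn_all(_coords3(track, 0.0, v), config.k)
        _, idx1 = _knn_all(_coords3(track, s, v), config.k)
        changed = [not np.array_equal(np.sort(idx0[p]), np.sort(idx1[p])) for p in range(n)]
    else:
        a = config.a if config.a is not None else a_for_k(track, config.k, s, v)
        sets0 = _adaptive_sets(_coords3(track, 0.0, v), a)
        sets1 = _adaptive_sets(_coords3(track, s, v), a)
        changed = [not np.array_equal(sets0[p], sets1[p]) for p in range(n)]
    return float(np.mean(changed))


def choose_s(
    track: Track,
    candidates: Sequence[float],
    config: TLoCoHConfig,
    band: tuple[float, float] = (0.40, 0.80),
) -> ParamDiagnostics:
    """Sweep ``s`` candidates; recommend the smallest whose time-selected
    fraction falls in ``band`` (40–80 % by default)."""
    cands = np.asarray(sorted(candidates), dtype=float)
    fracs = np.array([time_selected_fraction(track, s, config) for s in cands])
    rec = None
    for s, f in zip(cands, fracs):
        if band[0] <= f <= band[1]:
            rec = float(s)
            break
    return ParamDiagnostics(
        parameter="s", candidates=cands, time_selected_fraction=fracs, recommendation=rec
    )


def isopleth_diagnostics(
    track: Track,
    candidates: Sequence[float],
    config: TLoCoHConfig,
    parameter: Literal["k", "a"] = "k",
    level: float = 0.95,
    stabilisation: float = 0.10,
) -> ParamDiagnostics:
    """Isopleth area and edge:area across ``k`` (or ``a``) candidates.

    Large jumps in the area curve flag a risk of including unused space;
    the recommendation is the first candidate at which the relative change
    of the ``level`` isopleth area from the previous candidate drops below
    ``stabilisation`` (an explicit form of choosing the point where the
    curve has stabilised).
    """
    from .hull_behaviour import compute_enclosed_points  # deferred: avoids cycle

    cands = list(candidates)
    if len(cands) < 1:
        raise ValueError("need at least one candidate")
    areas, e2a = [], []
    for c in cands:
        cfg_kwargs = dict(
            s=config.s, v_max=config.v_max, ivg_h=config.ivg_h,
            levels=(level,), min_season_fixes=config.min_season_fixes,
        )
        if parameter == "k":
            cfg = TLoCoHConfig(k=int(c), method="k", **cfg_kwargs)
        else:
            cfg = TLoCoHConfig(k=config.k, a=float(c), method="a", **cfg_kwargs)
        hulls = build_hulls(track, cfg)
        compute_enclosed_points(hulls, track)
        iso = build_isopleths(hulls, len(track.fixes), "point_density", (level,))
        entry = iso.at(level)
        areas.append(entry.area_km2)
        perim_km = shapely.length(entry.polygon) / 1000.0 if entry.polygon is not None else 0.0
        e2a.append(perim_km / entry.area_km2 if entry.area_km2 > 0 else np.inf)

    rec = None
    if len(cands) >= 2:
        for i in range(1, len(cands)):
            prev = areas[i - 1]
            if prev > 0 and abs(areas[i] - prev) / prev < stabilisation:
                rec = float(cands[i])
                break
    return ParamDiagnostics(
        parameter=parameter,
        candidates=np.asarray(cands, dtype=float),
        isopleth_area=np.asarray(areas),
        edge_to_area=np.asarray(e2a),
        recommendation=rec,
    )


# ---------------------------------------------------------------------------
# isopleths


def _sort_hulls(hulls: list[Hull], metric: np.ndarray, parent_time: np.ndarray) -> np.ndarray:
    """Descending by metric; ties -> smaller area, then earlier parent."""
    areas = np.array([h.area_km2 for h in hulls])
    return np.lexsort((parent_time, areas, -metric))


def build_isopleths(
    hulls: list[Hull],
    n_fixes: int,
    sort_metric: Literal["point_density", "visit_frequency"],
    levels: Sequence[float],
) -> IsoplethSet:
    """Merge sorted hulls into nested isopleths.

    Hulls are taken densest-first (``point_density``) or most-visited-first
    (``visit_frequency``) and accumulated until the union encloses at
    least the requested fraction of all ``n_fixes`` retained fixes
    (enclosed fixes counted uniquely across the union).  Degenerate hulls
    are excluded.  Requires per-hull enclosed points (and ``nsv`` for
    visit sorting) to be precomputed.
    """
    valid = [h for h in hulls if not h.degenerate and h.enclosed is not None]
    if not valid:
        raise ValueError("no valid (non-degenerate) hulls to build isopleths from")
    if n_fixes <= 0:
        raise ValueError("n_fixes must be positive")

    if sort_metric == "point_density":
        metric = np.array([h.density for h in valid])
    elif sort_metric == "visit_frequency":
        if any(h.nsv is None for h in valid):
            raise ValueError("visit_frequency sorting requires nsv per hull")
        metric = np.array([float(h.nsv) for h in valid])
    else:
        raise ValueError(f"unknown sort metric {sort_metric!r}")

    parent_time = np.array([float(h.parent) for h in valid])
    order = _sort_hulls(valid, metric, parent_time)

    covered: np.ndarray = np.zeros(n_fixes, dtype=bool)
    out: list[IsoplethLevel] = []
    pos = 0
    for level in levels:
        if not 0 < level <= 1:
            raise ValueError(f"isopleth level {level} outside (0, 1]")
        target = level * n_fixes
        while covered.sum() < target and pos < len(order):
            covered[valid[order[pos]].enclosed] = True
            pos += 1
        chosen = [valid[order[i]] for i in range(pos)]
        union = unary_union([h.polygon for h in chosen])
        out.append(
            IsoplethLevel(
                level=float(level),
                polygon=union,
                area_km2=union.area / 1e6,
                achieved_fraction=float(covered.sum()) / n_fixes,
                n_hulls=pos,
            )
        )
    return IsoplethSet(sort_metric=sort_metric, levels=out)


# ---------------------------------------------------------------------------
# per-season home range and core area


@dataclass(frozen=True)
class SeasonalIsopleth:
    season: Season
    entry: IsoplethLevel | None
    n_fixes: int
    insufficient: bool


def _season_subtracks(track: Track) -> dict[Season, Track]:
    from .track_io import assign_season_series

    fx = track.fixes
    seasons = fx["season"] if "season" in fx.columns else assign_season_series(fx["timestamp"])
    out = {}
    for season in (Season.SUMMER, Season.FALL):
        sub = fx[np.asarray(seasons) == season.value].reset_index(drop=True)
        t = track.copy()
        t.fixes = sub
        out[season] = t
    return out


def _seasonal_isopleth(
    track: Track, config: TLoCoHConfig, level: float,
    sort_metric: Literal["point_density", "visit_frequency"],
) -> dict[Season, SeasonalIsopleth]:
    from .hull_behaviour import compute_enclosed_points, compute_visits

    out = {}
    for season, sub in _season_subtracks(track).items():
        n = len(sub.fixes)
        if n < config.min_season_fixes:
            out[season] = SeasonalIsopleth(season, None, n, True)
            continue
        hulls = build_hulls(sub, config)
        compute_enclosed_points(hulls, sub)
        if sort_metric == "visit_frequency":
            compute_visits(hulls, sub, ivg_h=config.ivg_h)
        iso = build_isopleths(hulls, n, sort_metric, (level,))
        out[season] = SeasonalIsopleth(season, iso.at(level), n, False)
    return out


def home_range_95(track: Track, config: TLoCoHConfig) -> dict[Season, SeasonalIsopleth]:
    """Per-season 95 % home range: density-sorted isopleth at level 0.95."""
    return _seasonal_isopleth(track, config, 0.95, "point_density")


def core_area_30(track: Track, config: TLoCoHConfig) -> dict[Season, SeasonalIsopleth]:
    """Per-season 30 % core area: visit-frequency-sorted isopleth."""
    return _seasonal_isopleth(track, config, 0.30, "visit_frequency")
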
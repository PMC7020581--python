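"""Per-hull behaviour metrics and the six-category classification.

Each hull is summarised by how often the animal came back to it (``nsv``,
number of separate visits — a proxy for site fidelity), how long it stayed
(``mnlv``, mean locations per visit — a proxy for residency), the
elongation of its bounding ellipse (eccentricity: circular hulls suggest
exploitative search, linear ones ballistic travel), and the mean posterior
probability of area-restricted search over its enclosed fixes.

The population of hulls is then split into six behavioural categories:
the first and third quartiles of area-normalised visit frequency define
three visitation bands (infrequent / frequent / very frequent), and each
band splits at its median of area-normalised locations-per-visit into a
short-duration and a long-duration category — categories 1–2, 3–4 and 5–6
respectively.  Hulls parented within a configurable radius of the colony
(15 km by default) are excluded beforehand, since movements around the
haul-out site would otherwise dominate the revisitation signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd
import shapely

from .tlocoh_core import Hull
from .track_io import Season, Track

__all__ = [
    "HullMetricsTable",
    "BehaviourClassification",
    "TimeBudget",
    "compute_enclosed_points",
    "count_visits",
    "mean_locations_per_visit",
    "compute_visits",
    "normalize_by_area",
    "min_enclosing_ellipse",
    "hull_eccentricity",
    "hull_mean_pars",
    "exclude_near_colony",
    "hull_metrics_table",
    "classify_categories",
    "time_budget",
]


# ---------------------------------------------------------------------------
# enclosed points and visits


def compute_enclosed_points(hulls: list[Hull], track: Track) -> None:
    """Fill ``hull.enclosed`` with indices of all fixes inside each hull.

    Points exactly on a hull edge count as enclosed (so a hull's own
    member points are always enclosed).  Degenerate hulls get an empty
    list.  Candidates are prefiltered by bounding box before the exact
    point-in-polygon test.
    """
    x = track.fixes["x"].to_numpy(dtype=float)
    y = track.fixes["y"].to_numpy(dtype=float)
    for hull in hulls:
        if hull.degenerate or hull.polygon is None:
            hull.enclosed = np.empty(0, dtype=int)
            continue
        minx, miny, maxx, maxy = hull.polygon.bounds
        cand = np.flatnonzero((x >= minx) & (x <= maxx) & (y >= miny) & (y <= maxy))
        inside = shapely.intersects_xy(hull.polygon, x[cand], y[cand])
        hull.enclosed = cand[inside]


def count_visits(enclosed_times: np.ndarray | pd.Series, ivg_h: float = 12.0) -> int:
    """Number of separate visits among time-sorted enclosed timestamps.

    A new visit starts when the animal has been outside the hull for
    *strictly more than* ``ivg_h`` hours; a gap of exactly ``ivg_h`` keeps
    the same visit.  Empty input gives 0.
    """
    t = _times_to_hours(enclosed_times)
    if len(t) == 0:
        return 0
    return 1 + int(np.sum(np.diff(t) > ivg_h))


def mean_locations_per_visit(enclosed_times: np.ndarray | pd.Series, ivg_h: float = 12.0) -> float:
    """Total enclosed fixes divided by the number of visits (NaN if empty)."""
    t = _times_to_hours(enclosed_times)
    if len(t) == 0:
        return float("nan")
    return len(t) / count_visits(t, ivg_h)


def _times_to_hours(times) -> np.ndarray:
    if isinstance(times, pd.Series):
        times = times.astype("int64").to_numpy() / 3.6e12
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and np.any(np.diff(times) < 0):
        raise ValueError("enclosed timestamps must be sorted")
    return times


def compute_visits(hulls: list[Hull], track: Track, ivg_h: float = 12.0) -> None:
    """Fill ``hull.nsv`` and ``hull.mnlv`` from enclosed fix timestamps."""
    t_h = track.fixes["timestamp"].astype("int64").to_numpy() / 3.6e12
    for hull in hulls:
        if hull.enclosed is None:
            raise ValueError("compute_enclosed_points must run first")
        times = t_h[hull.enclosed]
        hull.nsv = count_visits(times, ivg_h)
        hull.mnlv = mean_locations_per_visit(times, ivg_h) if hull.nsv else float("nan")


def normalize_by_area(value: float, area_km2: float) -> float:
    """Value per km² of hull area (NaN for degenerate/zero-area hulls)."""
    if not np.isfinite(area_km2) or area_km2 <= 0:
        return float("nan")
    return value / area_km2


# ---------------------------------------------------------------------------
# eccentricity


@numba.njit(cache=True)
def _khachiyan_weights(P: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    n, d = P.shape
    Q = np.ones((d + 1, n))
    Q[:d, :] = P.T
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = (Q * u) @ Q.T
        Xinv = np.linalg.inv(X)
        # M_j = q_j' X^-1 q_j
        M = np.sum(Q * (Xinv @ Q), axis=0)
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1) * (M[j] - 1.0))
        if step <= tol:
            break
        u *= 1.0 - step
        u[j] += step
    return u


def min_enclosing_ellipse(points: np.ndarray, tol: float = 1e-7, max_iter: int = 10_000):
    """Minimum-area enclosing (Löwner–John) ellipse by Khachiyan iteration.

    Returns (center, semi_axes) with ``semi_axes`` sorted descending.
    """
    P = np.asarray(points, dtype=float)
    P = np.unique(P, axis=0)
    n, d = P.shape
    if n < 2:
        raise ValueError("need at least 2 distinct points")
    # scale to unit box for conditioning; axes rescale back
    lo, hi = P.min(axis=0), P.max(axis=0)
    span = float(max(np.max(hi - lo), 1e-12))
    u = _khachiyan_weights(np.ascontiguousarray((P - lo) / span), tol, max_iter)
    P_s = (P - lo) / span
    center_s = P_s.T @ u
    # ellipse (x-c)' A (x-c) <= 1 with A = [d * (P'UP - cc')]^-1;
    # semi-axes are the sqrt eigenvalues of A^-1
    A_inv = d * (P_s.T @ np.diag(u) @ P_s - np.outer(center_s, center_s))
    eig = np.clip(np.linalg.eigvalsh(A_inv), 0, None)
    semi_axes = np.sqrt(eig)[::-1] * span
    center = center_s * span + lo
    return center, semi_axes


def hull_eccentricity(hull: Hull | np.ndarray, tol: float = 1e-7, max_iter: int = 1000) -> float:
    """Eccentricity of the minimum-area ellipse enclosing the hull vertices.

    ``e = sqrt(1 - (b/a)^2)`` with semi-axes a >= b: 0 for circle-like
    hulls, approaching 1 for line-like ones.  Degenerate hulls return 1.
    The iteration cap keeps per-hull cost bounded; beyond it the axis
    ratio is accurate to well under a percent, ample for a shape index.
    """
    if isinstance(hull, Hull):
        if hull.degenerate or hull.polygon is None:
            return 1.0
        pts = np.asarray(hull.polygon.exterior.coords)[:-1]
    else:
        pts = np.asarray(hull, dtype=float)
    try:
        _, axes = min_enclosing_ellipse(pts, tol=tol, max_iter=max_iter)
    except (ValueError, np.linalg.LinAlgError):
        return 1.0
    a, b = axes[0], axes[-1]
    if a <= 0:
        return 1.0
    ratio = min(b / a, 1.0)
    return float(np.sqrt(max(1.0 - ratio * ratio, 0.0)))


def hull_mean_pars(hull: Hull, pars: np.ndarray) -> float:
    """Mean p(ARS) over a hull's enclosed fixes (NaN if none defined)."""
    if hull.enclosed is None or len(hull.enclosed) == 0:
        return float("nan")
    vals = np.asarray(pars, dtype=float)[hull.enclosed]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if len(vals) else float("nan")


# ---------------------------------------------------------------------------
# colony exclusion and the metrics table


def exclude_near_colony(hulls: list[Hull], track: Track, radius_km: float = 15.0) -> list[Hull]:
    """Drop hulls whose parent fix lies within ``radius_km`` of the colony.

    Only classification and time budgets use this; home ranges and core
    areas are built from the full hull set.
    """
    if radius_km <= 0:
        return list(hulls)
    if "dist_colony" not in track.fixes.columns:
        raise ValueError("track must be annotated with dist_colony first")
    d = track.fixes["dist_colony"].to_numpy(dtype=float)
    return [h for h in hulls if d[h.parent] >= radius_km]


def hull_metrics_table(
    hulls: list[Hull],
    track: Track,
    pars: np.ndarray | None = None,
    animal_id: str | None = None,
    with_eccentricity: bool = True,
) -> pd.DataFrame:
    """Tidy per-hull metrics table (one row per non-degenerate hull)."""
    fx = track.fixes
    rows = []
    for i, h in enumerate(hulls):
        if h.degenerate or h.nsv is None:
            continue
        nsv_km2 = normalize_by_area(h.nsv, h.area_km2)
        mnlv_km2 = normalize_by_area(h.mnlv, h.area_km2)
        rows.append({
            "animal_id": animal_id or track.animal_id,
            "hull_id": i,
            "parent": h.parent,
            "parent_time": fx["timestamp"].iloc[h.parent],
            "season": fx["season"].iloc[h.parent] if "season" in fx.columns else None,
            "area_km2": h.area_km2,
            "n_enclosed": h.n_enclosed,
            "nsv": h.nsv,
            "mnlv": h.mnlv,
            "nsv_km2": nsv_km2,
            "mnlv_km2": mnlv_km2,
            "eccentricity": hull_eccentricity(h) if with_eccentricity else np.nan,
            "mean_pars": hull_mean_pars(h, pars) if pars is not None else np.nan,
            "dist_colony": fx["dist_colony"].iloc[h.parent] if "dist_colony" in fx.columns else np.nan,
            "depth": fx["depth"].iloc[h.parent] if "depth" in fx.columns else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classification


@dataclass
class BehaviourClassification:
    """Population-level thresholds plus per-hull categories 1–6.

    ``q1``/``q3`` are the quartiles of nsv/km² over all classified hulls;
    ``band_medians`` maps each visitation band to its median mnlv/km².
    ``table`` is the input metrics table with ``band`` and ``category``
    columns added.
    """

    q1: float
    q3: float
    band_medians: dict[str, float]
    table: pd.DataFrame

    BANDS = ("infrequent", "frequent", "very_frequent")


def classify_categories(metrics: pd.DataFrame) -> BehaviourClassification:
    """Six-way behavioural classification over the pooled hull population.

    Visitation bands from the quartiles of ``nsv_km2``: below q1 →
    infrequent, above q3 → very frequent, else frequent.  Within each
    band, hulls at or below the band's median ``mnlv_km2`` take the lower
    category of the pair (1/3/5), the rest the upper (2/4/6).
    """
    t = metrics.copy()
    t = t[np.isfinite(t["nsv_km2"]) & np.isfinite(t["mnlv_km2"])].copy()
    if len(t) < 4:
        raise ValueError("need at least 4 classified hulls to set quartiles")
    q1, q3 = np.quantile(t["nsv_km2"].to_numpy(), [0.25, 0.75])
    if q1 == q3:
        raise ValueError("degenerate thresholds: nsv_km2 quartiles coincide")

    band = np.where(
        t["nsv_km2"] < q1, "infrequent", np.where(t["nsv_km2"] > q3, "very_frequent", "frequent")
    )
    t["band"] = band
    base = {"infrequent": 1, "frequent": 3, "very_frequent": 5}
    medians: dict[str, float] = {}
    category = np.zeros(len(t), dtype=int)
    for name in BehaviourClassification.BANDS:
        mask = band == name
        if not mask.any():
            medians[name] = float("nan")
            continue
        med = float(np.median(t.loc[mask, "mnlv_km2"]))
        medians[name] = med
        category[mask] = np.where(t.loc[mask, "mnlv_km2"] <= med, base[name], base[name] + 1)
    t["category"] = category
    return BehaviourClassification(q1=float(q1), q3=float(q3), band_medians=medians, table=t)


# ---------------------------------------------------------------------------
# time budgets


@dataclass
class TimeBudget:
    """Per animal × season category proportions plus population summaries.

    ``proportions`` has one row per animal × season with columns ``p1`` …
    ``p6`` summing to 1; ``summary`` holds per-category medians and raw
    median absolute deviations across animals.
    """

    proportions: pd.DataFrame
    summary: pd.DataFrame


def time_budget(classified: pd.DataFrame) -> TimeBudget:
    """Proportion of classified fixes per category, by animal and season.

    Each classified hull's parent fix stands for one sampling interval, so
    with near-uniform sampling the share of parent fixes per category is
    the share of time.
    """
    t = classified[classified["category"] > 0]
    rows = []
    for (animal, season), sub in t.groupby(["animal_id", "season"], sort=True):
        counts = np.array([(sub["category"] == c).sum() for c in range(1, 7)], dtype=float)
        total = counts.sum()
        if total == 0:
            continue
        row = {"animal_id": animal, "season": season}
        row.update({f"p{c}": counts[c - 1] / total for c in range(1, 7)})
        rows.append(row)
    props = pd.DataFrame(rows)

    sum_rows = []
    if len(props):
        for season, sub in props.groupby("season", sort=True):
            for c in range(1, 7):
                vals = sub[f"p{c}"].to_numpy()
                med = float(np.median(vals))
                sum_rows.append({
                    "season": season,
                    "category": c,
                    "median": med,
                    "mad": float(np.median(np.abs(vals - med))),
                    "n_animals": len(vals),
                })
    return TimeBudget(proportions=props, summary=pd.DataFrame(sum_rows))
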
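"""Reading, validating, quality-filtering and annotating GPS fix tables.

A *fix* is a single timestamped GPS position with its quality fields
(number of satellites, residual error).  A :class:`Track` is the ordered
fix table of one animal together with deployment metadata.  Tracks are
held as pandas DataFrames — the natural container for regularly sampled
telemetry — with one row per fix and well-known column names
(:data:`FIX_COLUMNS`).

The module also houses the study-design helpers that annotate fixes:
projection to a local planar frame (azimuthal equidistant, centred on the
colony, so that a central-place forager's distances are minimally
distorted), great-circle distance to the colony, the two-season calendar
split, and bilinear depth lookup on a regular bathymetry grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "EARTH_RADIUS_KM",
    "FIX_COLUMNS",
    "Season",
    "Track",
    "BathymetryGrid",
    "FilterReport",
    "FormatError",
    "read_fixes",
    "filter_fixes",
    "project",
    "unproject",
    "assign_season",
    "great_circle_km",
    "distance_to_colony",
    "annotate_track",
]

logger = logging.getLogger(__name__)

#: Mean Earth radius (IUGG), km.  All spherical formulas share it.
EARTH_RADIUS_KM = 6371.0088

#: Required columns of a fix CSV.
FIX_COLUMNS = ["animal_id", "timestamp", "lon", "lat", "n_sats", "residual"]

#: Required columns of the per-animal metadata CSV.
META_COLUMNS = [
    "animal_id", "sex", "deploy_date", "recapture_date",
    "deploy_mass_kg", "recapture_mass_kg", "pregnant", "postpartum_day",
]


class FormatError(ValueError):
    """An input table is missing required structure."""


class Season(str, Enum):
    """Seasonal split of the study window.

    Summer runs 1 June to 30 September and fall 1 October to 4 December,
    both inclusive; after ~4 December the animals return to the breeding
    colony and foraging is essentially arrested, so later dates (and
    dates before June) are ``excluded`` rather than an error.
    """

    SUMMER = "summer"
    FALL = "fall"
    EXCLUDED = "excluded"


@dataclass
class Track:
    """One animal's ordered fix table plus deployment metadata.

    ``fixes`` columns: ``timestamp`` (tz-aware UTC), ``lon``, ``lat``,
    ``n_sats``, ``residual`` and, once computed, ``x``/``y`` (metres in
    the local planar frame), ``speed_from_prev`` (km/h), ``dist_colony``
    (km), ``depth`` (m) and ``season``.
    """

    animal_id: str
    fixes: pd.DataFrame
    sex: str | None = None
    deployment_date: pd.Timestamp | None = None
    recapture_date: pd.Timestamp | None = None
    deployment_mass: float | None = None
    recapture_mass: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError(f"track {self.animal_id}: fixes not time-ordered")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def is_projected(self) -> bool:
        return "x" in self.fixes.columns and "y" in self.fixes.columns

    def copy(self) -> "Track":
        return Track(
            animal_id=self.animal_id,
            fixes=self.fixes.copy(),
            sex=self.sex,
            deployment_date=self.deployment_date,
            recapture_date=self.recapture_date,
            deployment_mass=self.deployment_mass,
            recapture_mass=self.recapture_mass,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class FilterReport:
    """Accounting of a quality-filter pass.

    Each removed fix is attributed to the *first* rule that fired, in the
    order satellites → residual → speed, so the three counts partition
    the removals.
    """

    n_input: int
    n_removed_sats: int
    n_removed_residual: int
    n_removed_speed: int

    @property
    def n_removed(self) -> int:
        return self.n_removed_sats + self.n_removed_residual + self.n_removed_speed

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


# ---------------------------------------------------------------------------
# reading


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_fixes(path: str | Path, metadata: str | Path | pd.DataFrame | None = None) -> list[Track]:
    """Read a fix CSV (and optional per-animal metadata CSV) into Tracks.

    Fixes are sorted by timestamp within each animal; rows repeating an
    already-seen timestamp are dropped, keeping the first occurrence, and
    the number dropped is logged.  An unparseable timestamp raises a
    :class:`FormatError` naming the offending row.
    """
    df = pd.read_csv(path)
    _require_columns(df, FIX_COLUMNS, f"fix table {path}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # find the first bad row for the error message
        parsed = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
        bad = int(np.flatnonzero(parsed.isna())[0])
        raise FormatError(
            f"fix table {path}: unparseable timestamp at row {bad}: {df['timestamp'].iloc[bad]!r}"
        ) from None

    meta_df = None
    if metadata is not None:
        meta_df = metadata if isinstance(metadata, pd.DataFrame) else pd.read_csv(metadata)
        _require_columns(meta_df, ["animal_id"], "metadata table")
        meta_df = meta_df.set_index(meta_df["animal_id"].astype(str))

    tracks: list[Track] = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("timestamp", kind="stable").reset_index(drop=True)
        dup = sub["timestamp"].duplicated(keep="first")
        if dup.any():
            logger.info("track %s: dropped %d duplicate-timestamp fixes", animal_id, int(dup.sum()))
            sub = sub[~dup].reset_index(drop=True)
        kwargs: dict = {}
        if meta_df is not None and str(animal_id) in meta_df.index:
            row = meta_df.loc[str(animal_id)]
            kwargs = dict(
                sex=str(row.get("sex")) if "sex" in row else None,
                deployment_date=pd.to_datetime(row.get("deploy_date"), utc=True) if "deploy_date" in row else None,
                recapture_date=pd.to_datetime(row.get("recapture_date"), utc=True) if "recapture_date" in row else None,
                deployment_mass=float(row["deploy_mass_kg"]) if "deploy_mass_kg" in row and pd.notna(row["deploy_mass_kg"]) else None,
                recapture_mass=float(row["recapture_mass_kg"]) if "recapture_mass_kg" in row and pd.notna(row["recapture_mass_kg"]) else None,
                meta={k: row[k] for k in ("pregnant", "postpartum_day") if k in row},
            )
        tracks.append(Track(animal_id=str(animal_id), fixes=sub, **kwargs))
    return tracks


# ---------------------------------------------------------------------------
# projection and distances


def _project_arrays(lon, lat, center_lon, center_lat):
    """Azimuthal-equidistant forward projection, metres."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    lon0, lat0 = np.radians(center_lon), np.radians(center_lat)
    dlon = lon - lon0
    cos_c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    # k = c / sin(c) -> 1 as c -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    R = EARTH_RADIUS_KM * 1000.0
    x = R * k * np.cos(lat) * np.sin(dlon)
    y = R * k * (np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dlon))
    return x, y


def _unproject_arrays(x, y, center_lon, center_lat):
    """Inverse of :func:`_project_arrays`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon0, lat0 = np.radians(center_lon), np.radians(center_lat)
    R = EARTH_RADIUS_KM * 1000.0
    rho = np.hypot(x, y)
    c = rho / R
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_c, cos_c = np.sin(c), np.cos(c)
        safe_rho = np.where(rho > 1e-12, rho, 1.0)
        lat = np.arcsin(np.clip(cos_c * np.sin(lat0) + y * sin_c * np.cos(lat0) / safe_rho, -1, 1))
        lon = lon0 + np.arctan2(
            x * sin_c, safe_rho * cos_c * np.cos(lat0) - y * sin_c * np.sin(lat0)
        )
    lat = np.where(rho > 1e-12, lat, lat0)
    lon = np.where(rho > 1e-12, lon, lon0)
    return np.degrees(lon), np.degrees(lat)


def project(track: Track, center: tuple[float, float]) -> Track:
    """Populate planar ``x``/``y`` (metres) about ``center=(lon, lat)``.

    Uses an azimuthal-equidistant projection so distances from the centre
    are exact and pairwise distances within a few hundred km are accurate
    to a fraction of a percent.  Returns a new Track; the original is not
    modified.
    """
    lon0, lat0 = center
    if not (-180 <= lon0 <= 180 and -90 <= lat0 <= 90):
        raise ValueError(f"invalid projection centre {center}")
    out = track.copy()
    x, y = _project_arrays(out.fixes["lon"].to_numpy(), out.fixes["lat"].to_numpy(), lon0, lat0)
    out.fixes["x"] = x
    out.fixes["y"] = y
    out.meta["projection_center"] = (lon0, lat0)
    return out


def unproject(x, y, center: tuple[float, float]):
    """Recover (lon, lat) arrays from planar metres about ``center``."""
    return _unproject_arrays(x, y, center[0], center[1])


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Haversine great-circle distance in km (vectorised)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def distance_to_colony(fix_lon, fix_lat, colony: tuple[float, float]):
    """Great-circle distance (km) from fix coordinates to the colony."""
    return great_circle_km(fix_lon, fix_lat, colony[0], colony[1])


# ---------------------------------------------------------------------------
# quality filter


def compute_speeds_kmh(x_m: np.ndarray, y_m: np.ndarray, t: pd.Series) -> np.ndarray:
    """Speed from each fix to the previous one, km/h; NaN for the first."""
    x_km = np.asarray(x_m, dtype=float) / 1000.0
    y_km = np.asarray(y_m, dtype=float) / 1000.0
    dt_h = np.diff(t.astype("int64").to_numpy()) / 3.6e12
    d_km = np.hypot(np.diff(x_km), np.diff(y_km))
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(dt_h > 0, d_km / np.where(dt_h > 0, dt_h, 1.0), np.inf)
    return np.concatenate([[np.nan], v])


def filter_fixes(
    track: Track,
    min_sats: int = 5,
    max_residual: float = 30.0,
    max_speed: float = 10.0,
) -> tuple[Track, FilterReport]:
    """Remove low-quality fixes: few satellites, high residual, or speed outliers.

    A fix is dropped when acquired from fewer than ``min_sats`` satellites,
    when its residual error exceeds ``max_residual``, or when the travel
    speed implied from the previous *retained* fix exceeds ``max_speed``
    km/h.  The speed rule runs as a single forward pass against the last
    retained fix, so one teleporting outlier cannot cascade-delete the
    rest of the track, and the pass is idempotent.
    """
    if min_sats <= 0 or max_residual <= 0 or max_speed <= 0:
        raise ValueError("filter thresholds must be positive")
    fx = track.fixes
    n = len(fx)
    if n == 0:
        return track.copy(), FilterReport(0, 0, 0, 0)
    if not track.is_projected:
        raise ValueError("track must be projected before speed filtering")

    sats = fx["n_sats"].to_numpy()
    resid = fx["residual"].to_numpy(dtype=float)
    x = fx["x"].to_numpy(dtype=float) / 1000.0
    y = fx["y"].to_numpy(dtype=float) / 1000.0
    t = fx["timestamp"].astype("int64").to_numpy() / 3.6e12  # hours

    bad_sats = sats < min_sats
    bad_resid = resid > max_residual

    keep = np.zeros(n, dtype=bool)
    n_speed = 0
    last = -1  # index of last retained fix
    for i in range(n):
        if bad_sats[i] or bad_resid[i]:
            continue
        if last >= 0:
            dt = t[i] - t[last]
            d = float(np.hypot(x[i] - x[last], y[i] - y[last]))
            speed = d / dt if dt > 0 else np.inf
            if speed > max_speed:
                n_speed += 1
                continue
        keep[i] = True
        last = i

    report = FilterReport(
        n_input=n,
        n_removed_sats=int(np.sum(bad_sats)),
        n_removed_residual=int(np.sum(bad_resid & ~bad_sats)),
        n_removed_speed=n_speed,
    )
    out = track.copy()
    out.fixes = fx[keep].reset_index(drop=True)
    if len(out.fixes) > 0:
        out.fixes["speed_from_prev"] = compute_speeds_kmh(
            out.fixes["x"].to_numpy(), out.fixes["y"].to_numpy(), out.fixes["timestamp"]
        )
    return out, report


# ---------------------------------------------------------------------------
# seasons


def assign_season(t) -> Season:
    """Map a timestamp to summer (1 Jun–30 Sep), fall (1 Oct–4 Dec) or excluded."""
    ts = pd.Timestamp(t)
    m, d = ts.month, ts.day
    if 6 <= m <= 9:
        return Season.SUMMER
    if m in (10, 11) or (m == 12 and d <= 4):
        return Season.FALL
    return Season.EXCLUDED


def assign_season_series(timestamps: pd.Series) -> pd.Series:
    """Vectorised :func:`assign_season` over a timestamp Series."""
    m = timestamps.dt.month
    d = timestamps.dt.day
    out = pd.Series(Season.EXCLUDED.value, index=timestamps.index, dtype=object)
    out[(m >= 6) & (m <= 9)] = Season.SUMMER.value
    out[(m == 10) | (m == 11) | ((m == 12) & (d <= 4))] = Season.FALL.value
    return out


# ---------------------------------------------------------------------------
# bathymetry


@dataclass
class BathymetryGrid:
    """Regular lon/lat grid of water depth (m, positive down).

    ``depth[i, j]`` is the value at latitude ``lat0 + i*cell`` and
    longitude ``lon0 + j*cell`` (row 0 at the southern edge).
    """

    lon0: float
    lat0: float
    cell: float
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2 or self.depth.size == 0:
            raise ValueError("depth must be a non-empty 2-D grid")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.cell * np.arange(self.depth.shape[1])

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.cell * np.arange(self.depth.shape[0])

    def lookup(self, lon, lat):
        """Bilinear depth (m) at (lon, lat); out-of-extent raises ValueError."""
        interp = RegularGridInterpolator(
            (self.lats, self.lons), self.depth, method="linear", bounds_error=True
        )
        pts = np.column_stack([np.atleast_1d(lat).astype(float), np.atleast_1d(lon).astype(float)])
        try:
            vals = interp(pts)
        except ValueError as exc:
            raise ValueError(f"bathymetry lookup outside grid extent: {exc}") from None
        return float(vals[0]) if np.isscalar(lon) else vals

    # -- ESRI ASCII raster dialect (plain text) -----------------------------

    def to_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        nrows, ncols = self.depth.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {self.lon0 - self.cell / 2:.10g}\n")
            fh.write(f"yllcorner {self.lat0 - self.cell / 2:.10g}\n")
            fh.write(f"cellsize {self.cell:.10g}\n")
            fh.write(f"NODATA_value {nodata:.10g}\n")
            for row in self.depth[::-1]:  # ESRI rows run north -> south
                fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "BathymetryGrid":
        with open(path) as fh:
            header: dict[str, float] = {}
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        data = data.reshape(nrows, ncols)[::-1]  # back to south-up
        cell = header["cellsize"]
        return cls(
            lon0=header["xllcorner"] + cell / 2,
            lat0=header["yllcorner"] + cell / 2,
            cell=cell,
            depth=data,
        )


def lookup_depth(grid: BathymetryGrid, lon, lat):
    """Functional alias for :meth:`BathymetryGrid.lookup`."""
    return grid.lookup(lon, lat)


def annotate_track(
    track: Track,
    colony: tuple[float, float],
    bathymetry: BathymetryGrid | None = None,
) -> Track:
    """Add ``dist_colony`` (km), ``season`` and optionally ``depth`` columns."""
    out = track.copy()
    out.fixes["dist_colony"] = great_circle_km(
        out.fixes["lon"].to_numpy(), out.fixes["lat"].to_numpy(), colony[0], colony[1]
    )
    out.fixes["season"] = assign_season_series(out.fixes["timestamp"])
    if bathymetry is not None:
        out.fixes["depth"] = bathymetry.lookup(
            out.fixes["lon"].to_numpy(), out.fixes["lat"].to_numpy()
        )
    return out
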
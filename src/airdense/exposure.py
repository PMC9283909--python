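"""Individual long-term exposure assignment from cleaned station panels.

For each participant and pollutant, the annual mean of the three nearest
included monitoring stations is interpolated to the participant's location
by inverse-distance weighting (IDW, power 2 by default), per calendar year.
When a participant works at a different location, the home and work
estimates are blended by weekly time budget (168 h): home hours =
168 - weekly work hours.  The long-term exposure is the unweighted mean of
the three yearly estimates.

Geometry is either planar (x_km/y_km, Euclidean distance) or geographic
(lat/lon, haversine with Earth radius 6371.0 km); the mode must match the
station network.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from airdense.qc import annual_means

EARTH_RADIUS_KM = 6371.0
EXACT_HIT_EPS = 1e-9
WEEK_HOURS = 168.0


class InsufficientStationsError(ValueError):
    """Fewer included stations than the k required for interpolation."""


@dataclass(frozen=True)
class GeoPoint:
    """A location in either planar-km or geographic (lat/lon degrees) mode."""

    x: float
    y: float
    geographic: bool = False

    def __post_init__(self) -> None:
        if self.geographic:
            lat, lon = self.x, self.y
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError(f"invalid lat/lon: ({lat}, {lon})")


def distance(a: GeoPoint, b: GeoPoint) -> float:
    """Planar Euclidean or haversine distance in km, per the points' mode."""
    if a.geographic != b.geographic:
        raise ValueError("mixed geometry modes")
    if not a.geographic:
        return math.hypot(a.x - b.x, a.y - b.y)
    lat1, lon1, lat2, lon2 = map(math.radians, (a.x, a.y, b.x, b.y))
    h = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def nearest_stations(
    point: GeoPoint,
    stations: pd.DataFrame,
    k: int = 3,
) -> list[tuple[str, float]]:
    """The k nearest stations to a point, as ``(station_id, distance_km)``.

    ``stations`` needs columns ``station_id`` and either ``x_km``/``y_km``
    or ``lat``/``lon``.  Ties are broken by station id lexical order so the
    result is deterministic.
    """
    if len(stations) < k:
        raise InsufficientStationsError(
            f"need {k} stations, only {len(stations)} available"
        )
    geographic = "lat" in stations.columns
    out = []
    for _, row in stations.iterrows():
        sp = (
            GeoPoint(row["lat"], row["lon"], geographic=True)
            if geographic
            else GeoPoint(row["x_km"], row["y_km"])
        )
        out.append((str(row["station_id"]), distance(point, sp)))
    out.sort(key=lambda t: (t[1], t[0]))
    return out[:k]


def idw_estimate(
    neighbors: list[tuple[float, float]],
    power: float = 2.0,
) -> float:
    """Inverse-distance-weighted mean of ``(value, distance)`` neighbors.

    Weights are ``d^-power`` normalized to sum 1.  A neighbor within
    ``1e-9`` km is an exact hit and its value is returned outright.
    Missing (NaN) neighbor values are dropped; if all are missing the
    result is NaN.
    """
    usable = [(v, d) for v, d in neighbors if np.isfinite(v)]
    if not usable:
        return float("nan")
    for v, d in usable:
        if d < EXACT_HIT_EPS:
            return float(v)
    w = np.array([d ** -power for _, d in usable])
    vals = np.array([v for v, _ in usable])
    return float(np.sum(w * vals) / np.sum(w))


def _included_station_means(
    means: pd.DataFrame,
    inclusion: pd.DataFrame,
    pollutant: str,
    year: int,
) -> pd.DataFrame:
    inc = inclusion[(inclusion["pollutant"] == pollutant) & inclusion["included"]]
    m = means[(means["pollutant"] == pollutant) & (means["year"] == year)]
    return m[m["station_id"].isin(inc["station_id"])]


def person_year_exposure(
    point: GeoPoint,
    pollutant: str,
    year: int,
    means: pd.DataFrame,
    inclusion: pd.DataFrame,
    stations: pd.DataFrame,
    k: int = 3,
    power: float = 2.0,
) -> tuple[float, list[dict]]:
    """IDW estimate at a point from the k nearest included stations' annual means.

    ``means`` is the output of :func:`airdense.qc.annual_means` on the
    cleaned panel.  Returns ``(estimate, provenance)`` where provenance
    lists the contributing stations with their distances and weights.
    """
    avail = _included_station_means(means, inclusion, pollutant, year)
    station_sub = stations[stations["station_id"].isin(avail["station_id"])]
    nearest = nearest_stations(point, station_sub, k=k)
    value_by_id = avail.set_index("station_id")["mean"]
    neighbors = [(float(value_by_id[sid]), d) for sid, d in nearest]
    est = idw_estimate(neighbors, power=power)
    dists = np.array([d for _, d in nearest])
    if np.any(dists < EXACT_HIT_EPS):
        weights = (dists < EXACT_HIT_EPS).astype(float)
    else:
        weights = dists ** -power
    weights = weights / weights.sum()
    prov = [
        {"station_id": sid, "distance_km": float(d), "weight": float(w)}
        for (sid, d), w in zip(nearest, weights)
    ]
    return est, prov


@dataclass
class TimeActivity:
    """A participant's geography: home point per year, optional work point + hours."""

    home: GeoPoint
    work: GeoPoint | None = None
    weekly_work_hours: float | None = None

    def __post_init__(self) -> None:
        if (self.work is None) != (self.weekly_work_hours is None):
            raise ValueError("weekly_work_hours must be present iff work is")
        if self.weekly_work_hours is not None and not (
            0 <= self.weekly_work_hours <= WEEK_HOURS
        ):
            raise ValueError("weekly_work_hours must be in [0, 168]")


def person_exposure(
    activity: TimeActivity,
    pollutant: str,
    years: list[int],
    means: pd.DataFrame,
    inclusion: pd.DataFrame,
    stations: pd.DataFrame,
    k: int = 3,
    power: float = 2.0,
) -> tuple[float, list[dict]]:
    """Long-term (multi-year mean) exposure to one pollutant.

    Per year the estimate blends home and work:
    ``(h_home * E_home + h_work * E_work) / 168`` with
    ``h_home = 168 - weekly_work_hours``; without a work address the home
    estimate is used directly.  The long-term value is the unweighted mean
    over ``years``.
    """
    yearly = []
    provenance = []
    for year in years:
        e_home, prov_home = person_year_exposure(
            activity.home, pollutant, year, means, inclusion, stations, k, power
        )
        if activity.work is not None:
            e_work, prov_work = person_year_exposure(
                activity.work, pollutant, year, means, inclusion, stations, k, power
            )
            h_work = activity.weekly_work_hours
            h_home = WEEK_HOURS - h_work
            est = (h_home * e_home + h_work * e_work) / WEEK_HOURS
            provenance.append(
                {"year": year, "home": prov_home, "work": prov_work, "work_hours": h_work}
            )
        else:
            est = e_home
            provenance.append({"year": year, "home": prov_home})
        yearly.append(est)
    return float(np.mean(yearly)), provenance


def assign_exposures(
    cohort: pd.DataFrame,
    cleaned_panel: pd.DataFrame,
    inclusion: pd.DataFrame,
    stations: pd.DataFrame,
    years: list[int],
    pollutants: tuple[str, ...] | None = None,
    k: int = 3,
    power: float = 2.0,
) -> pd.DataFrame:
    """Exposure vectors for a whole cohort from a cleaned panel.

    The cohort frame needs ``participant_id`` and home coordinates
    (``home_x_km``/``home_y_km`` or ``home_lat``/``home_lon``); optional
    work columns (``work_x_km``/``work_y_km`` or ``work_lat``/``work_lon``)
    with ``weekly_work_hours``.  Returns a wide frame, one column per
    pollutant, indexed like the cohort.
    """
    means = annual_means(cleaned_panel)
    missing_years = [
        y for y in years if y not in set(means["year"])
    ]
    if missing_years:
        raise ValueError(f"panel has no data for years {missing_years}")
    if pollutants is None:
        pollutants = tuple(sorted(means["pollutant"].unique()))
    geographic = "home_lat" in cohort.columns
    hx, hy = ("home_lat", "home_lon") if geographic else ("home_x_km", "home_y_km")
    wx, wy = ("work_lat", "work_lon") if geographic else ("work_x_km", "work_y_km")
    rows = []
    for _, person in cohort.iterrows():
        home = GeoPoint(person[hx], person[hy], geographic=geographic)
        work = None
        hours = None
        if wx in cohort.columns and pd.notna(person.get(wx)):
            if pd.isna(person.get("weekly_work_hours")):
                raise ValueError(
                    f"participant {person['participant_id']}: work address "
                    "without weekly_work_hours"
                )
            work = GeoPoint(person[wx], person[wy], geographic=geographic)
            hours = float(person["weekly_work_hours"])
        activity = TimeActivity(home, work, hours)
        rec = {"participant_id": person["participant_id"]}
        for pol in pollutants:
            est, _ = person_exposure(
                activity, pol, years, means, inclusion, stations, k, power
            )
            rec[pol] = est
        rows.append(rec)
    return pd.DataFrame(rows)
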
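"""Quality control of hourly air-quality station panels.

The cleaning chain applied to each station x pollutant hourly series is:

1. **Completeness filter** — a series is retained only when the fraction of
   non-missing hours over the study window is at least the threshold
   (default 0.75, closed bound).
2. **Modified Z-score** — hourly concentrations are standardized per
   calendar year: ``Z_t = (x_t - mean_year) / sd_year`` (sample SD by
   default).
3. **Four-condition spike detection** — an observed hour is an outlier when
   all four conditions hold (configurable to ``any``):

   * ``z1``: |Z_t| > 4
   * ``z2``: |Z_t - Z_{t-1}| > 6
   * ``z3``: |Z_t / RM3(Z)_t| > 1.5, where RM3 is the centered 3-point
     running median of Z over observed hours
   * ``z4``: |Z_t - Z_{t-1}| / |city mean of (Z_t - Z_{t-1}) over the other
     included stations| > 2

4. **Removal** — flagged hours are set missing; everything else is
   untouched; cleaning is single-pass.

Panels are long-format DataFrames with columns ``station_id``, ``timestamp``
(hourly), ``pollutant`` and ``value`` (NaN = missing).  Hours absent from
the frame are treated as missing when assessing completeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["station_id", "timestamp", "pollutant", "value"]


@dataclass(frozen=True)
class QCConfig:
    """Tunable knobs of the cleaning chain.

    Attributes
    ----------
    completeness_threshold:
        Minimum fraction of observed hours for a station x pollutant series
        to be included (closed bound: exactly the threshold is included).
    z_thresholds:
        The four condition thresholds ``(z1, z2, z3, z4)``.
    rule:
        ``"all"`` flags an hour only when every condition holds (the
        conservative conjunction), ``"any"`` when at least one does.
    one_sided:
        When True, conditions z2-z4 use the signed quantity rather than its
        absolute value (the literal one-sided reading); the default treats
        negative spikes symmetrically.
    sd_ddof:
        Delta degrees of freedom for the annual SD (1 = sample SD, 0 =
        population SD).
    rm3_guard / city_guard:
        When the z3 or z4 denominator magnitude falls below the guard the
        ratio is replaced by a direct comparison of the numerator against
        the threshold, so a spike against a flat background cannot escape
        by zero-division.
    station_level:
        When True a station failing the completeness threshold for any
        pollutant is excluded for all pollutants (whole-station exclusion);
        default is per station x pollutant.
    """

    completeness_threshold: float = 0.75
    z_thresholds: tuple[float, float, float, float] = (4.0, 6.0, 1.5, 2.0)
    rule: str = "all"
    one_sided: bool = False
    sd_ddof: int = 1
    rm3_guard: float = 1e-6
    city_guard: float = 1e-6
    station_level: bool = False

    def __post_init__(self) -> None:
        if self.rule not in ("all", "any"):
            raise ValueError(f"rule must be 'all' or 'any', got {self.rule!r}")
        if len(self.z_thresholds) != 4:
            raise ValueError("z_thresholds must have exactly 4 entries")


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check panel schema and invariants; returns the panel with parsed timestamps."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    panel = panel.copy()
    panel["timestamp"] = pd.to_datetime(panel["timestamp"])
    if (panel["value"].dropna() < 0).any():
        raise ValueError("panel contains negative concentrations")
    dup = panel.duplicated(["station_id", "pollutant", "timestamp"])
    if dup.any():
        raise ValueError("panel contains duplicate station/pollutant/timestamp rows")
    return panel


def panel_period(panel: pd.DataFrame) -> pd.DatetimeIndex:
    """Full hourly grid spanning the panel's first to last timestamp (inclusive)."""
    ts = pd.to_datetime(panel["timestamp"])
    return pd.date_range(ts.min(), ts.max(), freq="h")


def completeness(series: pd.Series, period: pd.DatetimeIndex) -> float:
    """Fraction of hours in ``period`` with an observed (non-missing) value.

    ``series`` is indexed by timestamp; hours of ``period`` absent from the
    index count as missing.
    """
    if len(period) == 0:
        raise ValueError("completeness period is empty")
    observed = series.dropna()
    n_obs = observed.index.intersection(period).size
    return n_obs / len(period)


def filter_stations(
    panel: pd.DataFrame,
    threshold: float = 0.75,
    station_level: bool = False,
) -> pd.DataFrame:
    """Per station x pollutant completeness and inclusion decision.

    Inclusion uses a closed bound: completeness exactly equal to the
    threshold is included.  With ``station_level=True`` a station is
    excluded wholesale if any pollutant it reports falls below threshold.
    """
    panel = validate_panel(panel)
    if panel.empty:
        raise ValueError("panel is empty")
    period = panel_period(panel)
    n_hours = len(period)
    obs = panel.dropna(subset=["value"])
    counts = obs.groupby(["station_id", "pollutant"], sort=True).size()
    # station/pollutant pairs present in the panel but fully missing
    all_pairs = panel[["station_id", "pollutant"]].drop_duplicates()
    rec = all_pairs.set_index(["station_id", "pollutant"]).assign(
        completeness=counts / n_hours
    )
    rec["completeness"] = rec["completeness"].fillna(0.0)
    rec["included"] = rec["completeness"] >= threshold
    rec = rec.reset_index()
    if station_level:
        bad = rec.loc[~rec["included"], "station_id"].unique()
        rec.loc[rec["station_id"].isin(bad), "included"] = False
    return rec.sort_values(["station_id", "pollutant"]).reset_index(drop=True)


def zscore(series: pd.Series, ddof: int = 1) -> pd.Series:
    """Modified Z-score of an hourly series, standardized per calendar year.

    ``Z_t = (x_t - mean_year(x)) / sd_year(x)`` over observed hours.  A year
    with fewer than 2 observed hours or zero SD yields missing Z there, with
    a warning.
    """
    z = pd.Series(np.nan, index=series.index, dtype=float)
    obs = series.dropna()
    for year, grp in obs.groupby(obs.index.year):
        sd = grp.std(ddof=ddof)
        if len(grp) < 2 or not np.isfinite(sd) or sd == 0:
            warnings.warn(
                f"year {year}: SD undefined or zero; Z set missing", stacklevel=2
            )
            continue
        z.loc[grp.index] = (grp - grp.mean()) / sd
    return z


def rolling_median3(z: pd.Series) -> pd.Series:
    """Centered 3-point running median of Z over observed hours.

    Gaps are skipped (the window is the previous, current and next observed
    hours); at series endpoints the median of the 2 available points is used.
    """
    obs = z.dropna()
    rm = obs.rolling(3, center=True, min_periods=2).median()
    return rm.reindex(z.index)


def _delta_within_year(obs: pd.Series) -> pd.Series:
    """Z_t - Z_{t-1} over observed hours, restarting at each calendar year."""
    return obs.groupby(obs.index.year).diff()


def _rm3_within_year(obs: pd.Series) -> pd.Series:
    return obs.groupby(obs.index.year).transform(
        lambda s: s.rolling(3, center=True, min_periods=2).median()
    )


def _magnitude(x, one_sided: bool):
    return x if one_sided else np.abs(x)


def detect_outliers(
    panel: pd.DataFrame,
    config: QCConfig | None = None,
    inclusion: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Evaluate the four spike conditions for every observed hour.

    Returns a DataFrame with one row per flagged hour: ``station_id``,
    ``timestamp``, ``pollutant``, the four condition booleans and
    ``outlier`` (True under the configured rule).  The city-wide z4
    denominator averages (Z_t - Z_{t-1}) over the *other* stations included
    by the completeness filter for that pollutant; with fewer than 2
    included stations z4 is undefined and treated False (with a warning).
    """
    config = config or QCConfig()
    panel = validate_panel(panel)
    if inclusion is None:
        inclusion = filter_stations(
            panel, config.completeness_threshold, config.station_level
        )
    t1, t2, t3, t4 = config.z_thresholds
    grid = panel_period(panel)
    records = []
    for pollutant, sub in panel.groupby("pollutant", sort=True):
        wide = sub.pivot(index="timestamp", columns="station_id", values="value")
        wide = wide.reindex(grid)
        included_ids = set(
            inclusion.loc[
                (inclusion["pollutant"] == pollutant) & inclusion["included"],
                "station_id",
            ]
        )
        if len(included_ids) < 2:
            warnings.warn(
                f"{pollutant}: fewer than 2 included stations; "
                "z4 undefined and treated False",
                stacklevel=2,
            )
        zw = pd.DataFrame(index=wide.index)
        dz = pd.DataFrame(index=wide.index)
        rm3 = pd.DataFrame(index=wide.index)
        for col in wide.columns:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                zcol = zscore(wide[col], ddof=config.sd_ddof)
            obs = zcol.dropna()
            zw[col] = zcol
            dz[col] = _delta_within_year(obs).reindex(wide.index)
            rm3[col] = _rm3_within_year(obs).reindex(wide.index)
        # city mean of dz over the *other* included stations, same hour
        inc_cols = [c for c in wide.columns if c in included_ids]
        dz_inc = dz[inc_cols] if inc_cols else pd.DataFrame(index=wide.index)
        s = dz_inc.sum(axis=1)
        c = dz_inc.notna().sum(axis=1)
        for col in wide.columns:
            z = zw[col]
            d = dz[col]
            r = rm3[col]
            obs_mask = z.notna()
            z1 = np.abs(z) > t1
            z2 = _magnitude(d, config.one_sided) > t2
            # z3: ratio guarded against a flat RM3 background
            ratio3 = _magnitude(z / r.where(np.abs(r) >= config.rm3_guard), config.one_sided)
            z3_guard = (np.abs(r) < config.rm3_guard) & _magnitude(
                z, config.one_sided
            ).gt(t3)
            z3 = (ratio3 > t3) | z3_guard
            # z4: station delta against the city-wide delta of other stations
            if col in included_ids:
                other_n = c - d.notna().astype(int)
                city = (s - d.fillna(0.0)) / other_n.where(other_n > 0)
            else:
                city = s / c.where(c > 0)
            valid_city = city.notna() & d.notna()
            ratio4 = _magnitude(
                d / city.where(np.abs(city) >= config.city_guard), config.one_sided
            )
            z4_guard = (
                valid_city
                & (np.abs(city) < config.city_guard)
                & _magnitude(d, config.one_sided).gt(t4)
            )
            z4 = (valid_city & (ratio4 > t4)) | z4_guard
            conds = pd.DataFrame(
                {
                    "z1": z1.fillna(False),
                    "z2": z2.fillna(False),
                    "z3": z3.fillna(False),
                    "z4": z4.fillna(False),
                }
            )[obs_mask]
            if config.rule == "all":
                outlier = conds.all(axis=1)
            else:
                outlier = conds.any(axis=1)
            flagged = conds[outlier]
            for ts, row in flagged.iterrows():
                records.append(
                    {
                        "station_id": col,
                        "timestamp": ts,
                        "pollutant": pollutant,
                        "z1": bool(row["z1"]),
                        "z2": bool(row["z2"]),
                        "z3": bool(row["z3"]),
                        "z4": bool(row["z4"]),
                    }
                )
    flags = pd.DataFrame(
        records, columns=["station_id", "timestamp", "pollutant", "z1", "z2", "z3", "z4"]
    )
    return flags


def clean_panel(
    panel: pd.DataFrame,
    config: QCConfig | None = None,
    inclusion: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass cleaning: flagged hours set missing, all other values untouched."""
    config = config or QCConfig()
    panel = validate_panel(panel)
    flags = detect_outliers(panel, config, inclusion)
    cleaned = panel.copy()
    if not flags.empty:
        key_cols = ["station_id", "timestamp", "pollutant"]
        idx = cleaned.set_index(key_cols).index
        bad = pd.MultiIndex.from_frame(flags[key_cols])
        cleaned.loc[idx.isin(bad), "value"] = np.nan
    return cleaned, flags


def annual_mean(series: pd.Series, year: int) -> float:
    """Arithmetic mean of observed hours in a calendar year (NaN + warning if none)."""
    obs = series.dropna()
    in_year = obs[obs.index.year == year]
    if in_year.empty:
        warnings.warn(f"year {year}: no observed hours; annual mean missing", stacklevel=2)
        return float("nan")
    return float(in_year.mean())


def annual_means(panel: pd.DataFrame) -> pd.DataFrame:
    """Annual mean concentration per station x pollutant x calendar year.

    Returns a DataFrame with columns ``station_id, pollutant, year, mean``;
    station-years with no observed hours are absent.
    """
    panel = validate_panel(panel)
    obs = panel.dropna(subset=["value"]).copy()
    obs["year"] = obs["timestamp"].dt.year
    out = (
        obs.groupby(["station_id", "pollutant", "year"], sort=True)["value"]
        .mean()
        .rename("mean")
        .reset_index()
    )
    return out


def qc_report(
    panel: pd.DataFrame,
    inclusion: pd.DataFrame,
    flags: pd.DataFrame,
) -> dict:
    """JSON-serializable QC summary: completeness, inclusion and flag counts."""
    n_flagged = (
        flags.groupby(["station_id", "pollutant"]).size().to_dict() if not flags.empty else {}
    )
    stations = []
    for _, row in inclusion.iterrows():
        key = (row["station_id"], row["pollutant"])
        stations.append(
            {
                "station_id": row["station_id"],
                "pollutant": row["pollutant"],
                "completeness": float(row["completeness"]),
                "included": bool(row["included"]),
                "n_flagged": int(n_flagged.get(key, 0)),
            }
        )
    return {
        "n_station_pollutant_series": len(inclusion),
        "n_included": int(inclusion["included"].sum()),
        "n_hours_flagged": int(len(flags)),
        "series": stations,
    }
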
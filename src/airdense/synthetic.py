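"""Synthetic station networks, hourly pollutant panels and study cohorts.

Everything downstream of raw data access is testable against this module:
it produces (a) a monitoring-station network on a planar-km square, (b)
hourly concentration panels built from a shared city-wide signal (seasonal
+ diurnal sinusoids) plus station offsets and iid noise, with missingness
and single-hour spike outliers injected at known locations, and (c) a
cohort whose binary high-density outcome follows a logistic model with
configurable true odds ratios, rated on the BI-RADS a-d scale by two
simulated radiologists with a tunable adjacent-category disagreement rate.

The city-wide signal is shared across stations deliberately: the z4
outlier condition compares a station's hourly change against the city-wide
change, which is only meaningful when stations co-move.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from airdense.exposure import GeoPoint

POLLUTANTS = ("pm25", "pm10", "no2", "so2", "o3", "co")


@dataclass(frozen=True)
class StationNetwork:
    """Monitoring stations on a planar square of side ``extent_km``."""

    stations: pd.DataFrame  # columns: station_id, x_km, y_km
    extent_km: float
    geographic: bool = False

    def __post_init__(self) -> None:
        ids = self.stations["station_id"]
        if ids.duplicated().any():
            raise ValueError("station ids must be unique")
        if len(ids) < 3:
            raise ValueError("a network needs at least 3 stations")


def generate_station_network(
    n_stations: int = 22, extent_km: float = 40.0, seed: int = 0
) -> StationNetwork:
    """Place ``n_stations`` uniformly at random in a square of side ``extent_km``."""
    if n_stations < 3:
        raise ValueError("n_stations must be >= 3 (exposure needs 3 nearest)")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, extent_km, size=(n_stations, 2))
    df = pd.DataFrame(
        {
            "station_id": [f"st{i:02d}" for i in range(n_stations)],
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
        }
    )
    return StationNetwork(stations=df, extent_km=extent_km)


@dataclass(frozen=True)
class PollutantSignal:
    """City-wide signal parameters for one pollutant (units of that pollutant)."""

    baseline: float
    diurnal_amp: float
    seasonal_amp: float
    offset_sd: float
    noise_sd: float
    winter_peak: bool = True  # O3 peaks in summer, the rest in winter


DEFAULT_SIGNALS: dict[str, PollutantSignal] = {
    "pm25": PollutantSignal(30.0, 5.0, 10.0, 3.0, 8.0),
    "pm10": PollutantSignal(80.0, 10.0, 20.0, 8.0, 20.0),
    "no2": PollutantSignal(40.0, 10.0, 8.0, 5.0, 8.0),
    "so2": PollutantSignal(8.0, 2.0, 2.0, 1.5, 2.5),
    "o3": PollutantSignal(25.0, 10.0, 8.0, 3.0, 7.0, winter_peak=False),
    "co": PollutantSignal(2.5, 0.8, 0.5, 0.3, 0.6),
}


@dataclass
class PanelSpec:
    """What the hourly panel generator emulates, and at what rates."""

    years: tuple[int, ...] = (2018, 2019, 2020)
    signals: dict[str, PollutantSignal] = field(
        default_factory=lambda: dict(DEFAULT_SIGNALS)
    )
    missing_rate: float = 0.05
    outlier_rate: float = 0.001
    outlier_magnitude: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1 and 0 <= self.outlier_rate < 1):
            raise ValueError("missing_rate and outlier_rate must lie in [0, 1)")
        if self.outlier_magnitude <= 0:
            raise ValueError("outlier_magnitude must be positive")
        if not self.years:
            raise ValueError("years must be non-empty")


def _hourly_grid(years: tuple[int, ...]) -> pd.DatetimeIndex:
    return pd.date_range(
        f"{min(years)}-01-01", f"{max(years)}-12-31 23:00", freq="h"
    )


def generate_hourly_panel(
    network: StationNetwork, spec: PanelSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly panel for every station x pollutant, plus ground-truth outliers.

    Each series is ``city signal + station offset + iid noise`` floored at
    zero; a fraction ``missing_rate`` of hours is set missing at random and
    a fraction ``outlier_rate`` of the remaining observed hours is replaced
    by ``baseline ± outlier_magnitude * series SD`` single-hour spikes.
    Returns ``(panel, truth)`` in long format; ``truth`` has one row per
    injected spike (station_id, timestamp, pollutant).
    """
    rng = np.random.default_rng(spec.seed)
    grid = _hourly_grid(spec.years)
    hours = grid.hour.to_numpy()
    doy = grid.dayofyear.to_numpy()
    n = len(grid)
    frames = []
    truth_rows = []
    station_ids = network.stations["station_id"].tolist()
    for pol in sorted(spec.signals):
        sig = spec.signals[pol]
        phase = 0.0 if sig.winter_peak else math.pi
        city = (
            sig.baseline
            + sig.seasonal_amp * np.cos(2 * math.pi * (doy - 15) / 365.25 + phase)
            + sig.diurnal_amp * np.sin(2 * math.pi * (hours - 2) / 24)
        )
        offsets = rng.normal(0.0, sig.offset_sd, size=len(station_ids))
        for sid, off in zip(station_ids, offsets):
            values = city + off + rng.normal(0.0, sig.noise_sd, size=n)
            values = np.maximum(values, 0.0)
            clean_sd = values.std(ddof=1)
            missing = rng.random(n) < spec.missing_rate
            observed_idx = np.flatnonzero(~missing)
            if spec.outlier_rate > 0 and observed_idx.size:
                spike_mask = rng.random(observed_idx.size) < spec.outlier_rate
                spike_idx = observed_idx[spike_mask]
                signs = rng.choice([-1.0, 1.0], size=spike_idx.size)
                values[spike_idx] = np.maximum(
                    sig.baseline + signs * spec.outlier_magnitude * clean_sd, 0.0
                )
                for i in spike_idx:
                    truth_rows.append(
                        {"station_id": sid, "timestamp": grid[i], "pollutant": pol}
                    )
            values = values.astype(float)
            values[missing] = np.nan
            frames.append(
                pd.DataFrame(
                    {
                        "station_id": sid,
                        "timestamp": grid,
                        "pollutant": pol,
                        "value": values,
                    }
                )
            )
    panel = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows, columns=["station_id", "timestamp", "pollutant"])
    return panel, truth


class SinusoidalExposureField:
    """A smooth spatial exposure surface with cross-pollutant correlation.

    Each pollutant's surface is ``mean + sd * g(x, y)`` where ``g`` mixes a
    shared random-sinusoid field (inducing the inter-pollutant correlation
    the multi-pollutant regression has to cope with) with a
    pollutant-specific one; over points uniform on the extent, ``g`` has
    approximately zero mean and unit variance.  Values are floored at 1% of
    the mean so concentrations stay positive.
    """

    def __init__(
        self,
        means_sds: dict[str, tuple[float, float]],
        extent_km: float,
        seed: int = 0,
        shared_rho: float = 0.6,
        n_harmonics: int = 8,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.means_sds = dict(means_sds)
        self.extent = extent_km
        self.rho = shared_rho
        self._fields = {}
        def make_field():
            freq = rng.uniform(0.5, 2.5, size=(n_harmonics, 2))
            signs = rng.choice([-1.0, 1.0], size=(n_harmonics, 2))
            phase = rng.uniform(0, 2 * math.pi, size=n_harmonics)
            return freq * signs, phase
        self._shared = make_field()
        for pol in self.means_sds:
            self._fields[pol] = make_field()

    def _eval(self, fld, x, y):
        freq, phase = fld
        k = len(phase)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        args = (
            2 * math.pi * (np.outer(freq[:, 0], x) + np.outer(freq[:, 1], y))
            / self.extent
            + phase[:, None]
        )
        return math.sqrt(2.0 / k) * np.sin(args).sum(axis=0)

    def batch(self, xy: np.ndarray) -> pd.DataFrame:
        """Evaluate the surface at an (n, 2) array of points."""
        u0 = self._eval(self._shared, xy[:, 0], xy[:, 1])
        out = {}
        for pol, (mean, sd) in self.means_sds.items():
            up = self._eval(self._fields[pol], xy[:, 0], xy[:, 1])
            g = self.rho * u0 + math.sqrt(1 - self.rho ** 2) * up
            out[pol] = np.maximum(mean + sd * g, 0.01 * mean)
        return pd.DataFrame(out)

    def __call__(self, point: GeoPoint) -> dict[str, float]:
        row = self.batch(np.array([[point.x, point.y]])).iloc[0]
        return row.to_dict()


DEFAULT_EXPOSURE_FIELD = {
    "pm25": (30.0, 8.0),
    "pm10": (80.0, 15.0),
    "no2": (40.0, 8.0),
    "so2": (8.0, 2.5),
    "o3": (25.0, 6.0),
    "co": (2.5, 0.6),
}

# Per-unit log odds ratios of the two pollutants the stepwise model retains
# (NO2 per ppb, CO per ppm); the other four are null.
DEFAULT_TRUE_LOG_OR = {
    "pm25": 0.0,
    "pm10": 0.0,
    "no2": math.log(1.039),
    "so2": 0.0,
    "o3": 0.0,
    "co": math.log(0.331),
}

# Covariate log odds ratios of the fully adjusted confounder model.
DEFAULT_COVARIATE_LOG_OR = {
    "age": math.log(0.947),
    "bmi": math.log(0.884),
    "smoking": math.log(0.624),
    "ocp_history": math.log(0.536),
    "menopause": math.log(0.544),
    "parity": math.log(0.995),
    "breast_disease_history": math.log(0.735),
    "metformin": math.log(0.913),
    "aspirin": math.log(0.641),
    "vitamin_d": math.log(1.426),
    "calcium": math.log(0.795),
}


@dataclass
class CohortSpec:
    """Cohort size, true effect sizes and covariate marginals.

    Marginal parameters approximate a screening-mammography population of
    women in a polluted megacity: mean age ~50, about half postmenopausal,
    ~10% smoking exposure, ~11% employed outside the home.  ``intercept``
    of None calibrates the logistic intercept so that the mean outcome
    prevalence equals ``target_prevalence`` (default 62.2% high density).
    """

    n: int = 791
    true_log_or: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_LOG_OR)
    )
    covariate_log_or: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LOG_OR)
    )
    intercept: float | None = None
    target_prevalence: float = 0.622
    disagreement_rate: float = 0.02
    age_mean: float = 50.14
    age_sd: float = 7.61
    bmi_mean: float = 28.2
    bmi_sd: float = 4.7
    menarche_mean: float = 13.58
    menarche_sd: float = 1.52
    parity_mean: float = 2.2
    breastfeeding_mean: float = 33.7
    menopause_frac: float = 0.499
    ocp_frac: float = 0.379
    smoking_frac: float = 0.095
    metformin_frac: float = 0.115
    aspirin_frac: float = 0.134
    vitamin_d_frac: float = 0.497
    calcium_frac: float = 0.444
    vitamin_e_frac: float = 0.185
    primrose_frac: float = 0.049
    omega3_frac: float = 0.119
    breast_disease_frac: float = 0.230
    employed_frac: float = 0.11
    # BI-RADS split within each dichotomous class
    p_a_given_low: float = 0.25
    p_c_given_high: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("cohort size must be at least 10")
        if not (0 <= self.disagreement_rate < 1):
            raise ValueError("disagreement_rate must lie in [0, 1)")
        if not (0 < self.target_prevalence < 1):
            raise ValueError("target_prevalence must lie strictly inside (0, 1)")


_ADJACENT = {"a": ["b"], "b": ["a", "c"], "c": ["b", "d"], "d": ["c"]}


def generate_cohort(
    network: StationNetwork,
    exposures_by_location,
    spec: CohortSpec,
) -> pd.DataFrame:
    """Simulate a cohort with known true exposure and covariate effects.

    Home points are uniform over the network extent; ``exposures_by_location``
    maps a :class:`GeoPoint` to a pollutant -> concentration dict.  The
    probability of high density is ``expit(intercept + sum(beta_p * exposure)
    + sum(beta_c * covariate))``; the two raters' BI-RADS labels derive from
    the realized class, with the second rater moved to an adjacent category
    at ``disagreement_rate``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    ext = network.extent_km
    home_xy = rng.uniform(0.0, ext, size=(n, 2))
    if hasattr(exposures_by_location, "batch"):
        exposures = exposures_by_location.batch(home_xy).reset_index(drop=True)
    else:
        exposures = pd.DataFrame(
            [exposures_by_location(GeoPoint(x, y)) for x, y in home_xy]
        )
    cov = pd.DataFrame(
        {
            "age": rng.normal(spec.age_mean, spec.age_sd, n).clip(35, 85),
            "bmi": rng.normal(spec.bmi_mean, spec.bmi_sd, n).clip(15, 55),
            "menarche_age": rng.normal(spec.menarche_mean, spec.menarche_sd, n).clip(9, 18),
            "parity": rng.poisson(spec.parity_mean, n).astype(float),
            "breastfeeding_months": rng.gamma(1.2, spec.breastfeeding_mean / 1.2, n),
            "menopause": (rng.random(n) < spec.menopause_frac).astype(float),
            "ocp_history": (rng.random(n) < spec.ocp_frac).astype(float),
            "smoking": (rng.random(n) < spec.smoking_frac).astype(float),
            "metformin": (rng.random(n) < spec.metformin_frac).astype(float),
            "aspirin": (rng.random(n) < spec.aspirin_frac).astype(float),
            "vitamin_d": (rng.random(n) < spec.vitamin_d_frac).astype(float),
            "calcium": (rng.random(n) < spec.calcium_frac).astype(float),
            "vitamin_e": (rng.random(n) < spec.vitamin_e_frac).astype(float),
            "primrose": (rng.random(n) < spec.primrose_frac).astype(float),
            "omega3": (rng.random(n) < spec.omega3_frac).astype(float),
            "breast_disease_history": (rng.random(n) < spec.breast_disease_frac).astype(float),
        }
    )
    cov["age_first_birth"] = np.where(
        cov["parity"] > 0, rng.normal(22.0, 5.3, n).clip(14, 45), np.nan
    )
    lp0 = np.zeros(n)
    for pol, beta in spec.true_log_or.items():
        if beta != 0.0 and pol not in exposures.columns:
            raise ValueError(f"exposure field does not provide pollutant {pol!r}")
        if pol in exposures.columns:
            lp0 += beta * exposures[pol].to_numpy()
    for name, beta in spec.covariate_log_or.items():
        if name not in cov.columns:
            raise ValueError(f"unknown covariate in covariate_log_or: {name!r}")
        lp0 += beta * cov[name].to_numpy()
    if spec.intercept is None:
        b0 = calibrate_intercept(lp0, spec.target_prevalence)
    else:
        b0 = spec.intercept
    p = expit(b0 + lp0)
    y = (rng.random(n) < p).astype(int)
    if y.min() == y.max():
        warnings.warn("degenerate cohort: all outcomes identical", stacklevel=2)
    # rater 1 reads the true class; splits within class set the a-d marginals
    u = rng.random(n)
    birads1 = np.where(
        y == 1,
        np.where(u < spec.p_c_given_high, "c", "d"),
        np.where(u < spec.p_a_given_low, "a", "b"),
    )
    birads2 = birads1.copy()
    flip = rng.random(n) < spec.disagreement_rate
    for i in np.flatnonzero(flip):
        birads2[i] = rng.choice(_ADJACENT[birads1[i]])
    # work geography for the employed minority
    employed = rng.random(n) < spec.employed_frac
    work_xy = rng.uniform(0.0, ext, size=(n, 2))
    weekly_hours = rng.normal(44.0, 8.0, n).clip(8, 84)
    cohort = pd.DataFrame(
        {
            "participant_id": [f"p{i:05d}" for i in range(n)],
            "home_x_km": home_xy[:, 0],
            "home_y_km": home_xy[:, 1],
            "work_x_km": np.where(employed, work_xy[:, 0], np.nan),
            "work_y_km": np.where(employed, work_xy[:, 1], np.nan),
            "weekly_work_hours": np.where(employed, weekly_hours, np.nan),
            "birads_rater1": birads1,
            "birads_rater2": birads2,
            "high_density": y,
        }
    )
    cohort["density"] = np.where(y == 1, "high", "low")
    for col in exposures.columns:
        cohort[col] = exposures[col].to_numpy()
    for col in cov.columns:
        cohort[col] = cov[col].to_numpy()
    return cohort


def calibrate_intercept(lp0: np.ndarray, target_prevalence: float) -> float:
    """Intercept making mean(expit(b0 + lp0)) equal the target prevalence."""
    def f(b0):
        return float(np.mean(expit(b0 + lp0))) - target_prevalence
    lo, hi = -50.0, 50.0
    lo = min(lo, -float(np.max(lp0)) - 10)
    hi = max(hi, -float(np.min(lp0)) + 10)
    return float(brentq(f, lo, hi, xtol=1e-10))
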
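"""End-to-end orchestration: simulate -> qc -> expose -> analyze.

:func:`run_pipeline` executes the whole chain on synthetic data and writes
a manifest with per-stage row counts and output checksums, so a rerun with
the same seed is verifiably identical.  The cohort outcome is generated
from the exposure surface the cleaned panel implies (IDW over annual
station means), so the downstream regression has a recoverable truth.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from airdense import analysis, exposure, qc, synthetic
from airdense.exposure import GeoPoint
from airdense.qc import QCConfig

POLLUTANTS = synthetic.POLLUTANTS


@dataclass
class RunConfig:
    """Configuration for a full synthetic pipeline run."""

    out_dir: str = "airdense_run"
    seed: int = 0
    # network / panel
    n_stations: int = 22
    extent_km: float = 40.0
    years: tuple[int, ...] = (2018, 2019, 2020)
    missing_rate: float = 0.05
    outlier_rate: float = 0.001
    outlier_magnitude: float = 8.0
    n_low_completeness: int = 5
    low_completeness_missing: float = 0.40
    # cohort / eligibility
    n_screened: int = 813
    n_suspicious: int = 14
    n_bad_address: int = 8
    # qc
    qc: QCConfig = field(default_factory=QCConfig)
    # exposure
    idw_k: int = 3
    idw_power: float = 2.0
    # analysis
    p_enter: float = 0.05
    p_remove: float = 0.10

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        qc_raw = raw.pop("qc", {})
        if "z_thresholds" in qc_raw:
            qc_raw["z_thresholds"] = tuple(qc_raw["z_thresholds"])
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        return cls(qc=QCConfig(**qc_raw), **raw)


def apply_eligibility(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop participants failing any eligibility criterion; log per-criterion counts.

    Recognized flag columns (all optional): ``suspicious_mammogram``,
    ``incomplete_address`` (booleans) and ``residency_years`` (numeric,
    excluded when < 3).  Overlapping flags are counted per criterion but a
    row is removed once, so the ledger in the returned log balances:
    screened = analyzed + excluded_unique.
    """
    drop = pd.Series(False, index=cohort.index)
    log: dict = {"screened": int(len(cohort))}
    if "suspicious_mammogram" in cohort.columns:
        m = cohort["suspicious_mammogram"].fillna(False).astype(bool)
        log["suspicious_mammogram"] = int(m.sum())
        drop |= m
    if "incomplete_address" in cohort.columns:
        m = cohort["incomplete_address"].fillna(False).astype(bool)
        log["incomplete_address"] = int(m.sum())
        drop |= m
    if "residency_years" in cohort.columns:
        m = cohort["residency_years"] < 3
        log["residency_under_3y"] = int(m.sum())
        drop |= m
    log["excluded_unique"] = int(drop.sum())
    log["analyzed"] = int((~drop).sum())
    return cohort[~drop].reset_index(drop=True), log


# Table-shaped categorical margins of a 791-woman screening cohort:
# {variable: {level: (n_low_density, n_high_density)}}
_CATEGORICAL_MARGINS = {
    "menopause": {"no": (93, 303), "yes": (206, 189)},
    "ocp_history": {"no": (160, 331), "yes": (139, 161)},
    "smoking": {"no": (261, 455), "active_or_passive": (38, 37)},
    "occupation": {"housewife": (264, 407), "employed": (20, 67), "retired": (15, 18)},
    "metformin": {"no": (250, 450), "yes": (49, 42)},
    "aspirin": {"no": (239, 446), "yes": (60, 46)},
    "calcium": {"no": (143, 297), "yes": (156, 195)},
    "vitamin_d": {"no": (164, 234), "yes": (135, 258)},
    "vitamin_e": {"no": (247, 398), "yes": (52, 94)},
    "primrose": {"no": (287, 465), "yes": (12, 27)},
    "omega3": {"no": (264, 433), "yes": (35, 59)},
    "breast_disease_history": {"no": (217, 392), "yes": (82, 100)},
}
_N_LOW, _N_HIGH = 299, 492
_N_LIFETIME_TEHRAN = 420


def make_table_fixtures() -> pd.DataFrame:
    """A 791-row categorical fixture with exact published-style margins.

    Every categorical variable's cross-tab with dichotomized density
    reproduces the stated 2x2 (or 2x3) counts exactly; 62.2% of rows are
    high density and 420 are lifetime Tehran residents.  Deterministic row
    order (low-density block first).
    """
    density = ["low"] * _N_LOW + ["high"] * _N_HIGH
    df = pd.DataFrame({"density": density})
    df["high_density"] = (df["density"] == "high").astype(int)
    for var, levels in _CATEGORICAL_MARGINS.items():
        col = []
        for block, n_block in ((0, _N_LOW), (1, _N_HIGH)):
            for level, counts in levels.items():
                col.extend([level] * counts[block])
        df[var] = col
    lifetime = [1] * _N_LIFETIME_TEHRAN + [0] * (len(df) - _N_LIFETIME_TEHRAN)
    df["lifetime_tehran"] = lifetime
    return df


class PanelExposureField:
    """Callable point -> pollutant exposures, IDW over a panel's annual means.

    Evaluates, for each pollutant, the mean over the panel's years of the
    inverse-distance-weighted annual mean of the k nearest included
    stations — i.e. the exposure surface the study design assigns.
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        stations: pd.DataFrame,
        inclusion: pd.DataFrame,
        years: tuple[int, ...],
        k: int = 3,
        power: float = 2.0,
    ) -> None:
        self.means = qc.annual_means(panel)
        self.stations = stations
        self.inclusion = inclusion
        self.years = years
        self.k = k
        self.power = power
        self.pollutants = sorted(self.means["pollutant"].unique())

    def __call__(self, point: GeoPoint) -> dict[str, float]:
        out = {}
        for pol in self.pollutants:
            vals = []
            for year in self.years:
                est, _ = exposure.person_year_exposure(
                    point, pol, year, self.means, self.inclusion, self.stations,
                    self.k, self.power,
                )
                vals.append(est)
            out[pol] = float(np.mean(vals))
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _degrade_stations(
    panel: pd.DataFrame, station_ids: list[str], extra_missing: float, seed: int
) -> pd.DataFrame:
    """Push selected stations below the completeness threshold by masking hours."""
    rng = np.random.default_rng(seed)
    panel = panel.copy()
    mask = panel["station_id"].isin(station_ids)
    knockout = rng.random(mask.sum()) < extra_missing
    idx = panel.index[mask][knockout]
    panel.loc[idx, "value"] = np.nan
    return panel


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> qc -> expose -> analyze; write outputs + manifest.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {
        name: int(s)
        for name, s in zip(
            ["network", "panel", "degrade", "cohort", "eligibility"],
            rng.integers(0, 2**31 - 1, size=5),
        )
    }
    manifest: dict = {"config": _config_echo(config), "stages": {}}

    # --- simulate ------------------------------------------------------
    network = synthetic.generate_station_network(
        config.n_stations, config.extent_km, seeds["network"]
    )
    panel_spec = synthetic.PanelSpec(
        years=config.years,
        missing_rate=config.missing_rate,
        outlier_rate=config.outlier_rate,
        outlier_magnitude=config.outlier_magnitude,
        seed=seeds["panel"],
    )
    panel, truth = synthetic.generate_hourly_panel(network, panel_spec)
    low_ids = network.stations["station_id"].tolist()[-config.n_low_completeness :]
    if config.n_low_completeness:
        panel = _degrade_stations(
            panel, low_ids, config.low_completeness_missing, seeds["degrade"]
        )
    manifest["stages"]["simulate"] = {
        "n_stations": int(len(network.stations)),
        "n_panel_rows": int(len(panel)),
        "n_injected_outliers": int(len(truth)),
        "degraded_stations": low_ids,
    }

    # --- qc ------------------------------------------------------------
    inclusion = qc.filter_stations(
        panel, config.qc.completeness_threshold, config.qc.station_level
    )
    cleaned, flags = qc.clean_panel(panel, config.qc, inclusion)
    included_stations = sorted(
        inclusion.loc[inclusion["included"], "station_id"].unique()
    )
    manifest["stages"]["qc"] = {
        "n_series": int(len(inclusion)),
        "n_series_included": int(inclusion["included"].sum()),
        "n_stations_included": len(included_stations),
        "n_hours_flagged": int(len(flags)),
    }
    report = qc.qc_report(panel, inclusion, flags)
    (out / "qc_report.json").write_text(json.dumps(report, indent=2))

    # --- cohort + eligibility -----------------------------------------
    field_fn = PanelExposureField(
        cleaned, network.stations, inclusion, config.years,
        config.idw_k, config.idw_power,
    )
    cohort_spec = synthetic.CohortSpec(n=config.n_screened, seed=seeds["cohort"])
    screened = synthetic.generate_cohort(network, field_fn, cohort_spec)
    elig_rng = np.random.default_rng(seeds["eligibility"])
    flagged_idx = elig_rng.choice(
        config.n_screened, size=config.n_suspicious + config.n_bad_address,
        replace=False,
    )
    screened["suspicious_mammogram"] = False
    screened["incomplete_address"] = False
    screened.loc[flagged_idx[: config.n_suspicious], "suspicious_mammogram"] = True
    screened.loc[flagged_idx[config.n_suspicious :], "incomplete_address"] = True
    cohort, elig_log = apply_eligibility(screened)
    manifest["stages"]["eligibility"] = elig_log

    # --- expose --------------------------------------------------------
    exposures = exposure.assign_exposures(
        cohort, cleaned, inclusion, network.stations, list(config.years),
        pollutants=tuple(sorted(POLLUTANTS)), k=config.idw_k, power=config.idw_power,
    )
    cohort = cohort.drop(columns=list(POLLUTANTS), errors="ignore").merge(
        exposures, on="participant_id"
    )
    manifest["stages"]["expose"] = {"n_participants": int(len(cohort))}

    # --- analyze -------------------------------------------------------
    agreement = analysis.cohens_kappa(
        cohort["birads_rater1"], cohort["birads_rater2"]
    )
    stepwise = analysis.stepwise_logistic(
        cohort, sorted(POLLUTANTS), p_enter=config.p_enter, p_remove=config.p_remove
    )
    non_stepwise = analysis.fit_logistic(
        cohort, sorted(POLLUTANTS), label="non-stepwise"
    )
    retained = stepwise.terms if stepwise.terms else ["no2", "co"]
    models = analysis.confounder_models(cohort, exposures=retained)
    results = {
        "kappa": {
            "kappa": agreement.kappa,
            "ci": [agreement.ci_low, agreement.ci_high],
            "n": agreement.n,
        },
        "prevalence_high_density": float(cohort["high_density"].mean()),
        "stepwise": _model_to_dict(stepwise),
        "non_stepwise": _model_to_dict(non_stepwise),
        "confounder_models": {k: _model_to_dict(m) for k, m in models.items()},
    }
    try:
        strat = analysis.stratified_and_moderator(cohort, exposures=retained)
        results["stratified"] = {
            "interaction_p_value": strat["interaction_p_value"],
            "strata": {
                str(k): _model_to_dict(m) for k, m in strat["strata"].items()
            },
        }
    except (analysis.SeparationError, analysis.ConvergenceError) as exc:
        results["stratified"] = {"error": str(exc)}
    manifest["stages"]["analyze"] = {
        "stepwise_terms": stepwise.terms,
        "kappa": agreement.kappa,
    }

    # --- outputs -------------------------------------------------------
    cleaned.to_csv(out / "cleaned_panel.csv", index=False)
    flags.to_csv(out / "flags.csv", index=False)
    cohort.to_csv(out / "cohort.csv", index=False)
    exposures.to_csv(out / "exposures.csv", index=False)
    (out / "analysis.json").write_text(json.dumps(results, indent=2, default=float))
    manifest["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(out.glob("*.csv")) + [out / "analysis.json"]
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _model_to_dict(model: analysis.ModelResult) -> dict:
    frame = model.odds_ratios
    return {
        "label": model.label,
        "n": model.n,
        "terms": {
            str(term): {
                "or": float(frame.loc[term, "or"]),
                "ci_low": float(frame.loc[term, "ci_low"]),
                "ci_high": float(frame.loc[term, "ci_high"]),
                "p_value": float(frame.loc[term, "p_value"]),
            }
            for term in frame.index
        },
        "trace": model.trace,
    }


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    echo["qc"] = asdict(config.qc)
    return echo
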
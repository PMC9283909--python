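import numpy as np
import pandas as pd
import pytest

from airdense.synthetic import (
    CohortSpec,
    PanelSpec,
    SinusoidalExposureField,
    DEFAULT_EXPOSURE_FIELD,
    generate_cohort,
    generate_hourly_panel,
    generate_station_network,
)


def make_panel(values_by_station, pollutant="no2", start="2020-01-01"):
    """Long-format panel from {station_id: array-like}; NaN marks missing."""
    frames = []
    for sid, vals in values_by_station.items():
        vals = np.asarray(vals, dtype=float)
        ts = pd.date_range(start, periods=len(vals), freq="h")
        frames.append(
            pd.DataFrame(
                {"station_id": sid, "timestamp": ts, "pollutant": pollutant, "value": vals}
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def network4():
    return generate_station_network(4, extent_km=10.0, seed=11)


@pytest.fixture(scope="session")
def small_panel():
    """3 stations x 6 pollutants x 1 year with injected spikes and gaps."""
    net = generate_station_network(3, extent_km=10.0, seed=5)
    spec = PanelSpec(years=(2020,), missing_rate=0.08, outlier_rate=0.002, seed=7)
    panel, truth = generate_hourly_panel(net, spec)
    return net, panel, truth


@pytest.fixture(scope="session")
def recovery_cohort():
    """n=20k cohort generated from pollutants-only truth (for refit checks)."""
    net = generate_station_network(22, 40.0, seed=3)
    field = SinusoidalExposureField(DEFAULT_EXPOSURE_FIELD, 40.0, seed=4)
    spec = CohortSpec(n=20_000, covariate_log_or={}, seed=9)
    return generate_cohort(net, field, spec)
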
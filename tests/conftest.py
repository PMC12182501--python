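import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from soilresp import ForcingSeries, ObsSeries

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_forcing() -> ForcingSeries:
    """One year of clean daily drivers with a simple seasonal cycle."""
    dates = pd.date_range("2010-01-01", "2010-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    frame = pd.DataFrame(
        {
            "soil_T": 15.0 + 10.0 * np.sin(2 * np.pi * (doy - 105) / 365),
            "soil_M": 30.0 + 8.0 * np.sin(2 * np.pi * (doy - 105) / 365),
            "LAI": 4.0 + 1.0 * np.sin(2 * np.pi * (doy - 105) / 365),
            "GPP": 6.0 + 4.0 * np.sin(2 * np.pi * (doy - 105) / 365),
        },
        index=dates,
    )
    return ForcingSeries(frame)


@pytest.fixture
def obs_with_violations() -> ObsSeries:
    """Ten observations: two with HR > SR, one on a rain date (2010-05-03)."""
    dates = pd.date_range("2010-01-05", periods=10, freq="14D")
    hr = np.full(10, 1.0)
    sr_ = np.full(10, 1.8)
    hr[2] = 2.0  # HR > SR
    hr[7] = 3.0  # HR > SR
    frame = pd.DataFrame({"HR": hr, "SR": sr_}, index=dates)
    return ObsSeries(frame)
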
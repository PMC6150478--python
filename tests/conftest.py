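import numpy as np
import pandas as pd
import pytest

from undocpop import AnnualInputSeries, SynthConfig, generate_inputs, load_us_inputs


@pytest.fixture(scope="session")
def us_inputs():
    """Bundled synthetic stand-in for the 1990-2016 U.S. series."""
    return load_us_inputs()


@pytest.fixture(scope="session")
def synth_inputs():
    return generate_inputs(SynthConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_inputs(
    years=range(1990, 2017),
    apprehensions=1_000_000.0,
    visas=6_000_000.0,
    deportations=0.0,
    adjustments=0.0,
    overstay_rate=0.0,
    dhs_rates=None,
):
    """Hand-built input series with constant columns (NaN recidivism block)."""
    years = np.array(list(years))
    n = len(years)
    frame = pd.DataFrame(
        {
            "apprehensions": np.full(n, float(apprehensions)),
            "recidivist_apprehensions": np.full(n, np.nan),
            "deterrence_rate": np.full(n, np.nan),
            "dhs_apprehension_rate": np.full(n, np.nan),
            "visas_issued": np.full(n, float(visas)),
            "deportations": np.full(n, float(deportations)),
            "status_adjustments": np.full(n, float(adjustments)),
        },
        index=pd.Index(years, name="year"),
    )
    if dhs_rates:
        for year, rate in dhs_rates.items():
            frame.at[year, "dhs_apprehension_rate"] = rate
    return AnnualInputSeries(frame=frame, overstay_rate_2016=overstay_rate)
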
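import numpy as np
import pytest

from otolife import BombCurveConfig, GrowthParams, RadiocarbonSample


@pytest.fixture(scope="session")
def table1_params() -> GrowthParams:
    """Posterior point estimates of the published growth/mortality fit."""
    return GrowthParams(
        linf=1533.0, k=0.14, t0=1.82, cv_len=0.17,
        l50=812.0, sel_steepness=78.8, m_nat=0.066, f_mort=0.34,
    )


@pytest.fixture(scope="session")
def bomb_config() -> BombCurveConfig:
    return BombCurveConfig(seed=0)


def make_core_samples(years, d14c_values, collection_year=2017, d14c_sd=5.0):
    """Build RadiocarbonSample objects with the given birth years/values."""
    out = []
    for i, (y, v) in enumerate(zip(np.asarray(years), np.asarray(d14c_values))):
        out.append(
            RadiocarbonSample(
                sample_id=f"SYN-{i:02d}",
                collection_date=int(collection_year),
                tl_mm=1000.0,
                age_years=int(collection_year - y),
                d14c=float(v),
                d14c_sd=d14c_sd,
            )
        )
    return out
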
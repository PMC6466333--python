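import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fertrisk as fr
from fertrisk.metals import METAL_COLUMNS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exposure():
    return fr.load_exposure_parameters()


@pytest.fixture(scope="session")
def toxicity():
    return fr.load_toxicity_parameters()


@pytest.fixture(scope="session")
def soil_limits():
    return fr.load_soil_limits()


def region_params(region):
    return fr.load_region_parameters(region)


def survey_medians(region):
    summary = fr.load_survey_summary(region)
    return {m: float(summary.loc[m.value, "median"]) for m in fr.METALS}


def make_table(columns: dict, region: str = "test") -> pd.DataFrame:
    """Concentration table from per-metal value arrays; unspecified metals
    are filled with an arbitrary positive constant."""
    n = len(next(iter(columns.values())))
    data = {c: np.asarray(columns.get(c, np.full(n, 1.0)), dtype=float)
            for c in METAL_COLUMNS}
    return pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)], "region": region, **data}
    )
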
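import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_records(temperature_K, k, rate_type="uptake", *, species="sp",
                 chemical="chem", mass_kg=np.nan, log_dow=np.nan, taxon="Crustacea"):
    """Minimal canonical-schema frame for fitting/prep tests."""
    t = np.atleast_1d(np.asarray(temperature_K, dtype=float))
    kk = np.atleast_1d(np.asarray(k, dtype=float))
    n = t.size
    return pd.DataFrame({
        "source_id": [f"src{i}" for i in range(n)],
        "species": species, "taxon": taxon, "life_stage": np.nan,
        "chemical": chemical, "chemical_group": "PCBs",
        "log_dow": log_dow, "temperature_K": t, "rate_type": rate_type,
        "k": kk, "k_unit": "", "mass_kg": mass_kg,
    })


@pytest.fixture
def records_factory():
    return make_records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
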
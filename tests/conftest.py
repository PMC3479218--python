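import numpy as np
import pytest

from ovucycle.reference_data import HormoneSeries, generate_reference_cycle


@pytest.fixture(scope="session")
def reference():
    return generate_reference_cycle()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_series(rng, n_days: int = 28, first_day: int = -14) -> HormoneSeries:
    """A random valid hormone series for round-trip/property tests."""
    days = np.arange(first_day, first_day + n_days)
    return HormoneSeries(
        days=days,
        fsh=rng.uniform(0.0, 30.0, n_days),
        lh=rng.uniform(0.0, 60.0, n_days),
        estradiol=rng.uniform(0.0, 1000.0, n_days),
        progesterone=rng.uniform(0.0, 40.0, n_days),
    )
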
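import pandas as pd
import pytest

from ulcerguard import EstimatorCoefficients, InjuryThreshold


@pytest.fixture
def default_coeffs():
    return EstimatorCoefficients()


@pytest.fixture
def default_threshold():
    return InjuryThreshold()


def make_damage_observations(c0, c1, c2, n, sigma, rng):
    """Synthetic (duration, pressure, damage) table from a known affine model."""
    duration = rng.uniform(0.0, 60.0, n)
    pressure = rng.uniform(5.0, 100.0, n)
    damage = c0 + c1 * duration + c2 * pressure
    if sigma > 0:
        damage = damage + rng.normal(0.0, sigma, n)
    return pd.DataFrame(
        {"duration_min": duration, "pressure_kpa": pressure, "damage": damage}
    )


@pytest.fixture
def damage_table_factory():
    return make_damage_observations
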
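"""Shared fixtures: class tables, scaled-down study configurations and runs.

Scenario runs use a reduced problem (k_max = 25 classes, dz = 0.5 m,
dt = 30 s over the 10 m column) so the whole suite stays fast; the physics
and the numerics are exactly those of the full-size setup.
"""

from dataclasses import replace

import numpy as np
import pytest

import cyanoagg as ca

HIGH = ca.ScenarioSchedule(mode="constant", labels=("high_wind",))
LOW = ca.ScenarioSchedule(mode="constant", labels=("low_wind",))
DAILY = ca.ScenarioSchedule(mode="alternating", labels=("high_wind", "low_wind"), period=86400.0)
HOURLY = ca.ScenarioSchedule(mode="alternating", labels=("high_wind", "low_wind"), period=3600.0)


@pytest.fixture(scope="session")
def table101():
    """Full-size class table with all default parameters."""
    return ca.build_colony_table()


@pytest.fixture(scope="session")
def table25():
    """Reduced class table (k_max = 25) for scenario runs."""
    return ca.build_colony_table(k_max=25)


@pytest.fixture(scope="session")
def scaled_cfg():
    """Scaled-down 7-day configuration at the standard seeded concentration."""
    return ca.NumericalConfig(
        dz=0.5, dt=30.0, z_max=10.0, t_end=7 * 86400.0, h_ML=3.0, n0=2.3e7
    )


@pytest.fixture(scope="session")
def dense_cfg(scaled_cfg):
    """High-concentration (2.3e8 colonies/m^3) 4-day configuration; at this
    concentration the largest reduced class appears within ~1.5 days under
    constant high wind, which keeps comparative scenario runs short."""
    return replace(scaled_cfg, n0=2.3e8, t_end=4 * 86400.0)


@pytest.fixture(scope="session")
def base_run(scaled_cfg, table25):
    """Constant high wind, 7 days, standard concentration."""
    return ca.run_simulation(scaled_cfg, HIGH, table25)


@pytest.fixture(scope="session")
def dense_run_high(dense_cfg, table25):
    return ca.run_simulation(dense_cfg, HIGH, table25)


@pytest.fixture(scope="session")
def dense_run_low(dense_cfg, table25):
    return ca.run_simulation(dense_cfg, LOW, table25)


@pytest.fixture(scope="session")
def dense_run_daily(dense_cfg, table25):
    return ca.run_simulation(dense_cfg, DAILY, table25)


@pytest.fixture(scope="session")
def dense_run_hourly(dense_cfg, table25):
    return ca.run_simulation(dense_cfg, HOURLY, table25)


@pytest.fixture(scope="session")
def dense_run_noadv(dense_cfg, table25):
    """Same as dense_run_high but with the buoyant velocity forced to zero."""
    return ca.run_simulation(dense_cfg, HIGH, table25, include_advection=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
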
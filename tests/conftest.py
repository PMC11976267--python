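import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import axonbrake as ab
from axonbrake import defaults

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dls():
    return ab.build_region_params("DLS")


@pytest.fixture(scope="session")
def nacc():
    return ab.build_region_params("NAcc")


@pytest.fixture(scope="session")
def both_regions(dls, nacc):
    return {"DLS": dls, "NAcc": nacc}


@pytest.fixture(scope="session")
def default_kernel():
    return ab.make_parametric_kernel()


def run_default_scenario(region_params, beta, chi_label, *, desensitization=True,
                         da_label="burst", duration=1500.0, dt=1.0):
    """One default-conditions scenario run, shared across simulator tests."""
    cfg = ab.SimConfig(
        beta=beta,
        duration=duration,
        dt=dt,
        da_tonic_rate=defaults.DA_TONIC_HZ,
        desensitization_enabled=desensitization,
    )
    da = ab.resolve_da_pattern(da_label, duration, dt)
    chi = ab.resolve_chi_pattern(chi_label, duration, dt, region_params.tonic_chi_rate)
    return ab.simulate_dao(da, chi, region_params, cfg)


@pytest.fixture(scope="session")
def scenario_runner():
    return run_default_scenario
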
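import numpy as np
import pytest

from robinflux import (SimulationConfig, SourceSpec, domain_partition,
                       make_body, simulate)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def sphere_body():
    return make_body("sphere")


@pytest.fixture(scope="session")
def spheroid_body():
    return make_body("prolate_spheroid", 3.0)


@pytest.fixture(scope="session")
def spherocylinder_body():
    return make_body("spherocylinder", 2.0)


@pytest.fixture(scope="session")
def sphere_partition_16(sphere_body):
    return domain_partition(sphere_body, 16)


@pytest.fixture(scope="session")
def sphere_counts_16(sphere_body, sphere_partition_16):
    """A modest reflective run on the unit sphere shared by statistical
    unit tests (lambda = 0.01 keeps it quick)."""
    config = SimulationConfig(lam=0.01, n_try=20_000, M=16, seed=11,
                              subsample_size=2_000)
    return simulate(sphere_body, sphere_partition_16, config, SourceSpec())
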
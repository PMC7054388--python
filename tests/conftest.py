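from pathlib import Path

import pytest

from clonalgc import GCParameters, SeedingConfig, SolverSettings

CONFIG_DIR = Path(__file__).resolve().parent.parent / "configs"


@pytest.fixture(scope="session")
def baseline_params() -> GCParameters:
    """Few-stage baseline: n=8, sigma_c = 0.5 sigma, Table-style defaults."""
    return GCParameters(n=8)


@pytest.fixture(scope="session")
def many_stage_params() -> GCParameters:
    return GCParameters(n=50)


@pytest.fixture(scope="session")
def toy_params() -> GCParameters:
    """Minimal two-stage system for cheap solver cross-checks."""
    return GCParameters(n=2)


@pytest.fixture(scope="session")
def equal_seeding() -> SeedingConfig:
    return SeedingConfig()


@pytest.fixture
def config_dir() -> Path:
    return CONFIG_DIR
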
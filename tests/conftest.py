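import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from thermoseed.materials import (
    SeedComponent,
    default_registry,
    default_seed_spec,
)
from thermoseed.scenarios import conduction_benchmark, single_seed_liver
from thermoseed.solver import solve_steady


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def seed_spec():
    return default_seed_spec()


@pytest.fixture(scope="session")
def table_components(registry):
    """Composite-seed components with the published volume fractions."""
    fr = registry["seed_volume_fractions"]
    return [
        SeedComponent(material=registry["materials"][name], volume_fraction=frac)
        for name, frac in fr.items()
    ]


@pytest.fixture(scope="session")
def single_seed_problem():
    """Moderate-resolution axisymmetric single-seed liver problem."""
    return single_seed_liver(resolution=5e-5)


@pytest.fixture(scope="session")
def single_seed_field(single_seed_problem):
    return solve_steady(single_seed_problem)


@pytest.fixture(scope="session")
def benchmark_problem():
    return conduction_benchmark(resolution=5e-5)


@pytest.fixture(scope="session")
def benchmark_field(benchmark_problem):
    return solve_steady(benchmark_problem)
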
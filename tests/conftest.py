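import warnings

import pytest
from hypothesis import settings, HealthCheck

from specfilt import GridSpec, load_standards, generate_synthetic_database, compute_database_metrics

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def bundle(grid):
    return load_standards(grid)


@pytest.fixture(scope="session")
def synthetic_db(bundle):
    """Seeded 121-filter synthetic database with metrics, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = generate_synthetic_database(n=121, seed=0, grid=bundle.grid)
    return compute_database_metrics(db, bundle)
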
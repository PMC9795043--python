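import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cdr3shm.germline import SUBSET1, SUBSET6, build_archetype, default_db

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def db():
    return default_db()


@pytest.fixture(scope="session")
def arc1(db):
    return build_archetype(SUBSET1, db)


@pytest.fixture(scope="session")
def arc6(db):
    return build_archetype(SUBSET6, db)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
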
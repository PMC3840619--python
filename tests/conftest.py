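import pytest
from hypothesis import HealthCheck, settings

from trimeth.digest import digest, parse_cut_site, select_and_mask
from trimeth.genome import build_index
from trimeth.simulate import assign_methylation, generate_genome

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genome50k():
    return generate_genome(50_000, 0.5, seed=7)


@pytest.fixture(scope="session")
def bundle50k(genome50k):
    return build_index(genome50k)


@pytest.fixture(scope="session")
def states50k(genome50k):
    return assign_methylation(genome50k, {"CG": 0.8, "CHG": 0.2, "CHH": 0.05}, seed=8)


@pytest.fixture(scope="session")
def genome5k():
    return generate_genome(5_000, 0.5, seed=9)


@pytest.fixture(scope="session")
def bundle5k(genome5k):
    return build_index(genome5k)


@pytest.fixture(scope="session")
def rr50k(genome50k):
    frags = digest(genome50k, [parse_cut_site("C'CGG")])
    return select_and_mask(genome50k, frags, 40, 250)


@pytest.fixture(scope="session")
def rr_bundle50k(rr50k):
    return build_index(rr50k)
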
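import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def cspds5_alignment():
    from sexmarker import fixtures
    return fixtures.cspds5_alignment()


@pytest.fixture(scope="session")
def cspds5_genomic():
    from sexmarker import fixtures
    return fixtures.cspds5_genomic()


@pytest.fixture(scope="session")
def enzymes():
    from sexmarker import read_enzyme_table
    from sexmarker.fixtures import enzyme_table_path
    return read_enzyme_table(enzyme_table_path())


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
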
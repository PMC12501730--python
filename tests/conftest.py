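import pytest
from hypothesis import HealthCheck, settings

from irdtriage import fixtures

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


# function-scoped: flag_novel mutates records in place
@pytest.fixture
def table2_records():
    return fixtures.load_table2()


@pytest.fixture(scope="session")
def table3_rows():
    return fixtures.load_table3()


@pytest.fixture(scope="session")
def table1_frame():
    return fixtures.load_table1()
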
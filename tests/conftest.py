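import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    caplog.set_level(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def table2_frame():
    from modscreen import datasets

    return datasets.table2()


@pytest.fixture(scope="session")
def table2_records():
    from modscreen import datasets

    return datasets.table2_progeny()
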
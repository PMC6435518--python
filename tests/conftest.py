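import json
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def worked_example_expected() -> dict:
    """Hand-computed score table for the fixed worked example."""
    return json.loads((DATA / "worked_example_expected.json").read_text())


@pytest.fixture(scope="session")
def worked_network():
    from trimodenet import worked_example

    return worked_example()
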
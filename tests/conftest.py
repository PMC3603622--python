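"""Shared fixtures: each paper scenario is simulated once per session."""

import pytest

from coroflow import CoronaryCirculationModel


def _run(name, **kw):
    return CoronaryCirculationModel.from_scenario(name, **kw).simulate()


@pytest.fixture(scope="session")
def healthy_run():
    """Healthy baseline; also serves as the post-AVR state of the LVH scenario."""
    return _run("healthy")


@pytest.fixture(scope="session")
def mild_stenosis_run():
    return _run("stenosis-mild")


@pytest.fixture(scope="session")
def severe_stenosis_run():
    return _run("stenosis-severe")


@pytest.fixture(scope="session")
def severe_stenosis_linear_run():
    """Severe stenosis with the linear (E = 1.5 MPa) coronary wall law."""
    return _run("stenosis-severe", coronary_wall="linear")


@pytest.fixture(scope="session")
def lvh_pre_run():
    return _run("lvh-pre")
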
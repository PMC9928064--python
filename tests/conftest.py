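import pytest

from aedcorridor import fixture_corridor22, make_corridor


@pytest.fixture(scope="session")
def fig_fixture():
    """The 22-cell uniform corridor and its named worked-example deployments."""
    return fixture_corridor22()


@pytest.fixture(scope="session")
def corridor22(fig_fixture):
    return fig_fixture[0]


@pytest.fixture(scope="session")
def corridor17():
    return make_corridor(17)
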
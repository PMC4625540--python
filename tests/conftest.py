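import pytest

from signcons.synth import builtin_instances


@pytest.fixture(scope="session")
def instances():
    """The hand-built example instances (name -> (graph, profile))."""
    return builtin_instances()


@pytest.fixture
def g1(instances):
    return instances["g1"]


@pytest.fixture
def g2(instances):
    return instances["g2"]


@pytest.fixture
def g3(instances):
    return instances["g3"]


@pytest.fixture
def g4(instances):
    return instances["g4"]


@pytest.fixture
def posloop(instances):
    return instances["posloop"]
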
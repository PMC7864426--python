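import pytest

from schemarec import (
    build_task_diagram,
    make_cyclic_monoid,
    make_klein_monoid,
    regular_representation,
)


@pytest.fixture(scope="session")
def c2():
    return make_cyclic_monoid(2)


@pytest.fixture(scope="session")
def c3():
    return make_cyclic_monoid(3)


@pytest.fixture(scope="session")
def c4():
    return make_cyclic_monoid(4)


@pytest.fixture(scope="session")
def c6():
    return make_cyclic_monoid(6)


@pytest.fixture(scope="session")
def klein():
    return make_klein_monoid()


@pytest.fixture(scope="session")
def tau1(c3):
    """The triangle-rotation task on the first trigram vocabulary."""
    return regular_representation(c3, ("BEH", "FUT", "PEJ"))


@pytest.fixture(scope="session")
def tau2(c3):
    """The structurally identical task on a fresh trigram vocabulary."""
    return regular_representation(c3, ("HUQ", "KES", "NIZ"))


@pytest.fixture(scope="session")
def two_task_diagram(tau1, tau2):
    return build_task_diagram([tau1, tau2])
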
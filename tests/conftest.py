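import pytest

from pedrel import builtin


@pytest.fixture(scope="session")
def habsburg():
    return builtin("habsburg")


@pytest.fixture(scope="session")
def fig1():
    return builtin("fig1-example")


@pytest.fixture(scope="session")
def incest():
    return builtin("figS1-incest")


@pytest.fixture(scope="session")
def trio():
    return builtin("trio")


@pytest.fixture(scope="session")
def full_sibs():
    return builtin("full-siblings")
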
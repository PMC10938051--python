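import pytest

from arklint.checks import CheckConfig
from arklint.fixtures import build_paper_example, build_revised_example


@pytest.fixture
def config():
    return CheckConfig()


@pytest.fixture(scope="session")
def paper_tree():
    return build_paper_example()


@pytest.fixture(scope="session")
def revised_tree():
    return build_revised_example()
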
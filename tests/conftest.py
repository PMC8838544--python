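import pytest

from dqas import naiis_response, naiis_rubric


@pytest.fixture(scope="session")
def rubric():
    return naiis_rubric()


@pytest.fixture(scope="session")
def response():
    return naiis_response()
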
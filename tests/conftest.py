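import pytest

from ms1class import default_kb


@pytest.fixture(scope="session")
def kb():
    return default_kb()
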